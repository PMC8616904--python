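import numpy as np
import pytest

from supergene.simulate import (
    DEFAULT_SWEEP_AXES,
    EMPIRICAL_GENOTYPE_COUNTS,
    SimConfig,
    SimState,
    choose_mates,
    fitness,
    init_population,
    ratio_difference,
    recombine,
    run,
    spatial_stratification,
    step_generation,
    sweep,
)


def _state(pos, inv, pop=None, n_loci=4, neut=None):
    pos = np.asarray(pos, dtype=float)
    inv = np.asarray(inv, dtype=np.uint8)
    m = len(pos)
    if neut is None:
        neut = np.zeros((m, 2, n_loci), dtype=np.uint8)
    locus_pos = np.linspace(2500, 97_500, n_loci)
    pop = np.zeros(m, dtype=int) if pop is None else np.asarray(pop)
    return SimState(pos, pop, inv, np.asarray(neut, dtype=np.uint8), locus_pos)


class TestInitPopulation:
    def test_fixed_seed_identical_state(self):
        cfg = SimConfig(model=1, n=50, seed=3)
        a = init_population(cfg, np.random.default_rng(9))
        b = init_population(cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a.pos, b.pos)
        np.testing.assert_array_equal(a.inv, b.inv)

    def test_zero_init_frequency_all_aa(self):
        cfg = SimConfig(model=1, n=30, init_B_frequency=0.0)
        state = init_population(cfg, np.random.default_rng(0))
        assert state.genotype_counts() == (30, 0, 0)

    def test_heterozygote_count_within_binomial_interval(self):
        cfg = SimConfig(model=1, n=1000, init_B_frequency=0.5)
        counts = []
        for seed in range(20):
            state = init_population(cfg, np.random.default_rng(seed))
            counts.append(state.genotype_counts()[1])
        # E[n_AB] = 500, sd = sqrt(1000 * 0.25) ~ 15.8; 99% band over 20 seeds
        assert abs(np.mean(counts) - 500) < 3 * 15.8 / np.sqrt(20)

    def test_model2_two_demes(self):
        cfg = SimConfig(model=2, n=40)
        state = init_population(cfg, np.random.default_rng(0))
        assert len(state.pos) == 80
        assert (np.bincount(state.pop) == [40, 40]).all()


class TestFitness:
    def test_neutral_selection_equal_fitness(self):
        state = _state([[0.5, 0.1], [0.5, 0.9]], [[0, 0], [1, 1]])
        cfg = SimConfig(model=1, n=2, s=0.0, competition_strength=0.0)
        w = fitness(state, cfg)
        assert np.allclose(w, 1.0)

    def test_matched_genotype_no_neighbors_full_fitness(self):
        state = _state([[0.5, 1.0]], [[1, 1]])  # BB at y = 1
        cfg = SimConfig(model=1, n=1, s=0.7, competition_strength=0.0)
        assert fitness(state, cfg)[0] == pytest.approx(1.0)

    def test_mismatch_linear_penalty(self):
        state = _state([[0.5, 1.0]], [[0, 0]])  # AA at y = 1
        cfg = SimConfig(model=1, n=1, s=0.4, competition_strength=0.0)
        assert fitness(state, cfg)[0] == pytest.approx(0.6)

    def test_competition_divides_fitness(self):
        pos = [[0.5, 0.5], [0.5, 0.5], [0.5, 0.5]]
        state = _state(pos, [[1, 0]] * 3)
        cfg = SimConfig(model=1, n=3, s=0.0, competition_strength=0.5,
                        competition_radius=0.1)
        w = fitness(state, cfg)
        assert np.allclose(w, 1.0 / (1 + 0.5 * 2))

    def test_model2_gradient_continues_across_demes(self):
        # BB at the top of deme 1 sits at the global optimum for phenotype 1
        state = _state([[0.5, 1.0]], [[1, 1]], pop=[1])
        cfg = SimConfig(model=2, n=1, s=1.0)
        assert fitness(state, cfg)[0] == pytest.approx(1.0)
        state2 = _state([[0.5, 1.0]], [[0, 0]], pop=[1])  # AA at global y = 1
        assert fitness(state2, cfg)[0] == pytest.approx(0.0)


class TestChooseMates:
    def test_uniform_choice_under_neutrality(self):
        rng = np.random.default_rng(0)
        k = 4
        dosage = np.array([1, 0, 1, 2])
        w = np.ones(k)
        in_range = ~np.eye(k, dtype=bool)
        cfg = SimConfig(model=1, n=k, a=0.0)
        mothers = np.zeros(10_000, dtype=int)
        mates = choose_mates(dosage, cfg, w, in_range, mothers, rng)
        counts = np.bincount(mates, minlength=k)
        assert counts[0] == 0
        from scipy.stats import chisquare

        assert chisquare(counts[1:]).pvalue > 0.001

    def test_single_candidate_chosen_with_certainty(self):
        rng = np.random.default_rng(0)
        dosage = np.array([1, 2])
        in_range = np.array([[False, True], [True, False]])
        cfg = SimConfig(model=1, n=2, a=0.0)
        mates = choose_mates(dosage, cfg, np.ones(2), in_range,
                             np.zeros(50, dtype=int), rng)
        assert (mates == 1).all()

    def test_strong_assortment_prefers_same_genotype(self):
        rng = np.random.default_rng(0)
        dosage = np.array([1, 0, 1, 2])
        in_range = ~np.eye(4, dtype=bool)
        cfg = SimConfig(model=1, n=4, a=0.99)
        mates = choose_mates(dosage, cfg, np.ones(4), in_range,
                             np.zeros(20_000, dtype=int), rng)
        same = (dosage[mates] == 1).mean()
        # weights 1 : 0.01 : 0.01 -> P(same genotype) = 1/1.02 ~ 0.98
        assert same == pytest.approx(1 / 1.02, abs=0.01)


class TestRecombine:
    @staticmethod
    def _ab_parent_state(n_loci=6):
        inv = np.array([[0, 1]])
        neut = np.zeros((1, 2, n_loci), dtype=np.uint8)
        neut[0, 1] = 1  # B haplotype carries allele 1 at every neutral locus
        return _state([[0.5, 0.5]], inv, n_loci=n_loci, neut=neut)

    def test_heterozygote_inversion_is_never_recombined(self):
        # all loci and the whole chromosome inside the inversion: every
        # crossover is rejected, so gametes are pure parental haplotypes
        state = self._ab_parent_state()
        cfg = SimConfig(model=1, n=1, inversion_interval=(0, 100_000),
                        recombination_rate=2e-4, mutation_rate=0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            inv_g, neut_g = recombine(state, np.array([0]), cfg, rng)
            assert (neut_g[0] == inv_g[0]).all()  # B-linked alleles stay with B

    def test_homozygote_crossovers_accepted(self):
        state = self._ab_parent_state()
        state.inv[0] = [0, 0]  # homozygote with heterogeneous neutral haplotypes
        cfg = SimConfig(model=1, n=1, inversion_interval=(0, 100_000),
                        recombination_rate=2e-4, mutation_rate=0.0)
        rng = np.random.default_rng(0)
        mixed = False
        for _ in range(50):
            _, neut_g = recombine(state, np.array([0]), cfg, rng)
            vals = set(neut_g[0].tolist())
            if vals == {0, 1}:
                mixed = True
        assert mixed

    def test_zero_rate_gives_exact_parental_haplotypes(self):
        state = self._ab_parent_state()
        cfg = SimConfig(model=1, n=1, recombination_rate=0.0, mutation_rate=0.0)
        rng = np.random.default_rng(1)
        inv_g, neut_g = recombine(state, np.zeros(200, dtype=int), cfg, rng)
        assert set(map(tuple, np.unique(neut_g, axis=0).tolist())) <= {
            (0,) * 6, (1,) * 6
        }
        assert ((neut_g.sum(axis=1) == 0) == (inv_g == 0)).all()


class TestStepGeneration:
    def test_population_size_conserved(self):
        cfg = SimConfig(model=1, n=80, s=0.3, a=0.5, generations=1)
        rng = np.random.default_rng(0)
        state = init_population(cfg, rng)
        for _ in range(5):
            state = step_generation(state, cfg, rng)
            assert len(state.pos) == 80
            assert sum(state.genotype_counts()) == 80

    def test_zero_dispersal_keeps_mother_positions(self):
        cfg = SimConfig(model=1, n=60, s=0.0, a=0.0, dispersal_sd=0.0,
                        competition_strength=0.0)
        rng = np.random.default_rng(0)
        state = init_population(cfg, rng)
        parents = {tuple(p) for p in state.pos}
        state = step_generation(state, cfg, rng)
        assert {tuple(p) for p in state.pos} <= parents

    def test_hardy_weinberg_at_birth_under_random_mating(self):
        cfg = SimConfig(model=1, n=2000, s=0.0, a=0.0, competition_strength=0.0,
                        mate_search_radius=1.5, init_B_frequency=0.4)
        rng = np.random.default_rng(2)
        state = init_population(cfg, rng)
        offspring = step_generation(state, cfg, rng)
        p = offspring.b_frequency
        n_aa, n_ab, n_bb = offspring.genotype_counts()
        expected_ab = 2 * p * (1 - p) * cfg.n
        assert abs(n_ab - expected_ab) < 4 * np.sqrt(cfg.n * 0.5)

    def test_model2_migration_rebalances_demes(self):
        cfg = SimConfig(model=2, n=100, s=0.0, m=0.5, generations=1)
        rng = np.random.default_rng(0)
        state = init_population(cfg, rng)
        state = step_generation(state, cfg, rng)
        assert len(state.pos) == 200
        assert abs(np.bincount(state.pop, minlength=2)[0] - 100) < 50


class TestRunAndSweep:
    def test_identical_seeds_identical_results(self):
        cfg = SimConfig(model=1, n=40, generations=30, iterations=2, seed=5,
                        s=0.2, a=0.5)
        r1, r2 = run(cfg), run(cfg)
        np.testing.assert_array_equal(r1.counts, r2.counts)
        for a, b in zip(r1.final_positions, r2.final_positions):
            np.testing.assert_array_equal(a, b)

    def test_zero_generations_reflects_initial_draw(self):
        cfg = SimConfig(model=1, n=50, generations=0, iterations=3, seed=0)
        res = run(cfg)
        assert (res.generations_run == 0).all()
        assert res.stable.all()  # p0 = 0.5 segregates at N = 50 almost surely

    def test_neutral_drift_loses_haplotype_over_ten_n_generations(self):
        cfg = SimConfig(model=1, n=100, generations=1000, iterations=10, seed=4,
                        s=0.05, a=0.05, record_every=100)
        res = run(cfg)
        assert res.stable.mean() <= 0.1

    def test_one_by_one_sweep_equals_bare_run(self):
        cfg = SimConfig(model=1, n=40, generations=20, iterations=2, seed=8)
        grid = sweep(cfg, [0.2], [0.5])
        assert grid.stable_fraction.shape == (1, 1)
        assert grid.results[0][0].stable_fraction == grid.stable_fraction[0, 0]

    def test_default_axes_shapes(self):
        assert set(DEFAULT_SWEEP_AXES[1]) == {"s", "a"}
        assert set(DEFAULT_SWEEP_AXES[2]) == {"s", "m"}

    def test_config_text_round_trip(self):
        cfg = SimConfig(model=2, n=123, m=0.01, inversion_interval=(10, 20))
        assert SimConfig.from_text(cfg.to_text()) == cfg

    @pytest.mark.parametrize(
        "bad", [dict(model=3), dict(a=1.0), dict(m=0.6), dict(s=-1.0),
                dict(inversion_interval=(50, 40))]
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad).validate()


class TestRatioDifference:
    def test_proportional_counts_give_zero(self):
        assert ratio_difference((74, 14, 56)) == pytest.approx(0.0)

    def test_no_heterozygotes(self):
        assert ratio_difference((50, 0, 50)) == pytest.approx(-7 / 72)

    def test_excess_heterozygotes(self):
        assert ratio_difference((25, 50, 25)) == pytest.approx(0.5 - 7 / 72)

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            ratio_difference((0, 0, 0))

    def test_empirical_reference(self):
        assert EMPIRICAL_GENOTYPE_COUNTS == (37, 7, 28)


class TestSpatialStratification:
    def test_hand_placed_ordering(self):
        pos = np.array([[0.5, 0.1], [0.5, 0.2], [0.5, 0.5], [0.5, 0.8], [0.5, 0.9]])
        geno = np.array([0, 0, 1, 2, 2])
        out = spatial_stratification(pos, geno, n_bootstrap=50, seed=0)
        assert out["stratified"] is True

    def test_single_class_is_undefined(self):
        pos = np.random.default_rng(0).random((10, 2))
        out = spatial_stratification(pos, np.zeros(10, dtype=int),
                                     n_bootstrap=10, seed=0)
        assert out["stratified"] is None

    def test_random_positions_rate_near_one_sixth(self, rng):
        hits = 0
        n_rep = 600
        for _ in range(n_rep):
            pos = rng.random((60, 2))
            geno = np.repeat([0, 1, 2], 20)
            out = spatial_stratification(pos, geno, n_bootstrap=2,
                                         seed=int(rng.integers(2**31 - 1)))
            hits += out["stratified"]
        assert hits / n_rep == pytest.approx(1 / 6, abs=3 * np.sqrt(5 / 36 / n_rep))
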