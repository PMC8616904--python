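"""Windowed-statistic tests against brute-force pairwise-difference oracles."""

import itertools

import numpy as np
import pytest

from supergene.io import GenotypeMatrix, VariantRecord, make_windows
from supergene.scan import (
    observed_heterozygosity,
    scan,
    site_dxy,
    site_pi,
    window_fst,
)


def _chromosomes(dosages):
    """Expand diploid dosages into per-chromosome alleles (missing dropped)."""
    alleles = []
    for d in dosages:
        if d < 0:
            continue
        alleles += [1] * d + [0] * (2 - d)
    return alleles


def brute_pi(dosages):
    """Mean pairwise difference among chromosomes of one group at one site."""
    chrom = _chromosomes(dosages)
    pairs = list(itertools.combinations(chrom, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def brute_dxy(dosages1, dosages2):
    """Mean pairwise difference across chromosomes of two groups at one site."""
    c1, c2 = _chromosomes(dosages1), _chromosomes(dosages2)
    pairs = [(a, b) for a in c1 for b in c2]
    return sum(a != b for a, b in pairs) / len(pairs)


def brute_hudson_fst(calls1, calls2):
    pis = [(brute_pi(c1) + brute_pi(c2)) / 2 for c1, c2 in zip(calls1.T, calls2.T)]
    dxys = [brute_dxy(c1, c2) for c1, c2 in zip(calls1.T, calls2.T)]
    return 1 - np.mean(pis) / np.mean(dxys)


class TestSitePi:
    @pytest.mark.parametrize(
        "dosages,expected",
        [
            ([0, 0, 0], 0.0),           # monomorphic
            ([1], 1.0),                 # 2 chromosomes, one of each allele
            ([1, 1], 2 / 3),            # 4 chromosomes, counts 2/2
            ([2, 1, 0, 1], None),       # checked against the oracle
            ([2, 0, -1, 1], None),      # missing call dropped
        ],
    )
    def test_matches_pairwise_enumeration(self, dosages, expected):
        got = site_pi(np.array(dosages).reshape(-1, 1))[0]
        want = brute_pi(dosages) if expected is None else expected
        assert got == pytest.approx(want, abs=1e-12)

    def test_all_missing_site_is_nan(self):
        assert np.isnan(site_pi(np.array([[-1], [-1]], dtype=int)))[0]


class TestSiteDxy:
    @pytest.mark.parametrize(
        "p1,p2,expected", [(1.0, 0.0, 1.0), (0.5, 0.5, 0.5), (0.2, 0.7, 0.62)]
    )
    def test_formula(self, p1, p2, expected):
        assert site_dxy(p1, p2) == pytest.approx(expected, abs=1e-12)

    def test_matches_pairwise_enumeration(self):
        g1, g2 = [0, 1, 2, 1], [2, 2, 1]
        p1 = sum(g1) / (2 * len(g1))
        p2 = sum(g2) / (2 * len(g2))
        assert site_dxy(p1, p2) == pytest.approx(brute_dxy(g1, g2), abs=1e-12)

    def test_self_dxy_equals_uncorrected_pi(self):
        # dxy(p, p) = 2p(1-p) = ((n-1)/n) * site_pi
        dosages = np.array([[0], [1], [2], [1], [2]])
        n = 2 * len(dosages)
        p = dosages.sum() / n
        assert site_dxy(p, p) == pytest.approx(
            (n - 1) / n * site_pi(dosages)[0], abs=1e-12
        )


class TestWindowFst:
    def test_same_population_near_zero(self):
        # two equal-sized samples drawn from one frequency spectrum: the
        # estimator's expectation is ~0 (sampling noise inflates dXY exactly
        # as it inflates within-group diversity)
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 3000)
        g1 = rng.binomial(2, p, size=(8, 3000))
        g2 = rng.binomial(2, p, size=(8, 3000))
        assert abs(window_fst(g1, g2)) < 0.02

    def test_fixed_differences_give_one(self):
        g1 = np.zeros((4, 3), dtype=int)
        g2 = np.full((4, 3), 2, dtype=int)
        assert window_fst(g1, g2) == pytest.approx(1.0, abs=1e-12)

    def test_five_site_toy_matches_brute_force(self):
        rng = np.random.default_rng(99)
        g1 = rng.integers(0, 3, size=(4, 5))
        g2 = rng.integers(0, 3, size=(3, 5))
        got = window_fst(g1, g2)
        assert got == pytest.approx(brute_hudson_fst(g1, g2), abs=1e-12)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(7)
        g1 = rng.integers(0, 3, size=(5, 6))
        g2 = rng.integers(0, 3, size=(5, 6))
        assert window_fst(2 - g1, 2 - g2) == pytest.approx(
            window_fst(g1, g2), abs=1e-12
        )


class TestObservedHet:
    def test_counted_by_hand(self):
        calls = np.array([[1, 0, 1, 2], [1, 1, 0, 0]], dtype=np.int8)
        gm = GenotypeMatrix(
            ["a", "b"],
            [VariantRecord("chr1", p, "A", "G") for p in (10, 20, 30, 40)],
            calls,
        )
        assert observed_heterozygosity(gm, ["a", "b"]) == pytest.approx(4 / 8)
        assert observed_heterozygosity(gm, ["a"], ("chr1", 0, 25)) == 0.5

    def test_extremes(self):
        calls = np.array([[0, 2], [2, 0]], dtype=np.int8)
        gm = GenotypeMatrix(
            ["a", "b"],
            [VariantRecord("chr1", p, "A", "G") for p in (10, 20)],
            calls,
        )
        assert observed_heterozygosity(gm, ["a", "b"]) == 0.0


class TestScan:
    def test_single_window_equals_per_site_computation(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(6, 8)).astype(np.int8)
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(6)],
            [VariantRecord("chr1", 10 + j, "A", "G") for j in range(8)],
            calls,
        )
        groups = {"g1": ["s0", "s1", "s2"], "g2": ["s3", "s4", "s5"]}
        table = scan(gm, groups, make_windows({"chr1": 100}, 100))
        assert len(table) == 1
        row = table.iloc[0]
        idx = [0, 1, 2], [3, 4, 5]
        assert row["pi_g1"] == pytest.approx(np.mean(site_pi(calls[idx[0]])))
        assert row["fst_g1_g2"] == pytest.approx(
            window_fst(calls[idx[0]], calls[idx[1]]), abs=1e-12
        )
        assert row["n_sites"] == 8

    def test_planted_inversion_fst_contrast(self, default_cohort, inversion_region):
        gm, _, truth = default_cohort
        geno = np.array(truth.genotype)
        groups = {
            "AA": [s for s, g in zip(gm.sample_ids, geno) if g == "AA"],
            "BB": [s for s, g in zip(gm.sample_ids, geno) if g == "BB"],
        }
        table = scan(gm, groups, make_windows({"chr1": 1_000_000}, 25_000))
        _, lo, hi = inversion_region
        inside = (table["start"] >= lo) & (table["end"] <= hi)
        fst_in = table.loc[inside, "fst_AA_BB"].mean()
        fst_out = table.loc[~inside, "fst_AA_BB"].dropna().mean()
        assert fst_in > 5 * abs(fst_out)
        # homozygote pi depressed relative to heterozygotes inside the inversion
        ab = [s for s, g in zip(gm.sample_ids, geno) if g == "AB"]
        table2 = scan(
            gm, {"AA": groups["AA"], "AB": ab},
            make_windows({"chr1": 1_000_000}, 25_000),
        )
        assert (
            table2.loc[inside, "pi_AA"].mean() < table2.loc[inside, "pi_AB"].mean()
        )

    def test_divergence_monotonicity(self):
        from supergene.synth import CohortConfig, generate_cohort

        means = []
        for d in (0.2, 0.5, 0.9):
            gm, _, truth = generate_cohort(
                CohortConfig(seed=11, haplotype_divergence=d,
                             n_background_snps=300, n_inversion_snps=150)
            )
            geno = np.array(truth.genotype)
            groups = {
                "AA": [s for s, g in zip(gm.sample_ids, geno) if g == "AA"],
                "BB": [s for s, g in zip(gm.sample_ids, geno) if g == "BB"],
            }
            table = scan(gm, groups, make_windows({"chr1": 1_000_000}, 200_000))
            inside = (table["start"] >= 400_000) & (table["end"] <= 600_000)
            means.append(table.loc[inside, "fst_AA_BB"].mean())
        assert means[0] < means[1] < means[2]

    def test_empty_group_is_error(self, default_cohort):
        gm, _, _ = default_cohort
        with pytest.raises(ValueError, match="empty"):
            scan(gm, {"g1": [], "g2": gm.sample_ids},
                 make_windows({"chr1": 1_000_000}, 500_000))

    def test_overlapping_groups_is_error(self, default_cohort):
        gm, _, _ = default_cohort
        with pytest.raises(ValueError, match="overlap"):
            scan(gm, {"g1": gm.sample_ids[:5], "g2": gm.sample_ids[4:8]},
                 make_windows({"chr1": 1_000_000}, 500_000))
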