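"""Spatial forward-time models of inversion-polymorphism maintenance.

Two individual-based models ask under what combinations of spatially
varying selection, assortative mating, and migration a chromosomal
inversion persists as a balanced polymorphism rather than drifting to
fixation. Individuals are diploid for a 100-kb chromosome carrying a
50-kb inversion whose B-haplotype dosage g in {0,1,2} determines an
additive phenotype phi = g/2. Fitness declines linearly with the mismatch
between phi and the individual's position along the selection gradient
(the y-axis), scaled by the selection strength s.

Model 1: one population on the unit square, with assortative mating of
strength ``a`` (mate weight proportional to (1-a)^|dg|) and local
competition (fitness divided by 1 + c * neighbors within a radius).

Model 2: two populations on separate unit squares with the selection
gradient continued across them (population 0 favors low phenotypes,
population 1 high), random mating within populations, and offspring
migration between them with probability ``m`` per generation.

Generations are non-overlapping and hermaphroditic: every generation each
population produces a fixed number of offspring by sampling mothers in
proportion to fitness; each mother picks a mate among neighbors within
``mate_search_radius``. Gametes recombine at Poisson-distributed
crossovers, with crossovers inside the inversion rejected in inversion
heterozygotes (recombination suppression); neutral loci mutate at a
per-locus rate. Once one inversion haplotype is lost the outcome is
decided (no new inversion mutations arise), so the iteration stops at the
absorption generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "SimState",
    "SimResult",
    "SweepGrid",
    "init_population",
    "fitness",
    "choose_mates",
    "recombine",
    "step_generation",
    "run",
    "sweep",
    "ratio_difference",
    "spatial_stratification",
    "EMPIRICAL_GENOTYPE_COUNTS",
]

#: Observed inversion-genotype counts (AA, AB, BB) in the sampled cohort.
EMPIRICAL_GENOTYPE_COUNTS = (37, 7, 28)

#: Default sweep axes per model. The selection grids sit where the regimes of
#: the two models separate at desk scale (see docs/methods.md): weak
#: assortment or high migration drifting to loss, strong assortment or low
#: migration holding a low-heterozygote balanced polymorphism.
DEFAULT_SWEEP_AXES = {
    1: {"s": (0.02, 0.05, 0.10), "a": (0.05, 0.5, 0.95)},
    2: {"s": (0.05, 0.10, 0.15), "m": (0.25, 0.01, 0.0005)},
}


@dataclass
class SimConfig:
    """Simulation parameters. Defaults are the full-scale study conditions
    (1000 diploids, 10,000 generations, 50 iterations); tests and quick
    explorations pass scaled-down values explicitly."""

    model: int = 1
    n: int = 1000                     # diploid individuals per population
    generations: int = 10_000
    iterations: int = 50
    s: float = 0.5                    # selection strength
    a: float = 0.5                    # assortative-mating strength (model 1)
    m: float = 0.005                  # migration probability (model 2)
    competition_radius: float = 0.05
    competition_strength: float = 1.0
    mate_search_radius: float = 0.5
    dispersal_sd: float = 0.03
    chromosome_length: int = 100_000
    inversion_interval: tuple[int, int] = (25_000, 75_000)
    n_neutral_loci: int = 20
    mutation_rate: float = 1e-5       # per neutral locus per gamete
    recombination_rate: float = 1e-6  # crossovers per bp per gamete
    init_B_frequency: float = 0.5
    record_every: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if self.n < 2:
            raise ValueError("need N >= 2")
        if not 0 <= self.a < 1:
            raise ValueError("assortative-mating strength a must be in [0, 1)")
        if not 0 <= self.m <= 0.5:
            raise ValueError("migration probability m must be in [0, 0.5]")
        for name in ("s", "competition_radius", "competition_strength",
                     "mate_search_radius", "dispersal_sd", "mutation_rate",
                     "recombination_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.inversion_interval
        if not 0 <= lo < hi <= self.chromosome_length:
            raise ValueError("inversion_interval must lie within the chromosome")
        if not 0 <= self.init_B_frequency <= 1:
            raise ValueError("init_B_frequency must be in [0, 1]")

    def to_text(self) -> str:
        """Flat key = value block, echoed into simulation outputs."""
        lines = []
        for key, val in vars(self).items():
            lines.append(f"{key} = {val}")
        return "\n".join(lines)

    @classmethod
    def from_text(cls, text: str) -> "SimConfig":
        import ast

        kwargs = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kwargs[key.strip()] = ast.literal_eval(val.strip())
        return cls(**kwargs)


@dataclass
class SimState:
    """Mutable per-iteration state: positions, populations, haplotypes."""

    pos: np.ndarray          # (M, 2) in [0,1]^2
    pop: np.ndarray          # (M,) population index (all zero in model 1)
    inv: np.ndarray          # (M, 2) inversion allele per haplotype, 0=A 1=B
    neut: np.ndarray         # (M, 2, L) neutral alleles
    locus_pos: np.ndarray    # (L,) bp positions of neutral loci

    @property
    def dosage(self) -> np.ndarray:
        # signed dtype: dosage differences are taken in mate choice
        return self.inv.sum(axis=1, dtype=np.int64)

    @property
    def b_frequency(self) -> float:
        return float(self.inv.mean())

    def genotype_counts(self) -> tuple[int, int, int]:
        g = self.dosage
        return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


@dataclass
class SimResult:
    """Per-iteration outcomes of :func:`run`."""

    config: SimConfig
    stable: np.ndarray                      # (iterations,) bool
    counts: np.ndarray                      # (iterations, 3) final AA/AB/BB
    generations_run: np.ndarray             # (iterations,)
    trajectories: list[np.ndarray] = field(repr=False)   # B-frequency per record
    final_positions: list[np.ndarray] = field(repr=False)
    final_genotypes: list[np.ndarray] = field(repr=False)
    final_pops: list[np.ndarray] = field(repr=False)
    final_states: list[SimState] = field(repr=False)

    @property
    def stable_fraction(self) -> float:
        return float(self.stable.mean())

    def mean_stable_counts(self) -> np.ndarray | None:
        """Mean final genotype counts over stable iterations (None if none)."""
        if not self.stable.any():
            return None
        return self.counts[self.stable].mean(axis=0)

    def summary(self) -> str:
        lines = [
            f"model {self.config.model}: s={self.config.s}, "
            + (f"a={self.config.a}" if self.config.model == 1 else f"m={self.config.m}"),
            f"  {int(self.stable.sum())}/{len(self.stable)} iterations kept both haplotypes",
        ]
        mc = self.mean_stable_counts()
        if mc is not None:
            lines.append(
                f"  mean stable genotype counts AA/AB/BB: "
                f"{mc[0]:.1f}/{mc[1]:.1f}/{mc[2]:.1f}"
            )
            lines.append(
                f"  ratio difference vs empirical {EMPIRICAL_GENOTYPE_COUNTS}: "
                f"{ratio_difference(tuple(mc)):+.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def init_population(config: SimConfig, rng: np.random.Generator) -> SimState:
    """Uniformly placed individuals with Bernoulli(init_B_frequency) haplotypes.

    Model 2 initializes N individuals in each of the two populations.
    Neutral loci start monomorphic (allele 0) on an evenly spaced map.
    """
    config.validate()
    n_pop = 1 if config.model == 1 else 2
    m = config.n * n_pop
    pos = rng.random((m, 2))
    pop = np.repeat(np.arange(n_pop), config.n)
    inv = (rng.random((m, 2)) < config.init_B_frequency).astype(np.uint8)
    neut = np.zeros((m, 2, config.n_neutral_loci), dtype=np.uint8)
    locus_pos = (
        np.linspace(0, config.chromosome_length, config.n_neutral_loci, endpoint=False)
        + config.chromosome_length / (2 * max(config.n_neutral_loci, 1))
    )
    return SimState(pos, pop, inv, neut, locus_pos)


def _gradient_position(state: SimState, config: SimConfig) -> np.ndarray:
    """Position along the selection gradient, mapped to [0, 1].

    Model 1 uses y directly; model 2 continues the gradient across the two
    populations (population 0 spans [0, 0.5], population 1 spans [0.5, 1]).
    """
    if config.model == 1:
        return state.pos[:, 1]
    return (state.pos[:, 1] + state.pop) / 2.0


def fitness(
    state: SimState, config: SimConfig, dist2: np.ndarray | None = None
) -> np.ndarray:
    """Per-individual fitness, >= 0.

    w = max(0, 1 - s * |y - phi|) with phi = dosage/2, divided in model 1
    by (1 + c * n_neighbors within the competition radius).
    """
    phi = state.dosage / 2.0
    y = _gradient_position(state, config)
    w = np.clip(1.0 - config.s * np.abs(y - phi), 0.0, None)
    if config.model == 1 and config.competition_strength > 0:
        if dist2 is None:
            dist2 = _squared_distances(state.pos)
        n_nb = (dist2 <= config.competition_radius**2).sum(axis=1) - 1  # minus self
        w = w / (1.0 + config.competition_strength * n_nb)
    return w


def _squared_distances(pos: np.ndarray) -> np.ndarray:
    px, py = pos[:, 0], pos[:, 1]
    return (px[:, None] - px[None, :]) ** 2 + (py[:, None] - py[None, :]) ** 2


def choose_mates(
    dosage: np.ndarray,
    config: SimConfig,
    w: np.ndarray,
    in_range: np.ndarray,
    mothers: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized mate choice for an array of mother indices (one block).

    Each mother samples one mate among candidates within
    ``mate_search_radius`` (excluding herself), with weight proportional to
    the candidate's fitness times (1-a)^|dg| in model 1. Mothers were
    pre-filtered to have at least one candidate. Indices are local to the
    block; ``in_range`` is the block's boolean candidacy matrix.
    """
    m = len(dosage)
    weight = in_range[mothers] * w[None, :]
    if config.model == 1 and config.a > 0:
        dg = np.abs(dosage[mothers][:, None] - dosage[None, :])
        weight = weight * (1.0 - config.a) ** dg
    totals = weight.sum(axis=1)
    # fall back to uniform choice among candidates if all weights vanish
    dead = totals <= 0
    if dead.any():
        weight[dead] = in_range[mothers[dead]].astype(float)
        totals = weight.sum(axis=1)
    cum = np.cumsum(weight, axis=1)
    u = rng.random(len(mothers)) * totals
    return (cum < u[:, None]).sum(axis=1).clip(max=m - 1)


def recombine(
    state: SimState,
    parents: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete per parent index: (inversion allele, neutral haplotype).

    Crossover counts are Poisson(recombination_rate * chromosome_length)
    with uniform positions; any crossover inside the inversion interval is
    discarded when the parent is inversion-heterozygous. The inversion
    allele travels with the haplotype covering the inversion midpoint.
    Neutral alleles then mutate (0<->1 flip) at ``mutation_rate``.
    """
    k = len(parents)
    length = config.chromosome_length
    lam = config.recombination_rate * length
    start = rng.integers(2, size=k)
    n_cross = rng.poisson(lam, size=k) if lam > 0 else np.zeros(k, dtype=int)

    inv_par = state.inv[parents]          # (k, 2)
    neut_par = state.neut[parents]        # (k, 2, L)
    het = inv_par[:, 0] != inv_par[:, 1]
    lo, hi = config.inversion_interval
    mid = (lo + hi) / 2.0
    locus_pos = state.locus_pos
    n_loci = locus_pos.size

    rows = np.arange(k)
    gam_inv = inv_par[rows, start].copy()
    gam_neut = neut_par[rows, start].copy()

    # single-crossover gametes (the common case at low map length), vectorized
    ones = np.flatnonzero(n_cross == 1)
    if ones.size:
        cuts = rng.random(ones.size) * length
        keep = ~(het[ones] & (cuts >= lo) & (cuts < hi))  # rejected in AB parents
        idx, cuts = ones[keep], cuts[keep]
        if idx.size:
            hap_at = (start[idx][:, None] + (locus_pos[None, :] >= cuts[:, None])) % 2
            gam_neut[idx] = neut_par[idx[:, None], hap_at, np.arange(n_loci)[None, :]]
            gam_inv[idx] = inv_par[idx, (start[idx] + (mid >= cuts)) % 2]

    for i in np.flatnonzero(n_cross > 1):
        cuts = np.sort(rng.random(n_cross[i]) * length)
        if het[i]:
            cuts = cuts[(cuts < lo) | (cuts >= hi)]
        if cuts.size == 0:
            continue
        # haplotype index at each coordinate: start + number of cuts passed
        hap_at = (start[i] + np.searchsorted(cuts, locus_pos, side="right")) % 2
        gam_neut[i] = neut_par[i, hap_at, np.arange(n_loci)]
        gam_inv[i] = inv_par[i, (start[i] + np.searchsorted(cuts, mid)) % 2]

    if config.mutation_rate > 0 and locus_pos.size:
        flips = rng.random(gam_neut.shape) < config.mutation_rate
        gam_neut = gam_neut ^ flips.astype(np.uint8)
    return gam_inv, gam_neut


class ExtinctionError(RuntimeError):
    """No reproducing pair could be formed; the iteration terminates."""


def step_generation(
    state: SimState, config: SimConfig, rng: np.random.Generator
) -> SimState:
    """Advance one non-overlapping generation; population sizes are conserved.

    Each population produces exactly N offspring from mothers sampled in
    proportion to fitness among individuals with at least one mate
    candidate in range. Offspring disperse from the mother's position with
    an isotropic Gaussian kernel, reflected at the habitat boundary; in
    model 2 each offspring then migrates with probability m, its position
    redrawn uniformly in the destination population.
    """
    n_pop = 1 if config.model == 1 else 2
    r2_mate = config.mate_search_radius**2
    mothers_parts, fathers_parts = [], []
    for p in range(n_pop):
        members = np.flatnonzero(state.pop == p)
        for attempt in range(2):
            if members.size == 0:
                # deme empty (or no pair in range): recolonize from the metapopulation
                members = np.arange(len(state.pop))
            pos = state.pos[members]
            dist2 = _squared_distances(pos)
            if config.model == 1:
                w = fitness(state, config, dist2)[members]
            else:
                w = fitness(state, config)[members]
            in_range = dist2 <= r2_mate
            np.fill_diagonal(in_range, False)
            local = np.flatnonzero(in_range.any(axis=1))
            if local.size or members.size == len(state.pop):
                break
            members = np.arange(0)  # retry over the whole metapopulation
        if local.size == 0:
            raise ExtinctionError("no individual has a mate candidate in range")
        probs = w[local]
        tot = probs.sum()
        probs = probs / tot if tot > 0 else np.full(local.size, 1 / local.size)
        mothers_local = rng.choice(local, size=config.n, p=probs)
        fathers_local = choose_mates(
            state.dosage[members], config, w, in_range, mothers_local, rng
        )
        mothers_parts.append(members[mothers_local])
        fathers_parts.append(members[fathers_local])
    mothers = np.concatenate(mothers_parts)
    fathers = np.concatenate(fathers_parts)

    inv_a, neut_a = recombine(state, mothers, config, rng)
    inv_b, neut_b = recombine(state, fathers, config, rng)
    inv = np.stack([inv_a, inv_b], axis=1)
    neut = np.stack([neut_a, neut_b], axis=1)

    pos = state.pos[mothers] + rng.normal(0, config.dispersal_sd, size=(len(mothers), 2))
    pos = _reflect(pos)
    pop = state.pop[mothers].copy()
    if config.model == 2 and config.m > 0:
        migrate = rng.random(len(pop)) < config.m
        pop[migrate] = 1 - pop[migrate]
        pos[migrate] = rng.random((int(migrate.sum()), 2))
    return SimState(pos, pop, inv, neut, state.locus_pos)


def _reflect(pos: np.ndarray) -> np.ndarray:
    """Reflect coordinates into [0, 1] (handles multiple bounces)."""
    pos = np.abs(pos)
    pos = np.mod(pos, 2.0)
    return np.where(pos > 1.0, 2.0 - pos, pos)


# ---------------------------------------------------------------------------
# Iterated runs and sweeps
# ---------------------------------------------------------------------------


def _run_one(config: SimConfig, seed_seq: np.random.SeedSequence):
    rng = np.random.default_rng(seed_seq)
    state = init_population(config, rng)
    traj = [state.b_frequency]
    gen = 0
    terminated = False
    for gen in range(1, config.generations + 1):
        try:
            state = step_generation(state, config, rng)
        except ExtinctionError:
            terminated = True
            break
        if gen % config.record_every == 0:
            traj.append(state.b_frequency)
        freq = state.b_frequency
        if freq == 0.0 or freq == 1.0:
            break  # one haplotype lost: outcome decided
    traj.append(state.b_frequency)
    stable = (not terminated) and 0.0 < state.b_frequency < 1.0
    return state, np.array(traj), gen, stable


def run(config: SimConfig) -> SimResult:
    """Run ``config.iterations`` independent iterations of the model.

    Iterations use independent child seeds spawned from ``config.seed``. An
    iteration is stable if both inversion haplotypes are still segregating
    at its final generation.
    """
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(config.iterations)
    stable = np.zeros(config.iterations, dtype=bool)
    counts = np.zeros((config.iterations, 3), dtype=int)
    gens = np.zeros(config.iterations, dtype=int)
    trajectories, positions, genotypes, pops, states = [], [], [], [], []
    for i, ss in enumerate(seeds):
        state, traj, gen, ok = _run_one(config, ss)
        stable[i] = ok
        counts[i] = state.genotype_counts()
        gens[i] = gen
        trajectories.append(traj)
        positions.append(state.pos.copy())
        genotypes.append(state.dosage.copy())
        pops.append(state.pop.copy())
        states.append(state)
    return SimResult(
        config=config,
        stable=stable,
        counts=counts,
        generations_run=gens,
        trajectories=trajectories,
        final_positions=positions,
        final_genotypes=genotypes,
        final_pops=pops,
        final_states=states,
    )


@dataclass
class SweepGrid:
    """Grid of run() outcomes over s x (a or m)."""

    s_values: list[float]
    second_axis: list[float]
    second_axis_name: str
    stable_fraction: np.ndarray          # (n_s, n_second)
    mean_counts: np.ndarray              # (n_s, n_second, 3), NaN when unstable
    ratio_score: np.ndarray              # (n_s, n_second), NaN when unstable
    results: list[list[SimResult]] = field(repr=False)

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, s in enumerate(self.s_values):
            for j, v in enumerate(self.second_axis):
                rows.append(
                    {
                        "s": s,
                        self.second_axis_name: v,
                        "stable_fraction": self.stable_fraction[i, j],
                        "mean_AA": self.mean_counts[i, j, 0],
                        "mean_AB": self.mean_counts[i, j, 1],
                        "mean_BB": self.mean_counts[i, j, 2],
                        "ratio_difference": self.ratio_score[i, j],
                    }
                )
        return pd.DataFrame(rows)


def sweep(
    config: SimConfig,
    s_values: Sequence[float],
    second_axis_values: Sequence[float],
) -> SweepGrid:
    """run() at every grid cell of selection x (assortment or migration).

    The second axis is ``a`` for model 1 and ``m`` for model 2. Cells where
    no iteration keeps both haplotypes have NaN mean counts and score (the
    'white' cells of a stability heat map).
    """
    if not len(s_values) or not len(second_axis_values):
        raise ValueError("sweep axes must be non-empty")
    axis_name = "a" if config.model == 1 else "m"
    n_s, n_2 = len(s_values), len(second_axis_values)
    seeds = np.random.SeedSequence(config.seed).spawn(n_s * n_2)
    stable_fraction = np.zeros((n_s, n_2))
    mean_counts = np.full((n_s, n_2, 3), np.nan)
    score = np.full((n_s, n_2), np.nan)
    results: list[list[SimResult]] = []
    for i, s in enumerate(s_values):
        row = []
        for j, v in enumerate(second_axis_values):
            cell_seed = int(seeds[i * n_2 + j].generate_state(1)[0] % (2**31 - 1))
            cell = replace(config, s=float(s), seed=cell_seed, **{axis_name: float(v)})
            res = run(cell)
            stable_fraction[i, j] = res.stable_fraction
            mc = res.mean_stable_counts()
            if mc is not None:
                mean_counts[i, j] = mc
                score[i, j] = ratio_difference(tuple(mc))
            row.append(res)
        results.append(row)
    return SweepGrid(
        list(map(float, s_values)),
        list(map(float, second_axis_values)),
        axis_name,
        stable_fraction,
        mean_counts,
        score,
        results,
    )


def ratio_difference(
    sim_counts: Sequence[float],
    empirical_counts: Sequence[float] = EMPIRICAL_GENOTYPE_COUNTS,
) -> float:
    """Signed difference in heterozygote proportion, simulated minus empirical.

    Positive values mean the simulation produced proportionally more AB
    individuals than observed.
    """
    sim = np.asarray(sim_counts, dtype=float)
    emp = np.asarray(empirical_counts, dtype=float)
    if (sim < 0).any() or (emp < 0).any():
        raise ValueError("genotype counts must be non-negative")
    if sim.sum() == 0 or emp.sum() == 0:
        raise ValueError("genotype counts must have a nonzero total")
    return float(sim[1] / sim.sum() - emp[1] / emp.sum())


def spatial_stratification(
    positions: np.ndarray,
    genotypes: np.ndarray,
    pops: np.ndarray | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> dict:
    """Mean gradient position per genotype, with a stratification flag.

    Returns per-genotype mean y (continued across populations when ``pops``
    is given) with bootstrap CIs; ``stratified`` is True iff the means of
    the genotype classes present are strictly increasing AA < AB < BB, and
    None when fewer than two classes are present.
    """
    positions = np.asarray(positions, dtype=float)
    genotypes = np.asarray(genotypes)
    y = positions[:, 1] if pops is None else (positions[:, 1] + np.asarray(pops)) / 2.0
    rng = np.random.default_rng(seed)
    means, cis = {}, {}
    for g in (0, 1, 2):
        vals = y[genotypes == g]
        if vals.size == 0:
            continue
        means[g] = float(vals.mean())
        boots = np.array(
            [rng.choice(vals, size=vals.size, replace=True).mean()
             for _ in range(n_bootstrap)]
        )
        cis[g] = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    present = sorted(means)
    if len(present) < 2:
        flag = None
    else:
        vals = [means[g] for g in present]
        flag = bool(all(vals[i] < vals[i + 1] for i in range(len(vals) - 1)))
    return {"mean_y": means, "ci": cis, "stratified": flag}
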