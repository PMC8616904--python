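"""Synthetic genotype cohorts and window trees with planted inversion structure.

The generator emulates the statistical signature of a polymorphic
chromosomal-inversion supergene in a cohort of diploid genomes: a
genome-wide background homogenized by gene flow, one localized region
where two non-recombining haplotype pools diverge (producing three PCA
clusters and doubled heterozygosity in the middle cluster), a small set
of modifier loci differentiating one ecotype, an additive phenotype on
inversion dosage, and a latitudinal cline in the B haplotype.

Defaults mirror the observed cohort: 72 samples with inversion genotype
counts 37 AA : 7 AB : 28 BB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import GENOTYPES, GenotypeMatrix, SampleMetadata, VariantRecord

import pandas as pd


class ConfigError(ValueError):
    """Raised for infeasible cohort configurations."""


@dataclass
class CohortConfig:
    """Parameters for :func:`generate_cohort`.

    ``haplotype_divergence`` (d) is the per-site allele-frequency difference
    between the A and B haplotype pools at inversion sites; d = 1 means every
    inversion site is a fixed difference.
    """

    n_samples: dict[str, int] = field(
        default_factory=lambda: {"common": 25, "hoary": 33, "lesser": 14}
    )
    genotype_frequencies: tuple[float, float, float] = (37 / 72, 7 / 72, 28 / 72)
    n_background_snps: int = 2000
    n_inversion_snps: int = 500
    n_modifier_snps: int = 20
    chrom_length: int = 1_000_000
    inversion_interval: tuple[int, int] = (400_000, 600_000)
    haplotype_divergence: float = 0.8
    modifier_effect: float = 0.8
    beta_inversion: float = 1.0
    beta_modifier: float = 0.25
    phenotype_noise_sd: float = 0.25
    latitude_model: tuple[float, float, float] = (55.0, 5.0, 3.0)
    background_beta: tuple[float, float] = (0.8, 0.8)
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_samples.values()) or sum(self.n_samples.values()) < 2:
            raise ConfigError("need at least two samples")
        if not math.isclose(sum(self.genotype_frequencies), 1.0, abs_tol=1e-9):
            raise ConfigError("genotype_frequencies must sum to 1")
        if min(self.genotype_frequencies) < 0:
            raise ConfigError("genotype_frequencies must be non-negative")
        s, e = self.inversion_interval
        if not (0 <= s < e <= self.chrom_length):
            raise ConfigError("inversion_interval must lie within the chromosome")
        if not 0 <= self.haplotype_divergence <= 1:
            raise ConfigError("haplotype_divergence must be in [0, 1]")
        if self.n_inversion_snps == 0 and self.haplotype_divergence > 0:
            raise ConfigError("nonzero divergence requested with zero inversion SNPs")


@dataclass
class CohortTruth:
    """Generator ground truth used as the test oracle for downstream stages."""

    genotype: list[str]          # per-sample true inversion genotype
    region: list[str]            # per-variant label: background / inversion / modifier
    phenotype: np.ndarray        # per-sample phenotype value

    def to_tsv(self, sample_path, site_path, sample_ids, variants) -> None:
        pd.DataFrame(
            {"sample_id": sample_ids, "genotype": self.genotype, "phenotype": self.phenotype}
        ).to_csv(sample_path, sep="\t", index=False)
        pd.DataFrame(
            {
                "chrom": [v.chrom for v in variants],
                "pos": [v.pos for v in variants],
                "region": self.region,
            }
        ).to_csv(site_path, sep="\t", index=False)


def _exact_counts(total: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of `total` into len(fractions) classes."""
    raw = [f * total for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[GenotypeMatrix, SampleMetadata, CohortTruth]:
    """Simulate a diploid cohort with a planted inversion polymorphism.

    Background sites share one allele-frequency spectrum across all samples
    (Beta-distributed, no population structure). Inversion sites are drawn
    per haplotype pool with per-site frequency difference d; each individual
    carries two independently drawn haplotypes according to its genotype,
    so recombination suppression is implicit. Modifier sites differentiate
    the lesser-ecotype subsample. Phenotype is additive in B dosage plus a
    modifier score and Gaussian noise; latitude is Gaussian around a
    genotype-shifted mean.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    sample_ids, ecotypes = [], []
    for eco in sorted(config.n_samples):
        for i in range(config.n_samples[eco]):
            sample_ids.append(f"{eco}_{i}")
            ecotypes.append(eco)
    n = len(sample_ids)

    counts = _exact_counts(n, config.genotype_frequencies)
    genotype = np.repeat(np.array(GENOTYPES, dtype=object), counts)
    rng.shuffle(genotype)
    dosage = np.array([("AA", "AB", "BB").index(g) for g in genotype])

    inv_start, inv_end = config.inversion_interval
    pos_bg = _distinct_positions(
        rng, config.n_background_snps, config.chrom_length, exclude=(inv_start, inv_end)
    )
    pos_inv = _distinct_positions(
        rng, config.n_inversion_snps, inv_end - inv_start, offset=inv_start
    )

    a, b = config.background_beta
    p_bg = rng.beta(a, b, size=config.n_background_snps)
    calls_bg = rng.binomial(2, p_bg[None, :], size=(n, config.n_background_snps))

    # Inversion haplotype pools: per-site frequencies differing by exactly d,
    # with the higher-frequency pool chosen at random per site.
    d = config.haplotype_divergence
    m_inv = config.n_inversion_snps
    low = rng.uniform(0, 1 - d, size=m_inv)
    b_is_high = rng.random(m_inv) < 0.5
    p_pool_a = np.where(b_is_high, low, low + d)
    p_pool_b = np.where(b_is_high, low + d, low)
    hap1_p = np.where(dosage[:, None] >= 1, p_pool_b[None, :], p_pool_a[None, :])
    hap2_p = np.where(dosage[:, None] == 2, p_pool_b[None, :], p_pool_a[None, :])
    calls_inv = (rng.random((n, m_inv)) < hap1_p).astype(int) + (
        rng.random((n, m_inv)) < hap2_p
    ).astype(int)

    # Modifier sites on a second chromosome, differentiating the lesser ecotype.
    m_mod = config.n_modifier_snps
    pos_mod = _distinct_positions(rng, m_mod, config.chrom_length)
    low_m = rng.uniform(0, 1 - config.modifier_effect, size=m_mod)
    p_lesser = low_m + config.modifier_effect
    is_lesser = np.array([e == "lesser" for e in ecotypes])
    p_mod = np.where(is_lesser[:, None], p_lesser[None, :], low_m[None, :])
    calls_mod = rng.binomial(2, p_mod)

    variants = (
        [VariantRecord("chr1", int(p) + 1, "A", "G") for p in sorted(pos_bg + pos_inv)]
        + [VariantRecord("chr2", int(p) + 1, "A", "G") for p in sorted(pos_mod)]
    )
    chr1_pos = sorted(pos_bg + pos_inv)
    region_chr1 = [
        "inversion" if inv_start <= p < inv_end else "background" for p in chr1_pos
    ]
    region = region_chr1 + ["modifier"] * m_mod

    calls_chr1 = np.empty((n, len(chr1_pos)), dtype=np.int8)
    order = np.argsort(np.concatenate([pos_bg, pos_inv]))
    calls_chr1[:, :] = np.concatenate([calls_bg, calls_inv], axis=1)[:, order]
    calls_mod = calls_mod[:, np.argsort(pos_mod)]
    calls = np.concatenate([calls_chr1, calls_mod.astype(np.int8)], axis=1)
    gm = GenotypeMatrix(sample_ids, variants, calls)

    modifier_score = (
        calls_mod.mean(axis=1) - 1.0 if m_mod else np.zeros(n)
    )
    phenotype = (
        dosage * config.beta_inversion
        + config.beta_modifier * modifier_score
        + rng.normal(0, config.phenotype_noise_sd, size=n)
    )

    base, shift, lat_sd = config.latitude_model
    latitude = np.clip(base + dosage * shift + rng.normal(0, lat_sd, size=n), -90, 90)
    season = rng.choice(["breeding", "nonbreeding"], size=n, p=[0.65, 0.35])

    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "ecotype": ecotypes,
                "latitude": latitude,
                "season": season,
                "inversion_genotype": genotype,
            }
        )
    )
    truth = CohortTruth(list(genotype), region, phenotype)
    return gm, metadata, truth


def _distinct_positions(rng, k, span, offset=0, exclude=None):
    """k distinct 0-based positions in [offset, offset+span), avoiding `exclude`."""
    chosen: set[int] = set()
    while len(chosen) < k:
        draw = rng.integers(0, span, size=k - len(chosen)) + offset
        for p in draw:
            p = int(p)
            if exclude is not None and exclude[0] <= p < exclude[1]:
                continue
            chosen.add(p)
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Window trees
# ---------------------------------------------------------------------------


def generate_window_trees(
    n_windows: int,
    group_sizes: dict[str, int],
    concordance_mix: dict[str, float],
    scatter: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Generate newick trees whose taxon-level topology follows a stated mix.

    Each window draws a taxon-level topology (a newick string over group
    names) with the stated probability, then expands every group leaf into a
    clade of ``group_name_index`` tips (a random binary subtree). With
    ``scatter`` > 0, each tip is detached and regrafted onto a uniformly
    random edge with that probability, degrading within-group monophyly.
    """
    import dendropy

    if len(group_sizes) < 2 or min(group_sizes.values()) < 1:
        raise ValueError("need >= 2 groups with >= 1 tip each")
    probs = np.array(list(concordance_mix.values()), dtype=float)
    if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("concordance_mix must sum to 1")
    rng = np.random.default_rng(seed)
    topologies = list(concordance_mix.keys())
    trees: list[str] = []
    for _ in range(n_windows):
        topo = topologies[rng.choice(len(topologies), p=probs)]
        tree = dendropy.Tree.get(data=topo if topo.endswith(";") else topo + ";",
                                 schema="newick")
        _expand_groups(tree, group_sizes, rng)
        if scatter > 0:
            _scatter_tips(tree, scatter, rng)
        trees.append(tree.as_string(schema="newick", suppress_rooting=True).strip())
    return trees


def _random_binary_subtree(labels, rng, namespace):
    import dendropy

    nodes = []
    for lab in labels:
        node = dendropy.Node(edge_length=1.0)
        node.taxon = namespace.require_taxon(label=lab)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        parent = dendropy.Node(edge_length=1.0)
        for k in sorted((int(i), int(j)), reverse=True):
            parent.add_child(nodes.pop(k))
        nodes.append(parent)
    return nodes[0]


def _expand_groups(tree, group_sizes, rng) -> None:
    for leaf in list(tree.leaf_node_iter()):
        group = leaf.taxon.label
        size = group_sizes[group]
        labels = [f"{group}_{i}" for i in range(size)]
        sub = _random_binary_subtree(labels, rng, tree.taxon_namespace)
        parent = leaf.parent_node
        if parent is None:  # degenerate two-leaf tree rooted at leaf
            continue
        parent.remove_child(leaf)
        parent.add_child(sub)
    tree.taxon_namespace.clear()
    tree.update_taxon_namespace()


def _scatter_tips(tree, scatter, rng) -> None:
    leaves = list(tree.leaf_node_iter())
    for leaf in leaves:
        if rng.random() >= scatter:
            continue
        parent = leaf.parent_node
        if parent is None or len(tree.leaf_nodes()) < 4:
            continue
        # detach the leaf, suppress the degree-2 node left behind
        parent.remove_child(leaf)
        if len(parent.child_nodes()) == 1 and parent.parent_node is not None:
            only = parent.child_nodes()[0]
            grand = parent.parent_node
            grand.remove_child(parent)
            grand.add_child(only)
        elif len(parent.child_nodes()) == 1:
            # parent is the root: promote the single child to root
            tree.seed_node = parent.child_nodes()[0]
            tree.seed_node.parent_node = None
        # regraft on a uniformly chosen edge
        edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
        edge = edges[rng.choice(len(edges))]
        head = edge.head_node
        tail = edge.tail_node
        mid = head.__class__(edge_length=1.0)
        tail.remove_child(head)
        tail.add_child(mid)
        mid.add_child(head)
        mid.add_child(leaf)
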