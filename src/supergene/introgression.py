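"""ABBA-BABA D with block jackknife, and topology weighting of window trees.

The D statistic measures the imbalance of discordant site patterns on a
four-taxon tree (((P1,P2),P3),P4) from population allele frequencies:

    D = sum[(1-p1) p2 p3 (1-p4) - p1 (1-p2) p3 (1-p4)]
        / sum[(1-p1) p2 p3 (1-p4) + p1 (1-p2) p3 (1-p4)]

Under incomplete lineage sorting alone E[D] = 0; significance comes from a
weighted delete-one block jackknife over contiguous site blocks, which is
robust to local linkage.

Topology weighting decomposes a tree with several tips per taxon group
into the fraction of one-tip-per-group subsamples whose induced unrooted
tree matches each possible taxon-level topology. Rooted sister
relationships are recovered as cherries, since the outgroup is simply one
of the groups.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DResult:
    """ABBA-BABA D with block-jackknife uncertainty."""

    d: float
    se: float
    z: float
    p: float
    n_blocks: int
    block_d: np.ndarray = field(repr=False)

    def summary(self) -> str:
        return (
            f"ABBA-BABA D = {self.d:.4f} +/- {self.se:.4f} "
            f"(Z = {self.z:.2f}, p = {self.p:.3g}, {self.n_blocks} blocks)"
        )


def site_pattern_terms(p1, p2, p3, p4) -> tuple[np.ndarray, np.ndarray]:
    """Per-site ABBA and BABA weights from derived-allele frequencies."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def d_statistic(p1, p2, p3, p4) -> float:
    """Frequency-based D over all sites with defined frequencies."""
    abba, baba = site_pattern_terms(p1, p2, p3, p4)
    ok = np.isfinite(abba) & np.isfinite(baba)
    if not ok.any():
        raise ValueError("no site with all four frequencies defined")
    num = (abba[ok] - baba[ok]).sum()
    den = (abba[ok] + baba[ok]).sum()
    if den == 0:
        raise ValueError("D undefined: no ABBA or BABA signal at any site")
    return float(num / den)


def block_jackknife(
    numerator: np.ndarray,
    denominator: np.ndarray,
    block_size: int = 100,
) -> DResult:
    """Weighted delete-one block jackknife for a ratio statistic.

    Sites are cut into contiguous blocks of ``block_size`` (the last block
    may be short); blocks are weighted by their site counts. Z = D/SE and
    p = 2*Phi(-|Z|). Requires >= 10 blocks.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    ok = np.isfinite(num) & np.isfinite(den)
    num, den = num[ok], den[ok]
    n_sites = num.size
    n_blocks = math.ceil(n_sites / block_size)
    if n_blocks < 10:
        raise ValueError(
            f"only {n_blocks} blocks of size {block_size}; "
            "use a smaller block size (need >= 10 blocks)"
        )
    edges = [(i * block_size, min((i + 1) * block_size, n_sites)) for i in range(n_blocks)]
    tot_num, tot_den = num.sum(), den.sum()
    if tot_den == 0:
        raise ValueError("D undefined: zero total denominator")
    theta = tot_num / tot_den

    m = np.array([e - s for s, e in edges], dtype=float)
    theta_del = np.array(
        [
            (tot_num - num[s:e].sum()) / (tot_den - den[s:e].sum())
            if (tot_den - den[s:e].sum()) != 0
            else np.nan
            for s, e in edges
        ]
    )
    if np.isnan(theta_del).any():
        raise ValueError("a delete-one block leaves a zero denominator")

    # Busing et al. (1999) weighted delete-one jackknife
    g = float(n_blocks)
    n = float(n_sites)
    h = n / m
    theta_tilde = g * theta - ((1 - m / n) * theta_del).sum()
    var = (1 / g) * np.sum(
        (h * theta - (h - 1) * theta_del - theta_tilde) ** 2 / (h - 1)
    )
    se = math.sqrt(max(var, 0.0))
    if se <= 1e-12 * max(abs(theta), 1.0):
        se = 0.0
        warnings.warn("jackknife SE is zero (identical blocks); p reported at floor")
        z = math.inf if theta != 0 else 0.0
        p = np.finfo(float).tiny if theta != 0 else 1.0
    else:
        z = theta / se
        p = float(2 * stats.norm.sf(abs(z)))
        p = max(p, np.finfo(float).tiny)
    return DResult(d=float(theta), se=se, z=float(z), p=p,
                   n_blocks=n_blocks, block_d=theta_del)


def d_test(p1, p2, p3, p4, block_size: int = 100) -> DResult:
    """D statistic with block-jackknife significance from frequency arrays."""
    abba, baba = site_pattern_terms(p1, p2, p3, p4)
    return block_jackknife(abba - baba, abba + baba, block_size)


# ---------------------------------------------------------------------------
# Topology catalog
# ---------------------------------------------------------------------------

# A taxon-level unrooted topology is stored by its set of nontrivial splits:
# frozenset of splits, each split a frozenset of the two group-frozensets.


def _splits_of_nested(tree, all_groups: frozenset) -> frozenset:
    """Nontrivial splits of a nested-tuple tree rooted at an implicit leaf."""
    splits = set()

    def leafset(node):
        if isinstance(node, str):
            return frozenset([node])
        below = frozenset()
        for child in node:
            below |= leafset(child)
        if 2 <= len(below) <= len(all_groups) - 2:
            splits.add(frozenset([below, all_groups - below]))
        return below

    leafset(tree)
    return frozenset(splits)


@dataclass
class TopologyCatalog:
    """All distinct unrooted binary topologies over a set of taxon groups."""

    groups: list[str]
    newicks: list[str]
    split_sets: list[frozenset]

    def __len__(self) -> int:
        return len(self.newicks)

    def index_by_splits(self) -> dict[frozenset, int]:
        return {s: i for i, s in enumerate(self.split_sets)}

    def cherry_indices(self, pair: tuple[str, str]) -> list[int]:
        """Topologies in which the pair forms a cherry (two-group split)."""
        a, b = pair
        if a not in self.groups or b not in self.groups:
            raise ValueError(f"pair {pair} not in catalog groups {self.groups}")
        want = frozenset([a, b])
        out = []
        for i, splits in enumerate(self.split_sets):
            if any(want in split for split in splits):
                out.append(i)
        return out


def _render_newick(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(_render_newick(c) for c in node) + ")"


def _canonical(node):
    if isinstance(node, str):
        return node
    return tuple(sorted((_canonical(c) for c in node), key=str))


def enumerate_topologies(group_names: list[str]) -> TopologyCatalog:
    """Enumerate all (2g-5)!! unrooted binary topologies on g groups (3..7).

    Trees are built by inserting each taxon on every edge of every smaller
    tree, represented rooted at the first group; the catalog is
    deduplicated by canonical form and stores one newick per topology.
    """
    g = len(group_names)
    if not 3 <= g <= 7:
        raise ValueError(f"need 3..7 groups, got {g}")
    if len(set(group_names)) != g:
        raise ValueError("group names must be distinct")
    root, first, second, *rest = group_names
    # unrooted tree on 3 taxa rooted at `root`: the other two form the subtree
    trees = [(first, second)]
    for name in rest:
        new_trees = []
        for tree in trees:
            for t in _insert_on_every_edge(tree, name):
                new_trees.append(t)
        trees = new_trees
    seen = {}
    for tree in trees:
        key = _canonical(tree)
        if key not in seen:
            seen[key] = tree
    all_groups = frozenset(group_names)
    newicks, split_sets = [], []
    for tree in seen.values():
        newicks.append(f"({root},{_render_newick(tree)});")
        split_sets.append(_splits_of_nested(tree, all_groups))
    return TopologyCatalog(list(group_names), newicks, split_sets)


def _insert_on_every_edge(tree, name):
    """All trees obtained by attaching `name` on any edge (incl. the root edge)."""
    yield (tree, name)  # root edge (the edge leading to the implicit root leaf)
    if isinstance(tree, str):
        return
    a, b = tree
    for sub in _insert_on_every_edge(a, name):
        yield (sub, b)
    for sub in _insert_on_every_edge(b, name):
        yield (a, sub)


# ---------------------------------------------------------------------------
# Topology weighting
# ---------------------------------------------------------------------------


@dataclass
class TopologyWeightTable:
    """Per-window weight vectors over a topology catalog."""

    catalog: TopologyCatalog
    weights: np.ndarray               # (n_windows, n_topologies)
    mode: str
    n_subsamples: int | None

    def to_frame(self) -> pd.DataFrame:
        cols = {f"topo_{i}": self.weights[:, i] for i in range(len(self.catalog))}
        return pd.DataFrame(cols)


def _tree_bipartitions(tree) -> list[frozenset]:
    """Tip-label sets below each internal edge of a dendropy tree."""
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out.append(below)
    return out


def topology_weights(
    tree,
    tip_to_group: dict[str, str],
    catalog: TopologyCatalog | None = None,
    mode: str = "exact",
    n_subsamples: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Weight vector of one tree over the taxon-level topology catalog.

    The weight of topology T is the fraction of one-tip-per-group
    subsamples whose induced unrooted tree (restriction of the input tree
    to the chosen tips) matches T. ``exact`` mode enumerates all
    combinations when their product is <= 10,000 (else raises); ``mc``
    samples ``n_subsamples`` combinations with a seeded generator.
    """
    import dendropy

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    groups: dict[str, list[str]] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in tip_to_group:
            raise ValueError(f"tip {label!r} has no group assignment")
        groups.setdefault(tip_to_group[label], []).append(label)
    group_names = sorted(groups)
    for gname in group_names:
        if not groups[gname]:
            raise ValueError(f"group {gname!r} has zero tips")
    if catalog is None:
        catalog = enumerate_topologies(group_names)
    elif sorted(catalog.groups) != group_names:
        raise ValueError("catalog groups do not match the tree's groups")
    index = catalog.index_by_splits()
    all_groups = frozenset(group_names)

    biparts = _tree_bipartitions(tree)
    tip_lists = [groups[g] for g in group_names]
    sizes = [len(t) for t in tip_lists]
    n_combo = math.prod(sizes)

    def induced_splits(chosen: dict[str, str]) -> frozenset:
        chosen_tips = set(chosen.values())
        tip_of = {v: k for k, v in chosen.items()}
        splits = set()
        for below in biparts:
            side = frozenset(tip_of[t] for t in below & chosen_tips)
            if 2 <= len(side) <= len(all_groups) - 2:
                splits.add(frozenset([side, all_groups - side]))
        return frozenset(splits)

    counts = np.zeros(len(catalog))
    if mode == "exact":
        if n_combo > 10_000:
            raise ValueError(
                f"{n_combo} subsamples exceed the exact-mode cap; use mode='mc'"
            )
        for combo in itertools.product(*tip_lists):
            chosen = dict(zip(group_names, combo))
            counts[index[induced_splits(chosen)]] += 1
        total = n_combo
    elif mode in ("mc", "montecarlo"):
        rng = np.random.default_rng(seed)
        for _ in range(n_subsamples):
            chosen = {
                g: tips[rng.integers(len(tips))] for g, tips in zip(group_names, tip_lists)
            }
            counts[index[induced_splits(chosen)]] += 1
        total = n_subsamples
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return counts / total


def weight_trees(
    trees: list[str],
    tip_to_group: dict[str, str],
    mode: str = "exact",
    n_subsamples: int = 10_000,
    seed: int = 0,
) -> TopologyWeightTable:
    """Topology-weight every window tree against a shared catalog."""
    group_names = sorted(set(tip_to_group.values()))
    catalog = enumerate_topologies(group_names)
    rng = np.random.default_rng(seed)
    rows = []
    for tree in trees:
        rows.append(
            topology_weights(
                tree,
                tip_to_group,
                catalog=catalog,
                mode=mode,
                n_subsamples=n_subsamples,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return TopologyWeightTable(catalog, np.array(rows), mode, n_subsamples)


def summarize_weights(
    table: TopologyWeightTable, sister_pair: tuple[str, str]
) -> dict:
    """Mean per-topology weights and the aggregate over sister-pair topologies.

    The aggregate is the summed mean weight of all catalog topologies in
    which ``sister_pair`` forms a cherry.
    """
    if table.weights.size == 0:
        raise ValueError("empty weight table")
    mean_w = table.weights.mean(axis=0)
    idx = table.catalog.cherry_indices(sister_pair)
    return {
        "mean_weights": mean_w,
        "sister_topologies": idx,
        "sister_aggregate": float(mean_w[idx].sum()),
    }
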