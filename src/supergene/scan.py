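"""Windowed diversity and differentiation statistics: pi, dXY, Hudson FST.

Per-site estimators operate on alt-allele dosage arrays; per-window values
are unweighted means of per-site values over sites usable in all groups
involved. FST is the Hudson estimator as a ratio of averages,
``1 - mean(H_within) / mean(H_between)``, which is robust to unequal and
small sample sizes; negative values are reported, not clipped.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, WindowSpec

logger = logging.getLogger(__name__)


def _allele_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt frequency, number of non-missing chromosomes)."""
    calls = np.atleast_2d(calls)
    ok = calls != MISSING
    n_chrom = 2 * ok.sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
    return p, n_chrom


def site_pi(calls: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity within one group of dosage rows.

    pi = (n/(n-1)) * 2 p (1-p) over the n non-missing chromosomes — the
    mean pairwise difference among chromosomes. Sites with fewer than two
    chromosomes are NaN (skipped, with a log note).
    """
    p, n = _allele_stats(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, (n / np.maximum(n - 1, 1)) * 2 * p * (1 - p), np.nan)
    n_skipped = int((n < 2).sum())
    if n_skipped:
        logger.info("site_pi: %d sites skipped (<2 chromosomes)", n_skipped)
    return pi


def site_dxy(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-site between-group diversity: dXY = p1(1-p2) + p2(1-p1)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return p1 * (1 - p2) + p2 * (1 - p1)


def window_fst(calls1: np.ndarray, calls2: np.ndarray) -> float:
    """Hudson FST over the provided sites (ratio of averages).

    H_within is the average of the two groups' per-site pi, H_between is
    per-site dXY; FST = 1 - mean(H_within)/mean(H_between) over sites
    usable in both groups. Returns NaN with no usable site.
    """
    pi1 = site_pi(calls1)
    pi2 = site_pi(calls2)
    p1, n1 = _allele_stats(calls1)
    p2, n2 = _allele_stats(calls2)
    dxy = site_dxy(p1, p2)
    usable = ~np.isnan(pi1) & ~np.isnan(pi2)
    if not usable.any():
        return np.nan
    h_within = 0.5 * (pi1[usable] + pi2[usable])
    h_between = dxy[usable]
    denom = h_between.mean()
    if denom == 0:
        return np.nan
    return 1 - h_within.mean() / denom


def observed_heterozygosity(
    gm: GenotypeMatrix,
    sample_set: Sequence[str],
    region: tuple[str, int, int] | np.ndarray | None = None,
) -> float:
    """Fraction of non-missing calls that are heterozygous (dosage 1).

    ``region`` is either a (chrom, start, end) tuple in 0-based half-open
    coordinates, a boolean variant mask, or None for all sites. Returns NaN
    if there is no non-missing call.
    """
    sub = gm.take_samples(sample_set)
    if region is None:
        calls = sub.calls
    elif isinstance(region, tuple):
        calls = sub.take_variants(sub.region_mask(*region)).calls
    else:
        calls = sub.take_variants(np.asarray(region)).calls
    if calls.size == 0:
        return np.nan
    ok = calls != MISSING
    if not ok.any():
        return np.nan
    return float((calls[ok] == 1).mean())


def scan(
    gm: GenotypeMatrix,
    group_map: Mapping[str, Sequence[str]],
    windows: Sequence[WindowSpec],
) -> pd.DataFrame:
    """Windowed pi / dXY / Hudson FST over a window grid.

    ``group_map`` maps group name -> sample ids; groups must not overlap.
    Returns one row per window with columns ``chrom, start, end, n_sites``,
    ``pi_<group>`` for each group, and ``dxy_<g1>_<g2>`` / ``fst_<g1>_<g2>``
    for each group pair. Per-window values are unweighted means over sites
    usable in the groups involved; windows without usable sites hold NaN.
    """
    groups = list(group_map)
    seen: set[str] = set()
    for g in groups:
        ids = list(group_map[g])
        if not ids:
            raise ValueError(f"group {g!r} is empty")
        overlap = seen & set(ids)
        if overlap:
            raise ValueError(f"groups overlap on samples {sorted(overlap)}")
        seen |= set(ids)

    sample_index = {s: i for i, s in enumerate(gm.sample_ids)}
    rows_by_group = {g: [sample_index[s] for s in group_map[g]] for g in groups}

    # per-site statistics computed once over the full matrix
    pi = {g: site_pi(gm.calls[rows_by_group[g]]) for g in groups}
    freq = {g: _allele_stats(gm.calls[rows_by_group[g]])[0] for g in groups}

    chroms = gm.chroms
    pos0 = gm.positions - 1
    pairs = list(itertools.combinations(groups, 2))
    records = []
    for w in windows:
        in_w = (chroms == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        usable = in_w & np.all([~np.isnan(pi[g]) for g in groups], axis=0)
        rec: dict = {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "n_sites": int(usable.sum()),
        }
        for g in groups:
            rec[f"pi_{g}"] = float(np.mean(pi[g][usable])) if usable.any() else np.nan
        for g1, g2 in pairs:
            if usable.any():
                dxy = site_dxy(freq[g1][usable], freq[g2][usable])
                h_within = 0.5 * (pi[g1][usable] + pi[g2][usable])
                mean_dxy = float(dxy.mean())
                fst = 1 - float(h_within.mean()) / mean_dxy if mean_dxy > 0 else np.nan
            else:
                mean_dxy, fst = np.nan, np.nan
            rec[f"dxy_{g1}_{g2}"] = mean_dxy
            rec[f"fst_{g1}_{g2}"] = fst
        records.append(rec)
    return pd.DataFrame.from_records(records)
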