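"""Composite genotype linkage disequilibrium (r^2) and distance-binned decay.

r^2 is the squared Pearson correlation of unphased alt-allele dosage
vectors across individuals (composite LD), computed over pairwise-complete
samples. Distances are measured between the 1-based positions of the two
sites. The expected finite-sample floor for independent sites is
approximately 1/n for n individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass
class LDDecayCurve:
    """Mean r^2 by pair-distance bin for one genomic region."""

    bin_edges: np.ndarray     # length n_bins + 1, bp
    mean_r2: np.ndarray       # length n_bins, NaN where no pairs
    pair_count: np.ndarray    # length n_bins
    region: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region,
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "mean_r2": self.mean_r2,
                "pair_count": self.pair_count.astype(int),
            }
        )


def genotype_r2(dosage_x: np.ndarray, dosage_y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing calls (-1) are removed pairwise. Returns NaN when fewer than
    two complete pairs remain or either site is monomorphic among them.
    """
    x = np.asarray(dosage_x, dtype=float)
    y = np.asarray(dosage_y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """All-pairs r^2 matrix over sites (columns), pairwise-complete.

    Vectorized via masked cross-products; NaN for undefined pairs.
    """
    ok = (calls != MISSING).astype(float)
    x = np.where(calls == MISSING, 0, calls).astype(float)
    x2 = x * x
    n = ok.T @ ok                      # complete pairs per site pair
    sx = x.T @ ok                      # sum of x over complete pairs (row site i, col j)
    sxx = x2.T @ ok
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx * sx / n       # var of site i over pairs with j
        vary = varx.T
        r2 = np.where((n >= 2) & (varx > 0) & (vary > 0), cov**2 / (varx * vary), np.nan)
    return r2


def ld_decay(
    gm: GenotypeMatrix,
    region: tuple[str, int, int],
    max_distance: int = 100_000,
    bin_width: int = 1_000,
    label: str | None = None,
) -> LDDecayCurve:
    """Distance-binned mean r^2 among all site pairs inside a region.

    ``region`` is (chrom, start, end), 0-based half-open. All within-region
    pairs separated by at most ``max_distance`` bp contribute to the bin
    containing their distance; bins are [0, w), [w, 2w), ...
    """
    chrom, start, end = region
    sub = gm.take_variants(gm.region_mask(chrom, start, end))
    edges = np.arange(0, max_distance + bin_width, bin_width)
    n_bins = len(edges) - 1
    if sub.n_variants < 2:
        warnings.warn(f"ld_decay: fewer than 2 sites in region {region}")
        return LDDecayCurve(edges, np.full(n_bins, np.nan), np.zeros(n_bins),
                            label or f"{chrom}:{start}-{end}")
    r2 = _pairwise_r2(sub.calls)
    pos = sub.positions
    iu = np.triu_indices(sub.n_variants, k=1)
    dist = np.abs(pos[iu[0]] - pos[iu[1]])
    vals = r2[iu]
    keep = (dist <= max_distance) & ~np.isnan(vals)
    dist, vals = dist[keep], vals[keep]
    if dist.size == 0:
        warnings.warn(f"ld_decay: no qualifying pairs in region {region}")
    which = np.minimum(dist // bin_width, n_bins - 1).astype(int)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    sums = np.bincount(which, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(edges, means, counts, label or f"{chrom}:{start}-{end}")


def compare_regions(curves: list[LDDecayCurve]) -> pd.DataFrame:
    """Long-format table of region x bin x mean r^2 for a set of curves.

    All curves must share identical bin edges.
    """
    if not curves:
        raise ValueError("no curves given")
    edges = curves[0].bin_edges
    for c in curves[1:]:
        if not np.array_equal(c.bin_edges, edges):
            raise ValueError("curves have mismatched distance bins")
    return pd.concat([c.to_frame() for c in curves], ignore_index=True)
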