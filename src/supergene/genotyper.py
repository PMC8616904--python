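"""Inversion genotyping from region SNPs, plus association and trend tests.

A polymorphic inversion shows up as three clusters on PC1 of the genotype
matrix restricted to the inverted region: the two homozygote arrangements
at the extremes and heterozygotes in the middle, the latter with roughly
doubled heterozygosity because they carry one copy of each non-recombining
haplotype. Genotypes are assigned by 1-D k-means on PC1 (k = 3) with the
middle cluster labeled AB; a heterozygosity check guards the labeling.

The association scan is a per-site linear trend test of phenotype on
dosage. It deliberately omits the kinship-aware mixed model used in
field-scale association studies: synthetic cohorts carry no relatedness
structure, so a trend test achieves near-nominal error control here. Do
not use it on structured cohorts without correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GENOTYPES, MISSING, GenotypeMatrix, SampleMetadata
from .scan import observed_heterozygosity


@dataclass
class InversionCallSet:
    """Per-sample inversion genotype calls with the evidence behind them."""

    sample_ids: list[str]
    pc1: np.ndarray
    cluster: np.ndarray                  # 0/1/2 in ascending PC1 order
    genotype: list[str]                  # AA / AB / BB per sample
    cluster_heterozygosity: dict[str, float]
    variance_explained: np.ndarray
    pc1_flipped: bool
    het_check_passed: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "pc1": self.pc1,
                "cluster": self.cluster,
                "genotype": self.genotype,
            }
        )

    def summary(self) -> str:
        counts = pd.Series(self.genotype).value_counts().reindex(GENOTYPES, fill_value=0)
        lines = [
            "Inversion genotype calls",
            f"  PC1 variance explained: {self.variance_explained[0]:.4f}"
            f" (orientation {'flipped' if self.pc1_flipped else 'kept'})",
            "  cluster sizes: "
            + ", ".join(f"{g}={counts[g]}" for g in GENOTYPES),
            "  observed heterozygosity: "
            + ", ".join(f"{g}={self.cluster_heterozygosity[g]:.3f}" for g in GENOTYPES),
            f"  heterozygosity check (AB > AA and AB > BB): "
            + ("passed" if self.het_check_passed else "FAILED"),
        ]
        return "\n".join(lines)


@dataclass
class AssociationResult:
    """Per-site trend-test statistics and significance flags."""

    table: pd.DataFrame = field(repr=False)  # chrom, pos, beta, t, p, significant
    alpha: float = 1e-5

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def pca(gm: GenotypeMatrix, maf_cutoff: float = 0.0):
    """PCA of the centered dosage matrix after a MAF cutoff.

    Missing dosages are mean-imputed per site before centering. Returns
    (scores, variance_explained); scores has one row per sample and min(n-1,
    m) columns, variance_explained sums to <= 1.
    """
    from .io import filter_by_maf

    sub = filter_by_maf(gm, maf_cutoff) if maf_cutoff > 0 else gm
    if sub.n_variants < 2 or sub.n_samples < 2:
        raise ValueError(
            f"PCA needs >= 2 samples and >= 2 sites after MAF cutoff "
            f"(have {sub.n_samples} x {sub.n_variants})"
        )
    x = sub.calls.astype(float)
    col_mean = np.where(
        (x != MISSING).any(axis=0),
        np.nanmean(np.where(x == MISSING, np.nan, x), axis=0),
        0.0,
    )
    x = np.where(x == MISSING, col_mean[None, :], x)
    x -= x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    total = (x**2).sum()
    variance_explained = (s**2) / total if total > 0 else np.zeros_like(s)
    return scores, variance_explained


def cluster_pc1(scores: np.ndarray, k: int = 3, max_iter: int = 200) -> np.ndarray:
    """Deterministic 1-D k-means on PC1.

    Centers start at the 1/(2k), 3/(2k), ..., (2k-1)/(2k) quantiles (for
    k = 3: the 1/6, 3/6, 5/6 quantiles) and Lloyd iterations run to
    convergence. Returns assignments 0..k-1 in ascending PC1 order.
    """
    pc1 = np.asarray(scores, dtype=float)
    if pc1.ndim > 1:
        pc1 = pc1[:, 0]
    if len(np.unique(pc1)) < k:
        raise ValueError(f"fewer than {k} distinct PC1 values")
    qs = (2 * np.arange(k) + 1) / (2 * k)
    centers = np.quantile(pc1, qs)
    # guard degenerate quantile ties
    if len(np.unique(centers)) < k:
        centers = np.linspace(pc1.min(), pc1.max(), k)
    for _ in range(max_iter):
        assign = np.argmin(np.abs(pc1[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [pc1[assign == j].mean() if (assign == j).any() else centers[j] for j in range(k)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers)
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    return rank[assign]


def label_genotypes(
    gm: GenotypeMatrix,
    region: tuple[str, int, int] | np.ndarray,
    maf_cutoff: float = 0.40,
) -> InversionCallSet:
    """Call AA/AB/BB inversion genotypes from the SNPs of a region.

    Runs PCA (with ``maf_cutoff``) on the region submatrix, clusters PC1
    into three groups, orients PC1 so the largest cluster sits leftmost
    (the sign of a principal component is arbitrary and must be pinned),
    and labels clusters AA/AB/BB left to right. A post-condition verifies
    that the middle cluster's observed heterozygosity exceeds both outer
    clusters'; on failure the calls are returned with the check flagged.
    """
    if isinstance(region, tuple):
        mask = gm.region_mask(*region)
    else:
        mask = np.asarray(region)
    sub = gm.take_variants(mask)
    scores, varexp = pca(sub, maf_cutoff)
    pc1 = scores[:, 0]
    assign = cluster_pc1(pc1, k=3)
    sizes = np.bincount(assign, minlength=3)
    flipped = False
    if sizes.argmax() == 2:  # largest cluster rightmost -> flip orientation
        pc1 = -pc1
        assign = 2 - assign
        flipped = True
    genotype = [GENOTYPES[a] for a in assign]

    het = {}
    for j, g in enumerate(GENOTYPES):
        members = [s for s, a in zip(gm.sample_ids, assign) if a == j]
        het[g] = (
            observed_heterozygosity(gm, members, mask) if members else np.nan
        )
    het_ok = bool(
        np.isfinite(het["AB"])
        and het["AB"] > het["AA"]
        and het["AB"] > het["BB"]
    )
    return InversionCallSet(
        sample_ids=list(gm.sample_ids),
        pc1=pc1,
        cluster=assign,
        genotype=genotype,
        cluster_heterozygosity=het,
        variance_explained=varexp,
        pc1_flipped=flipped,
        het_check_passed=het_ok,
    )


def latitude_trend(
    metadata: SampleMetadata,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Kendall tau-b between B-haplotype dosage and latitude, permutation p.

    Dosage is 0/1/2 for AA/AB/BB. The p-value is two-sided from >= 10,000
    seeded permutations of latitude: (1 + #{|tau*| >= |tau|}) / (B + 1).
    """
    table = metadata.table
    if "inversion_genotype" not in table.columns:
        raise ValueError("metadata has no inversion_genotype column")
    geno = table["inversion_genotype"].to_numpy()
    if len(set(geno)) < 2:
        raise ValueError("need >= 2 genotype groups for a latitude trend")
    dosage = np.array([GENOTYPES.index(g) for g in geno], dtype=float)
    lat = table["latitude"].to_numpy(float)
    tau = stats.kendalltau(dosage, lat).statistic
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        t = stats.kendalltau(dosage, rng.permutation(lat)).statistic
        if abs(t) >= abs(tau) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return float(tau), float(p)


def association_scan(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    alpha: float = 1e-5,
) -> AssociationResult:
    """Per-site linear trend test of phenotype on alt-allele dosage.

    For each site, the slope t-test of ``phenotype ~ dosage`` over
    non-missing samples; monomorphic or under-filled sites get p = 1.
    Sites with p < alpha are flagged significant.
    """
    y_all = np.asarray(phenotype, dtype=float)
    if y_all.shape[0] != gm.n_samples:
        raise ValueError("phenotype length != number of samples")
    if np.ptp(y_all[np.isfinite(y_all)]) == 0:
        raise ValueError("phenotype is constant")

    calls = gm.calls
    ok = (calls != MISSING) & np.isfinite(y_all)[:, None]
    x = np.where(ok, calls, 0.0)
    y = np.where(ok, y_all[:, None], 0.0)
    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx, sy = x.sum(axis=0), y.sum(axis=0)
        sxx, syy, sxy = (x * x).sum(axis=0), (y * y).sum(axis=0), (x * y).sum(axis=0)
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        cov = sxy - sx * sy / n
        beta = cov / varx
        r2 = cov**2 / (varx * vary)
        r2 = np.clip(r2, 0.0, 1.0)
        tstat = np.sign(cov) * np.sqrt(
            np.clip(r2 * (n - 2) / np.maximum(1 - r2, 1e-300), 0, None)
        )
        p = 2 * stats.t.sf(np.abs(tstat), df=np.maximum(n - 2, 1))
    defined = (n >= 3) & (varx > 0) & (vary > 0)
    p = np.where(defined, p, 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    beta = np.where(defined, beta, np.nan)
    tstat = np.where(defined, tstat, np.nan)
    table = pd.DataFrame(
        {
            "chrom": gm.chroms,
            "pos": gm.positions,
            "beta": beta,
            "t": tstat,
            "p": p,
            "significant": p < alpha,
        }
    )
    return AssociationResult(table, alpha)


def additivity_check(
    phenotype: np.ndarray,
    genotype: list[str],
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotype-group phenotype means with bootstrap CIs and an additivity flag.

    The returned frame has one row per genotype with mean and 95% bootstrap
    interval; attribute ``frame.attrs['monotone']`` is True iff the group
    means are strictly ordered AA < AB < BB or the reverse (NaN-undefined
    when a genotype class is absent).
    """
    y = np.asarray(phenotype, dtype=float)
    geno = np.asarray(genotype, dtype=object)
    rng = np.random.default_rng(seed)
    rows = []
    means = {}
    for g in GENOTYPES:
        vals = y[geno == g]
        if vals.size == 0:
            rows.append({"genotype": g, "n": 0, "mean": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        boots = np.array(
            [rng.choice(vals, size=vals.size, replace=True).mean()
             for _ in range(n_bootstrap)]
        )
        means[g] = vals.mean()
        rows.append(
            {
                "genotype": g,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "ci_low": float(np.quantile(boots, 0.025)),
                "ci_high": float(np.quantile(boots, 0.975)),
            }
        )
    frame = pd.DataFrame(rows)
    if len(means) == 3:
        m = [means[g] for g in GENOTYPES]
        frame.attrs["monotone"] = bool(m[0] < m[1] < m[2] or m[0] > m[1] > m[2])
    else:
        frame.attrs["monotone"] = None
    return frame
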