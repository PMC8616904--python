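"""Genotype-matrix container, VCF I/O, variant filters, and window grids.

Internal coordinates are 0-based half-open; VCF input/output converts
to/from the 1-based positions of the format. Only biallelic SNPs are
retained: multiallelic records and indels are dropped, not split, and
half-calls (e.g. ``./1``) are treated as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

ECOTYPES = ("common", "hoary", "lesser")
SEASONS = ("breeding", "nonbreeding")
GENOTYPES = ("AA", "AB", "BB")

_NUCLEOTIDES = frozenset("ACGT")


class VCFParseError(ValueError):
    """Raised when a VCF header or record cannot be parsed."""


class EmptyMatrixError(ValueError):
    """Raised when an operation would produce or consume a matrix with no variants."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: chromosome, 1-based position, ref and alt nucleotides."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref not in _NUCLEOTIDES or self.alt not in _NUCLEOTIDES:
            raise ValueError(f"not a biallelic SNP: {self.ref}->{self.alt}")


class GenotypeMatrix:
    """Samples x biallelic variants with diploid alt-allele dosage calls.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers.
    variants
        Ordered :class:`VariantRecord` list, sorted by (chrom, pos).
    calls
        ``(n_samples, n_variants)`` integer array of alt-allele dosages in
        {0, 1, 2}, with ``MISSING`` (-1) for missing calls.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variants: Sequence[VariantRecord],
        calls: np.ndarray,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.variants = list(variants)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {calls.shape} != "
                f"({len(self.sample_ids)}, {len(self.variants)})"
            )
        bad = (calls < MISSING) | (calls > 2)
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or -1 (missing)")
        keys = [(v.chrom, v.pos) for v in self.variants]
        if keys != sorted(keys):
            raise ValueError("variants must be sorted by (chrom, pos)")
        self.calls = calls

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=object)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variants == other.variants
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"

    # -- derived quantities ---------------------------------------------------

    def alt_freq(self) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing chromosomes (NaN if none)."""
        ok = self.calls != MISSING
        n_chrom = 2 * ok.sum(axis=0)
        alt = np.where(ok, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chrom > 0, alt / n_chrom, np.nan)

    def missing_fraction(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_variants)
        return (self.calls == MISSING).mean(axis=0)

    # -- subsetting ------------------------------------------------------------

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.sample_ids,
            [self.variants[i] for i in index],
            self.calls[:, index],
        )

    def take_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [order[s] for s in ids]
        return GenotypeMatrix(
            [self.sample_ids[r] for r in rows], self.variants, self.calls[rows]
        )

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of variants inside [start, end) (0-based half-open)."""
        pos0 = self.positions - 1
        return (self.chroms == chrom) & (pos0 >= start) & (pos0 < end)


@dataclass(frozen=True)
class WindowSpec:
    """A genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end {self.end} <= start {self.start}")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class SampleMetadata:
    """Per-sample ecotype, latitude, season, and optional inversion genotype."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "ecotype", "latitude", "season")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        bad = set(self.table["ecotype"]) - set(ECOTYPES)
        if bad:
            raise ValueError(f"unknown ecotype labels: {sorted(bad)}")
        bad = set(self.table["season"]) - set(SEASONS)
        if bad:
            raise ValueError(f"unknown season labels: {sorted(bad)}")
        lat = self.table["latitude"].to_numpy(float)
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude outside [-90, 90]")
        if "inversion_genotype" in self.table.columns:
            vals = self.table["inversion_genotype"].dropna()
            bad = set(vals) - set(GENOTYPES)
            if bad:
                raise ValueError(f"unknown inversion genotypes: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def _is_biallelic_snp(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and ref in _NUCLEOTIDES
        and alts[0] in _NUCLEOTIDES
    )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    Non-SNP and multiallelic records are dropped (a count is logged), diploid
    GT is mapped to alt-allele dosage, and any genotype containing a missing
    allele (including half-calls) becomes a missing call.

    Raises
    ------
    VCFParseError
        On an unreadable header or record.
    EmptyMatrixError
        If no biallelic SNP survives.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VCFParseError(f"cannot parse VCF header of {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_dropped = 0
    lineno = 0
    try:
        for rec in vcf:
            lineno += 1
            if not _is_biallelic_snp(rec.REF, rec.ALT):
                n_dropped += 1
                continue
            geno = np.asarray(rec.genotype.array())
            alleles = geno[:, :2]
            dosage = np.where(
                (alleles < 0).any(axis=1), MISSING, alleles.clip(min=0).sum(axis=1)
            )
            variants.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
            columns.append(dosage.astype(np.int8))
    except VCFParseError:
        raise
    except Exception as exc:
        raise VCFParseError(f"malformed VCF record #{lineno} in {path}: {exc}") from exc
    finally:
        vcf.close()

    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    if not variants:
        raise EmptyMatrixError(f"no biallelic SNPs retained from {path}")
    calls = np.stack(columns, axis=1)
    order = np.lexsort((
        np.array([v.pos for v in variants]),
        np.array([v.chrom for v in variants], dtype=object),
    ))
    variants = [variants[i] for i in order]
    return GenotypeMatrix(sample_ids, variants, calls[:, order])


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 file; round-trips through :func:`read_vcf`."""
    if gm.n_samples == 0:
        raise ValueError("cannot write a VCF with no samples")
    contig_max: dict[str, int] = {}
    for v in gm.variants:
        contig_max[v.chrom] = max(contig_max.get(v.chrom, 0), v.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=supergene\n")
        for chrom, maxpos in contig_max.items():
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, v in enumerate(gm.variants):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in gm.calls[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------


def filter_by_maf(gm: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep sites whose minor-allele frequency (over non-missing alleles) >= threshold."""
    if not 0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    p = gm.alt_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1 - p)
    keep = np.nan_to_num(maf, nan=-1.0) >= threshold
    return gm.take_variants(keep)


def filter_by_missingness(gm: GenotypeMatrix, max_missing_fraction: float) -> GenotypeMatrix:
    """Keep sites whose fraction of missing calls <= max_missing_fraction."""
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    return gm.take_variants(gm.missing_fraction() <= max_missing_fraction)


# ---------------------------------------------------------------------------
# Window grids
# ---------------------------------------------------------------------------


def make_windows(
    chrom_lengths: dict[str, int], size: int, step: int | None = None
) -> list[WindowSpec]:
    """Tile each chromosome with windows of ``size`` bp every ``step`` bp.

    The last window of a chromosome may be short. With ``step == size`` the
    grid covers every base exactly once.
    """
    if size <= 0:
        raise ValueError("window size must be > 0")
    step = size if step is None else step
    if step <= 0:
        raise ValueError("window step must be > 0")
    windows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, step):
            windows.append(WindowSpec(chrom, start, min(start + size, length)))
    return windows


def windows_to_bed(windows: Iterable[WindowSpec], path) -> None:
    """Emit windows as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\n")
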