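"""Readers and writers for the genomic file formats used throughout the package.

Coordinate contracts are strict and conversions happen in exactly one place:

* BED / BEDPE intervals are 0-based, half-open, exactly as stored on disk.
* SNP tables are 1-based (dbSNP convention).
* The single conversion point between the two worlds is
  :func:`snp_in_interval`: a SNP at 1-based position ``p`` overlaps the
  interval ``[start, end)`` iff ``start <= p - 1 < end``.

Position weight matrices (PWMs) are probability matrices over A, C, G, T with
an explicit background model.  Zero entries are regularized with a small
pseudocount so that log-ratios stay finite.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_BACKGROUND = np.full(4, 0.25)

DEFAULT_MAF_THRESHOLD = 0.05
DEFAULT_HWE_ALPHA = 0.05
DEFAULT_PSEUDOCOUNT = 1e-3


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class LoopPair:
    """A chromatin loop connecting two anchor intervals."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval

    def __post_init__(self) -> None:
        if self.anchor1 == self.anchor2:
            raise ValueError("loop anchors must differ")


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with 1-based position and major/minor alleles.

    ``filters`` lists quality-control failures (``"maf"``, ``"hwe"``); an
    empty tuple means the SNP passed all filters applied at read time.
    """

    snp_id: str
    chrom: str
    pos: int
    major: str
    minor: str
    maf: float | None = None
    filters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for allele in (self.major, self.minor):
            if allele not in BASE_INDEX:
                raise ValueError(f"{self.snp_id}: allele {allele!r} not in ACGT")
        if self.major == self.minor:
            raise ValueError(f"{self.snp_id}: major and minor alleles are equal")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: positions are 1-based, got {self.pos}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")

    @property
    def passed(self) -> bool:
        return not self.filters


class Pwm:
    """A position weight matrix: per-position base probabilities.

    Probabilities are regularized with ``pseudocount`` and renormalized at
    construction, so every stored row sums to one and (for positive
    pseudocount) every entry is strictly positive.
    """

    def __init__(
        self,
        name: str,
        probs: np.ndarray,
        pseudocount: float = 0.0,
        background: np.ndarray | None = None,
    ) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError(f"PWM {name}: expected a w x 4 matrix, got {probs.shape}")
        if probs.shape[0] < 1:
            raise ValueError(f"PWM {name}: empty matrix")
        if np.any(probs < 0) or not np.all(np.isfinite(probs)):
            raise ValueError(f"PWM {name}: probabilities must be finite and >= 0")
        if pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        regularized = probs + pseudocount
        row_sums = regularized.sum(axis=1, keepdims=True)
        if np.any(row_sums <= 0):
            raise ValueError(f"PWM {name}: a row sums to zero")
        self.name = name
        self.probs = regularized / row_sums
        self.pseudocount = float(pseudocount)
        self.background = (
            UNIFORM_BACKGROUND.copy()
            if background is None
            else np.asarray(background, dtype=float)
        )
        if self.background.shape != (4,) or abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError(f"PWM {name}: background must be a length-4 probability vector")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Pwm({self.name!r}, width={self.width})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pwm):
            return NotImplemented
        return (
            self.name == other.name
            and self.probs.shape == other.probs.shape
            and np.allclose(self.probs, other.probs, atol=1e-12)
            and np.allclose(self.background, other.background, atol=1e-12)
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "probs": self.probs.tolist(),
            "pseudocount": self.pseudocount,
            "background": self.background.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Pwm":
        # probs are already regularized; do not re-apply the pseudocount
        pwm = cls(d["name"], np.asarray(d["probs"]), 0.0, np.asarray(d["background"]))
        pwm.pseudocount = float(d.get("pseudocount", 0.0))
        return pwm


@dataclass
class CohortData:
    """Genotype, expression and phenotype matrices over a shared sample panel.

    ``genotypes`` is SNP x sample minor-allele dosage (0/1/2, NaN = missing),
    ``expression`` is gene x sample, ``phenotypes`` is drug x sample (EC50).
    Column order is identical across the three matrices.
    """

    samples: list[str]
    genotypes: pd.DataFrame
    expression: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        for label, df in (
            ("genotypes", self.genotypes),
            ("expression", self.expression),
            ("phenotypes", self.phenotypes),
        ):
            if list(df.columns) != list(self.samples):
                raise ValueError(f"{label}: column order differs from the sample list")
        dosages = self.genotypes.to_numpy(dtype=float)
        observed = dosages[~np.isnan(dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype dosages must be 0, 1, 2 or missing")


# ---------------------------------------------------------------------------
# Coordinate predicate (the single 1-based <-> 0-based conversion point)
# ---------------------------------------------------------------------------


def snp_in_interval(snp: SnpRecord, interval: GenomicInterval) -> bool:
    """True iff the SNP's base lies inside the 0-based half-open interval."""
    return (
        snp.chrom == interval.chrom
        and interval.start <= snp.pos - 1 < interval.end
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into a chrom -> uppercase sequence mapping."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FormatError(f"duplicate FASTA record {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    if not seqs:
        raise FormatError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# PWM sets
# ---------------------------------------------------------------------------


def read_pwm_set(
    path: str | Path,
    dialect: str = "meme_minimal",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[Pwm]:
    """Read a set of PWMs from a motif file.

    Supported dialects are ``meme_minimal`` (MEME minimal motif format) and
    ``plain_matrix`` (whitespace-separated probability rows, motifs introduced
    by ``>name`` lines or separated by blank lines).
    """
    if dialect == "meme_minimal":
        return _read_meme_minimal(path, pseudocount)
    if dialect == "plain_matrix":
        return _read_plain_matrix(path, pseudocount)
    raise ValueError(f"unknown PWM dialect {dialect!r}")


def _read_meme_minimal(path: str | Path, pseudocount: float) -> list[Pwm]:
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "minimal")
        except Exception as exc:  # biopython raises bare ValueError
            raise FormatError(f"{path}: malformed MEME minimal file: {exc}") from exc
    pwms = []
    for motif in records:
        probs = np.array([[motif.pwm[b][j] for b in BASES] for j in range(motif.length)])
        bg = np.array([motif.background[b] for b in BASES], dtype=float)
        bg = bg / bg.sum()
        pwms.append(Pwm(motif.name or f"motif_{len(pwms) + 1}", probs, pseudocount, bg))
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def _read_plain_matrix(path: str | Path, pseudocount: float) -> list[Pwm]:
    pwms: list[Pwm] = []
    name: str | None = None
    rows: list[list[float]] = []
    auto = 0

    def flush() -> None:
        nonlocal name, rows, auto
        if rows:
            auto += 1
            pwms.append(
                Pwm(name or f"motif_{auto}", np.array(rows), pseudocount)
            )
        name, rows = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush()
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip() or None
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(
                    f"{path} line {lineno}: expected 4 probabilities, got {len(fields)}"
                )
            try:
                values = [float(x) for x in fields]
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: non-numeric entry") from exc
            total = sum(values)
            if not (0.9 <= total <= 1.1):
                raise FormatError(
                    f"{path} line {lineno}: row sums to {total:.4f}, outside [0.9, 1.1]"
                )
            if abs(total - 1.0) > 1e-6:
                warnings.warn(
                    f"{path} line {lineno}: row sum {total:.4f} renormalized to 1"
                )
            rows.append([v / total for v in values])
    flush()
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def write_pwm_set(pwms: Sequence[Pwm], path: str | Path, dialect: str = "plain_matrix") -> None:
    if dialect != "plain_matrix":
        raise ValueError("only the plain_matrix dialect is written")
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.probs:
                fh.write("\t".join(f"{p:.10g}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------

_BED_SKIP_PREFIXES = ("#", "track", "browser")


def read_intervals(path: str | Path, kind: str = "bed"):
    """Read BED3+ into GenomicIntervals, or BEDPE into LoopPairs."""
    if kind not in ("bed", "bedpe"):
        raise ValueError(f"unknown interval kind {kind!r}")
    min_cols = 3 if kind == "bed" else 6
    out: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path} line {lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            try:
                if kind == "bed":
                    name = fields[3] if len(fields) > 3 else None
                    out.append(
                        GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name)
                    )
                else:
                    name = fields[6] if len(fields) > 6 else None
                    a1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name)
                    a2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]), name)
                    out.append(LoopPair(a1, a2))
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
    return out


def write_intervals(items: Sequence, path: str | Path, kind: str = "bed") -> None:
    with open(path, "w") as fh:
        for item in items:
            if kind == "bed":
                cols = [item.chrom, str(item.start), str(item.end)]
                if item.name is not None:
                    cols.append(item.name)
            elif kind == "bedpe":
                a1, a2 = item.anchor1, item.anchor2
                cols = [
                    a1.chrom, str(a1.start), str(a1.end),
                    a2.chrom, str(a2.start), str(a2.end),
                ]
                if a1.name is not None:
                    cols.append(a1.name)
            else:
                raise ValueError(f"unknown interval kind {kind!r}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# SNP tables & genotype-derived statistics
# ---------------------------------------------------------------------------


def compute_maf(dosages: Sequence[float] | np.ndarray) -> float:
    """Minor-allele frequency from 0/1/2 dosages (NaN dropped)."""
    arr = np.asarray(dosages, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no observed genotypes")
    freq = arr.sum() / (2 * arr.size)
    return float(min(freq, 1.0 - freq))


def hwe_test_p(n_major_hom: int, n_het: int, n_minor_hom: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg equilibrium."""
    n = n_major_hom + n_het + n_minor_hom
    if n == 0:
        raise ValueError("no genotype counts")
    p = (2 * n_minor_hom + n_het) / (2 * n)
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    observed = np.array([n_major_hom, n_het, n_minor_hom], dtype=float)
    keep = expected > 0
    chi2 = float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    return float(stats.chi2.sf(chi2, df=1))


_SNP_COLUMNS = ("snp_id", "chrom", "pos", "major", "minor")


def read_snp_table(
    path: str | Path,
    genotypes: pd.DataFrame | None = None,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    hwe_alpha: float = DEFAULT_HWE_ALPHA,
) -> list[SnpRecord]:
    """Read a SNP TSV (snp_id, chrom, pos, major, minor[, maf]).

    When ``maf`` is absent it is computed from the dosage matrix
    ``genotypes`` (SNP x sample) if one is supplied.  SNPs with
    ``maf < maf_threshold`` or a Hardy-Weinberg chi-square p-value below
    ``hwe_alpha`` (computable only with genotypes) are flagged in
    ``SnpRecord.filters``, not removed; use :func:`passing_snps`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in _SNP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    dupes = df["snp_id"][df["snp_id"].duplicated()]
    if not dupes.empty:
        raise FormatError(f"{path}: duplicate snp_id {dupes.iloc[0]!r}")

    records: list[SnpRecord] = []
    for row in df.itertuples(index=False):
        maf = getattr(row, "maf", None)
        if maf is not None and (isinstance(maf, float) and math.isnan(maf)):
            maf = None
        filters: list[str] = []
        if maf is None and genotypes is not None and row.snp_id in genotypes.index:
            dosages = genotypes.loc[row.snp_id].to_numpy(dtype=float)
            maf = compute_maf(dosages)
            observed = dosages[~np.isnan(dosages)]
            counts = [int((observed == g).sum()) for g in (0, 1, 2)]
            if hwe_test_p(*counts) < hwe_alpha:
                filters.append("hwe")
        if maf is not None and maf < maf_threshold:
            filters.append("maf")
        records.append(
            SnpRecord(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                major=str(row.major).upper(),
                minor=str(row.minor).upper(),
                maf=None if maf is None else float(maf),
                filters=tuple(filters),
            )
        )
    return records


def passing_snps(records: Iterable[SnpRecord]) -> list[SnpRecord]:
    return [r for r in records if r.passed]


def write_snp_table(records: Sequence[SnpRecord], path: str | Path) -> None:
    rows = [
        {
            "snp_id": r.snp_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "major": r.major,
            "minor": r.minor,
            "maf": r.maf,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Labeled matrices (expression, genotypes, phenotypes)
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV with a header of sample ids.

    Empty cells become NaN (missing, never zero); ragged rows are an error.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise FormatError(f"{path}: empty file")
    n_header = len(lines[0].split("\t"))
    data_lines = [l for l in lines[1:] if l.strip()]
    if not data_lines:
        raise FormatError(f"{path}: no data rows")
    # R-style headers omit the index column name, so data rows may carry
    # either as many fields as the header or exactly one more
    expected = len(data_lines[0].split("\t"))
    if expected not in (n_header, n_header + 1):
        raise FormatError(
            f"{path} line 2: {expected} fields does not match header ({n_header})"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        if line.strip() and len(line.split("\t")) != expected:
            raise FormatError(
                f"{path} line {lineno}: {len(line.split(chr(9)))} fields, expected {expected}"
            )
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")
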