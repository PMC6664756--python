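"""Allele-specific windows and variant impact (delta) scores.

A SNP's impact on a TF's binding is scored by extracting the 501-bp window
centered on the SNP from the major-allele reference genome, substituting
each allele at the central base, scoring both sequences with a trained
binding predictor, and taking the absolute difference.  The same recipe
applies to any predictor exposing ``score(sequence)``: a calibrated
single-motif occupancy model (delta-STAP), the multi-motif fusion model
(delta-MOP), or the best-site PWM log-likelihood baseline (delta-PWM).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .formats_io import FormatError, Pwm, SnpRecord, UNIFORM_BACKGROUND
from .stap import encode_sequence, llr_profiles

WINDOW_FLANK = 250  # bases on each side of the SNP; total window = 501 bp


class SequenceScorer(Protocol):
    def score(self, sequence: str) -> float: ...


class EdgeSnpError(ValueError):
    """SNP too close to a chromosome end for a full window."""


def impact_from_allele_scores(major_score: float, minor_score: float) -> float:
    """The TFBS-SNP impact score: |score(major) - score(minor)|."""
    return abs(float(major_score) - float(minor_score))


def build_major_allele_reference(
    genome: Mapping[str, str], snps: Sequence[SnpRecord]
) -> dict[str, str]:
    """Return a copy of the genome with every SNP position set to its major allele."""
    out = dict(genome)
    mutable: dict[str, list[str]] = {}
    for snp in snps:
        if snp.chrom not in out:
            raise KeyError(f"{snp.snp_id}: chromosome {snp.chrom!r} not in genome")
        if snp.pos > len(out[snp.chrom]):
            raise ValueError(
                f"{snp.snp_id}: position {snp.pos} beyond {snp.chrom} length "
                f"{len(out[snp.chrom])}"
            )
        if out[snp.chrom][snp.pos - 1].upper() != snp.major:
            chars = mutable.setdefault(snp.chrom, list(out[snp.chrom]))
            chars[snp.pos - 1] = snp.major
    for chrom, chars in mutable.items():
        out[chrom] = "".join(chars)
    return out


def build_allele_windows(
    snp: SnpRecord, genome: Mapping[str, str], flank: int = WINDOW_FLANK
) -> tuple[str, str]:
    """(major_seq, minor_seq), each ``2*flank + 1`` bp centered on the SNP.

    The sequences differ only at the central index ``flank``.  SNPs within
    ``flank`` bases of a chromosome end raise :class:`EdgeSnpError` rather
    than being silently padded.
    """
    if snp.chrom not in genome:
        raise KeyError(f"{snp.snp_id}: chromosome {snp.chrom!r} not in genome")
    seq = genome[snp.chrom]
    center = snp.pos - 1
    if center >= len(seq):
        raise ValueError(f"{snp.snp_id}: position {snp.pos} beyond chromosome end")
    if center - flank < 0 or center + flank >= len(seq):
        raise EdgeSnpError(
            f"{snp.snp_id}: within {flank} bp of a chromosome end, no full window"
        )
    window = seq[center - flank : center + flank + 1].upper()
    major_seq = window[:flank] + snp.major + window[flank + 1 :]
    minor_seq = window[:flank] + snp.minor + window[flank + 1 :]
    return major_seq, minor_seq


def delta_score(
    snp: SnpRecord,
    genome: Mapping[str, str],
    predictor: SequenceScorer,
    flank: int = WINDOW_FLANK,
) -> float:
    """Impact of a SNP under any sequence-scoring binding predictor.

    Symmetric under major/minor swap by construction.
    """
    major_seq, minor_seq = build_allele_windows(snp, genome, flank)
    return impact_from_allele_scores(predictor.score(major_seq), predictor.score(minor_seq))


def _best_overlapping_llr(sequence: str, pwm: Pwm, center: int, background) -> float:
    """Best llr over both strands among placements covering ``center``.

    Placements not covering the SNP are identical between alleles and would
    cancel in the delta, so only the overlapping ones need scoring.
    """
    codes = encode_sequence(sequence)
    fwd, rev = llr_profiles(codes, pwm, background)
    w = pwm.width
    lo = max(0, center - w + 1)
    hi = min(center, len(sequence) - w)
    if hi < lo:
        return float("-inf")
    return float(max(fwd[lo : hi + 1].max(), rev[lo : hi + 1].max()))


def delta_pwm(
    snp: SnpRecord,
    genome: Mapping[str, str],
    pwm: Pwm,
    background=None,
    flank: int = WINDOW_FLANK,
) -> float:
    """Best-site PWM baseline: |max llr(major window) - max llr(minor window)|,
    both strands, restricted to motif placements overlapping the SNP."""
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    major_seq, minor_seq = build_allele_windows(snp, genome, flank)
    return impact_from_allele_scores(
        _best_overlapping_llr(major_seq, pwm, flank, bg),
        _best_overlapping_llr(minor_seq, pwm, flank, bg),
    )


def load_external_scores(path: str | Path) -> dict[tuple[str, str], float]:
    """Load a per-(SNP, TF) impact-score table, e.g. from a k-mer method.

    Expects TSV columns ``snp_id``, ``tf``, ``score``; duplicates and
    non-finite scores are rejected; unknown TFs pass through untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "tf": str})
    for col in ("snp_id", "tf", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    dupes = df.duplicated(subset=["snp_id", "tf"])
    if dupes.any():
        row = df[dupes].iloc[0]
        raise FormatError(f"{path}: duplicate entry ({row.snp_id}, {row.tf})")
    scores = df["score"].astype(float)
    if not np.all(np.isfinite(scores)):
        bad = df[~np.isfinite(scores)].iloc[0]
        raise FormatError(f"{path}: non-finite score for ({bad.snp_id}, {bad.tf})")
    return {
        (str(r.snp_id), str(r.tf)): float(r.score) for r in df.itertuples(index=False)
    }
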