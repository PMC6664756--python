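"""Balanced per-TF training/test window construction from ChIP peaks.

Positive windows are 500-bp segments centered on eligible peak midpoints of
the test TF.  A peak is eligible if it lies within 50 kbp upstream
(strand-aware) of some protein-coding TSS and is not a High Occupancy
Target (HOT) region, i.e. not overlapped at >= 50% of its length by peaks
of six or more distinct other TFs.  Negative windows are drawn from the
positive windows of other TFs, excluding any that touch a test-TF peak, so
that the classifier learns the test TF's sequence preference rather than
generic accessibility.  The balanced set is split 80/20 into balanced
train/test partitions (1600/400 at the standard 1000+1000 scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .formats_io import GenomicInterval
from .stap import LabeledWindow

UPSTREAM_SPAN = 50_000
WINDOW_LENGTH = 500
HOT_MIN_TFS = 6
HOT_MIN_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class Tss:
    """A transcription start site with gene strand."""

    gene: str
    strand: str
    chrom: str
    position: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene}: strand must be + or -, got {self.strand!r}")


def upstream_interval(tss: Tss, span: int = UPSTREAM_SPAN) -> GenomicInterval:
    """The strand-aware upstream region of a TSS."""
    if tss.strand == "+":
        start, end = max(0, tss.position - span), tss.position
    else:
        start, end = tss.position, tss.position + span
    if end <= start:  # TSS at position 0 on + strand
        end = start + 1
    return GenomicInterval(tss.chrom, start, end)


def _build_trees(peaks: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for peak in peaks:
        trees.setdefault(peak.chrom, IntervalTree()).addi(peak.start, peak.end, peak)
    return trees


def is_hot(
    peak: GenomicInterval,
    other_tf_peaks: Mapping[str, Sequence[GenomicInterval]],
    min_tfs: int = HOT_MIN_TFS,
    min_overlap_fraction: float = HOT_MIN_OVERLAP_FRACTION,
) -> bool:
    """HOT rule: >= ``min_tfs`` distinct TFs each overlap >= 50% of the peak."""
    needed = min_overlap_fraction * peak.length
    count = 0
    for tf_peaks in other_tf_peaks.values():
        if any(peak.overlap_length(p) >= needed for p in tf_peaks):
            count += 1
            if count >= min_tfs:
                return True
    return False


def select_positive_windows(
    tf: str,
    all_tf_peaks: Mapping[str, Sequence[GenomicInterval]],
    tss_list: Sequence[Tss],
    n: int,
    seed: int = 0,
    window_length: int = WINDOW_LENGTH,
    upstream_span: int = UPSTREAM_SPAN,
) -> list[GenomicInterval]:
    """Sample ``n`` positive windows (midpoint-centered) from eligible peaks."""
    peaks = all_tf_peaks[tf]
    other = {name: p for name, p in all_tf_peaks.items() if name != tf}
    upstream_trees = _build_trees([upstream_interval(t, upstream_span) for t in tss_list])

    eligible = []
    half = window_length // 2
    for peak in peaks:
        tree = upstream_trees.get(peak.chrom)
        if tree is None or not tree.overlap(peak.start, peak.end):
            continue
        if is_hot(peak, other):
            continue
        mid = peak.midpoint
        if mid - half < 0:
            continue
        eligible.append(
            GenomicInterval(peak.chrom, mid - half, mid + half, name=f"{tf}_pos")
        )
    if len(eligible) < n:
        raise ValueError(
            f"{tf}: only {len(eligible)} eligible peaks, {n} requested"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


def select_negative_windows(
    test_tf: str,
    positives_by_tf: Mapping[str, Sequence[GenomicInterval]],
    test_tf_peaks: Sequence[GenomicInterval],
    n: int,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Sample ``n`` windows from other TFs' positives not bound by the test TF.

    Any overlap with a test-TF peak, even a single base, disqualifies a
    candidate.
    """
    peak_trees = _build_trees(test_tf_peaks)
    pool: list[GenomicInterval] = []
    seen: set[tuple[str, int, int]] = set()
    for tf, windows in positives_by_tf.items():
        if tf == test_tf:
            continue
        for win in windows:
            key = (win.chrom, win.start, win.end)
            if key in seen:
                continue
            tree = peak_trees.get(win.chrom)
            if tree is not None and tree.overlap(win.start, win.end):
                continue
            seen.add(key)
            pool.append(GenomicInterval(win.chrom, win.start, win.end, name=f"{test_tf}_neg"))
    if len(pool) < n:
        raise ValueError(
            f"{test_tf}: negative pool has {len(pool)} windows, {n} requested"
        )
    pool.sort()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def split_train_test(
    windows: Sequence[LabeledWindow],
    seed: int = 0,
    test_fraction: float = 0.2,
) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Seeded balanced split: both partitions keep a 1:1 class ratio.

    2000 balanced windows split into 1600 train + 400 test.
    """
    positives = [w for w in windows if w.label == "positive"]
    negatives = [w for w in windows if w.label == "negative"]
    if len(positives) != len(negatives):
        raise ValueError(
            f"imbalanced input: {len(positives)} positives vs {len(negatives)} negatives"
        )
    n_test = int(round(test_fraction * len(positives)))
    rng = np.random.default_rng(seed)
    train: list[LabeledWindow] = []
    test: list[LabeledWindow] = []
    for group in (positives, negatives):
        order = rng.permutation(len(group))
        test.extend(group[i] for i in order[:n_test])
        train.extend(group[i] for i in order[n_test:])
    return train, test
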