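"""Single-motif thermodynamic occupancy model of TF-DNA binding.

A window is scanned on both strands for candidate sites of a PWM.  Each
candidate site at offset ``i`` gets a log-likelihood ratio (natural log)
against the background model,

    llr_i = sum_j ln( P[j, base_{i+j}] / bg[base_{i+j}] ),

and a relative affinity ``K_i = exp(llr_i - llr_consensus) <= 1``; the
consensus binding constant is absorbed into the single concentration
parameter ``tau``.  Sites further than ``eT`` natural-log units below the
consensus are discarded, and the predicted occupancy of the window is the
sum of independent fractional occupancies

    X = sum_i tau * K_i / (1 + tau * K_i),

i.e. the expected number of bound TF molecules under a factorized Boltzmann
model with no cooperativity and no overlap exclusion.  Training fits
``tau`` (grid search maximizing Pearson correlation with ChIP signal) and
the site-energy threshold ``eT`` (chosen on a held-out split).  Because the
Pearson objective is scale-free, the final linear calibration (reference
minimum -> 0, maximum -> 1) supplies the output scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .formats_io import BASES, GenomicInterval, Pwm, UNIFORM_BACKGROUND

DEFAULT_TAU_GRID: np.ndarray = np.logspace(-3.0, 3.0, 13)
DEFAULT_ET_GRID: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0, 8.0, float("inf"))
MIN_TRAIN_WINDOWS = 20

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def reverse_complement(sequence: str) -> str:
    table = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return sequence.translate(table)[::-1]


@dataclass(frozen=True)
class SiteHit:
    """One candidate binding site within a scanned window."""

    offset: int
    strand: str
    llr: float
    K: float


@dataclass
class LabeledWindow:
    """A training window: sequence, measured ChIP signal, class label."""

    sequence: str
    chip_signal: float
    label: str = "positive"
    location: GenomicInterval | None = None


def _score_matrices(pwm: Pwm, background: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position llr lookup tables for forward and reverse strands.

    Column 4 (unknown base) scores zero: N is treated as background.
    """
    with np.errstate(divide="ignore"):
        S = np.log(pwm.probs / background)
    S5 = np.column_stack([S, np.zeros(pwm.width)])
    # scoring the reverse complement of a site against the PWM is equivalent
    # to scoring the site against the reverse-complemented PWM
    S5_rc = S5[::-1][:, _COMPLEMENT]
    return S5, S5_rc


def consensus_llr(pwm: Pwm, background: np.ndarray | None = None) -> float:
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    with np.errstate(divide="ignore"):
        S = np.log(pwm.probs / bg)
    return float(S.max(axis=1).sum())


def llr_profiles(
    codes: np.ndarray, pwm: Pwm, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """llr of every placement on the forward and reverse strand.

    Entry ``i`` of each array scores the w-mer starting at offset ``i``.
    """
    w = pwm.width
    if codes.size < w:
        raise ValueError(f"sequence length {codes.size} shorter than motif width {w}")
    S5, S5_rc = _score_matrices(pwm, background)
    windows = sliding_window_view(codes, w)
    fwd = np.zeros(windows.shape[0])
    rev = np.zeros(windows.shape[0])
    for j in range(w):
        col = windows[:, j]
        fwd += S5[j, col]
        rev += S5_rc[j, col]
    return fwd, rev


def scan_sites(
    sequence: str, pwm: Pwm, background: np.ndarray | None = None
) -> list[SiteHit]:
    """Enumerate candidate sites of ``pwm`` on both strands of ``sequence``."""
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    codes = encode_sequence(sequence)
    fwd, rev = llr_profiles(codes, pwm, bg)
    llr_max = consensus_llr(pwm, bg)
    hits = []
    for strand, profile in (("+", fwd), ("-", rev)):
        for offset, llr in enumerate(profile):
            hits.append(
                SiteHit(offset, strand, float(llr), float(np.exp(llr - llr_max)))
            )
    return hits


@dataclass
class OccupancyModel:
    """A parameterized single-motif occupancy predictor."""

    pwm: Pwm
    tau: float
    eT: float
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    train_cc: float | None = None
    val_cc: float | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.eT < 0:
            raise ValueError(f"eT must be nonnegative, got {self.eT}")
        self.background = np.asarray(self.background, dtype=float)

    def occupancy(self, sequence: str) -> float:
        return float(predict_occupancy(sequence, self))

    def to_dict(self) -> dict:
        return {
            "pwm": self.pwm.to_dict(),
            "tau": self.tau,
            "eT": self.eT,
            "background": self.background.tolist(),
            "train_cc": self.train_cc,
            "val_cc": self.val_cc,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "OccupancyModel":
        return cls(
            pwm=Pwm.from_dict(d["pwm"]),
            tau=float(d["tau"]),
            eT=float(d["eT"]),
            background=np.asarray(d["background"], dtype=float),
            train_cc=d.get("train_cc"),
            val_cc=d.get("val_cc"),
        )


def _occupancy_from_llr(
    llr: np.ndarray, llr_max: float, tau: float, eT: float
) -> float:
    retained = llr >= llr_max - eT
    if not retained.any():
        return 0.0
    K = np.exp(llr[retained] - llr_max)
    x = tau * K
    return float((x / (1.0 + x)).sum())


def predict_occupancy(sequence: str, model: OccupancyModel) -> float:
    """Expected bound-TF count of a window under the occupancy model."""
    codes = encode_sequence(sequence)
    fwd, rev = llr_profiles(codes, model.pwm, model.background)
    llr = np.concatenate([fwd, rev])
    return _occupancy_from_llr(llr, consensus_llr(model.pwm, model.background),
                               model.tau, model.eT)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _padded_site_llrs(
    sequences: Sequence[str], pwm: Pwm, background: np.ndarray
) -> np.ndarray:
    """Per-window concatenated strand llr profiles, padded with -inf."""
    profiles = []
    for seq in sequences:
        fwd, rev = llr_profiles(encode_sequence(seq), pwm, background)
        profiles.append(np.concatenate([fwd, rev]))
    width = max(p.size for p in profiles)
    out = np.full((len(profiles), width), -np.inf)
    for i, p in enumerate(profiles):
        out[i, : p.size] = p
    return out


def _occupancy_matrix(
    llrs: np.ndarray, llr_max: float, tau_grid: np.ndarray, eT: float
) -> np.ndarray:
    """Occupancies, shape (n_tau, n_windows); -inf padding contributes zero."""
    with np.errstate(over="ignore"):
        K = np.exp(np.minimum(llrs - llr_max, 0.0))
    K = np.where(llrs >= llr_max - eT, K, 0.0)
    occ = np.empty((tau_grid.size, llrs.shape[0]))
    for t, tau in enumerate(tau_grid):
        x = tau * K
        occ[t] = (x / (1.0 + x)).sum(axis=1)
    return occ


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("-inf")
    return float(np.corrcoef(x, y)[0, 1])


def fit_stap(
    train: Sequence[LabeledWindow],
    pwm: Pwm,
    tau_grid: np.ndarray | None = None,
    eT_grid: Sequence[float] | None = None,
    background: np.ndarray | None = None,
    seed: int = 0,
    val_fraction: float = 0.2,
) -> OccupancyModel:
    """Fit (tau, eT) against ChIP signal by correlation-maximizing grid search.

    For each ``eT``, ``tau`` is chosen to maximize Pearson correlation on an
    80% split; ``eT`` is then chosen by correlation on the held-out 20%, and
    ``tau`` is re-optimized on all windows at the chosen ``eT``.  Exact ties
    resolve to the smallest ``tau``, then the largest (most permissive) ``eT``.
    """
    tau_grid = DEFAULT_TAU_GRID if tau_grid is None else np.asarray(tau_grid, float)
    eT_grid = DEFAULT_ET_GRID if eT_grid is None else tuple(eT_grid)
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)

    if len(train) < MIN_TRAIN_WINDOWS:
        raise ValueError(
            f"need >= {MIN_TRAIN_WINDOWS} training windows, got {len(train)}"
        )
    y = np.array([w.chip_signal for w in train], dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate target: constant chip_signal")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train))
    n_val = max(1, int(round(val_fraction * len(train))))
    val_idx, train_idx = order[:n_val], order[n_val:]

    llrs = _padded_site_llrs([w.sequence for w in train], pwm, bg)
    llr_max = consensus_llr(pwm, bg)

    best = None  # (val_cc, eT_index, tau)
    for e, eT in enumerate(eT_grid):
        occ = _occupancy_matrix(llrs, llr_max, tau_grid, eT)
        train_ccs = np.array(
            [_pearson(occ[t, train_idx], y[train_idx]) for t in range(tau_grid.size)]
        )
        t_best = int(np.argmax(train_ccs))  # ascending grid: ties -> smallest tau
        val_cc = _pearson(occ[t_best, val_idx], y[val_idx])
        # ties across eT resolve to the largest (most permissive) eT
        if best is None or val_cc >= best[0]:
            best = (val_cc, e, float(tau_grid[t_best]))
    assert best is not None
    val_cc, e_best, _ = best
    eT_final = float(eT_grid[e_best])

    # re-optimize tau on all windows at the chosen eT
    occ_all = _occupancy_matrix(llrs, llr_max, tau_grid, eT_final)
    all_ccs = np.array(
        [_pearson(occ_all[t], y) for t in range(tau_grid.size)]
    )
    t_final = int(np.argmax(all_ccs))
    return OccupancyModel(
        pwm=pwm,
        tau=float(tau_grid[t_final]),
        eT=eT_final,
        background=bg,
        train_cc=float(all_ccs[t_final]) if np.isfinite(all_ccs[t_final]) else None,
        val_cc=float(val_cc) if np.isfinite(val_cc) else None,
    )


# ---------------------------------------------------------------------------
# Linear [0, 1] calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearCalibration:
    """The affine map sending a reference score range onto exactly [0, 1].

    Scores of sequences outside the reference set may fall outside [0, 1];
    they are deliberately not clipped.
    """

    scale: float
    offset: float

    @classmethod
    def from_reference(cls, values: Iterable[float]) -> "LinearCalibration":
        arr = np.asarray(list(values), dtype=float)
        lo, hi = float(arr.min()), float(arr.max())
        if hi == lo:
            raise ValueError("degenerate calibration: reference max equals min")
        return cls(scale=1.0 / (hi - lo), offset=-lo / (hi - lo))

    @classmethod
    def identity(cls) -> "LinearCalibration":
        return cls(scale=1.0, offset=0.0)

    def __call__(self, x: float | np.ndarray):
        return self.scale * x + self.offset

    def to_dict(self) -> dict:
        return {"scale": self.scale, "offset": self.offset}

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearCalibration":
        return cls(scale=float(d["scale"]), offset=float(d["offset"]))


def predict_stap_score(
    sequence: str, model: OccupancyModel, calibration: LinearCalibration
) -> float:
    """Calibrated occupancy score of a window (not clipped to [0, 1])."""
    return float(calibration(predict_occupancy(sequence, model)))


@dataclass
class CalibratedStap:
    """An occupancy model together with its reference-set calibration."""

    model: OccupancyModel
    calibration: LinearCalibration

    def score(self, sequence: str) -> float:
        return predict_stap_score(sequence, self.model, self.calibration)

    @classmethod
    def train(
        cls,
        windows: Sequence[LabeledWindow],
        pwm: Pwm,
        reference: Sequence[LabeledWindow] | None = None,
        **fit_kwargs,
    ) -> "CalibratedStap":
        """Fit the occupancy model on ``windows`` and calibrate on ``reference``
        (default: the training windows themselves)."""
        model = fit_stap(windows, pwm, **fit_kwargs)
        ref = windows if reference is None else reference
        occupancies = [model.occupancy(w.sequence) for w in ref]
        return cls(model=model, calibration=LinearCalibration.from_reference(occupancies))

    def to_dict(self) -> dict:
        return {"model": self.model.to_dict(), "calibration": self.calibration.to_dict()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibratedStap":
        return cls(
            model=OccupancyModel.from_dict(d["model"]),
            calibration=LinearCalibration.from_dict(d["calibration"]),
        )
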