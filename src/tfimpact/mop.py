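"""Multi-motif occupancy prediction: fusing per-motif scores with SVR.

A TF frequently has several published motifs and none is known a priori to
be the best descriptor of its binding.  Each motif gets its own calibrated
occupancy submodel; the vector of calibrated per-motif scores of a window
is the feature vector of an epsilon support-vector regression (RBF kernel)
trained against measured ChIP signal.  The fused prediction is finally
mapped onto [0, 1] by the same reference-set linear calibration used for
single-motif scores, so the two scales are directly comparable.

Features are standardized (stored center/scale) before the kernel because
RBF distances are scale-sensitive; a constant feature gets unit scale so it
simply drops out of the kernel distance.  The fitted regression is stored
as explicit support vectors, dual coefficients, intercept and kernel width,
making re-prediction deterministic and the model JSON-serializable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVR

from .formats_io import Pwm
from .stap import CalibratedStap, LabeledWindow, LinearCalibration

DEFAULT_C = 1.0
DEFAULT_EPSILON = 0.1


@dataclass
class MopModel:
    """Per-TF fusion of calibrated single-motif occupancy scores."""

    tf_name: str
    submodels: list[CalibratedStap]
    center: np.ndarray
    scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    calibration: LinearCalibration

    def features(self, sequence: str) -> np.ndarray:
        if not self.submodels:
            raise ValueError("model has no submodels attached")
        return np.array([sm.score(sequence) for sm in self.submodels])

    def predict_raw(self, features: np.ndarray) -> np.ndarray:
        """Uncalibrated SVR prediction from a (n, d) feature matrix."""
        F = np.atleast_2d(np.asarray(features, dtype=float))
        if not np.all(np.isfinite(F)):
            raise ValueError("non-finite feature")
        Z = (F - self.center) / self.scale
        sq = (
            (Z**2).sum(axis=1)[:, None]
            + (self.support_vectors**2).sum(axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        kernel = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return kernel @ self.dual_coef + self.intercept

    def score(self, sequence: str) -> float:
        """Calibrated MOP score of a sequence (deterministic)."""
        raw = self.predict_raw(self.features(sequence)[None, :])[0]
        return float(self.calibration(raw))

    def to_dict(self) -> dict:
        return {
            "tf_name": self.tf_name,
            "submodels": [sm.to_dict() for sm in self.submodels],
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "calibration": self.calibration.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MopModel":
        return cls(
            tf_name=d["tf_name"],
            submodels=[CalibratedStap.from_dict(s) for s in d["submodels"]],
            center=np.asarray(d["center"], float),
            scale=np.asarray(d["scale"], float),
            support_vectors=np.asarray(d["support_vectors"], float),
            dual_coef=np.asarray(d["dual_coef"], float),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            calibration=LinearCalibration.from_dict(d["calibration"]),
        )


def build_feature_matrix(
    windows: Sequence[LabeledWindow], submodels: Sequence[CalibratedStap]
) -> np.ndarray:
    """Window x motif matrix of calibrated single-motif scores."""
    if not submodels:
        raise ValueError("empty submodel list")
    return np.array(
        [[sm.score(w.sequence) for sm in submodels] for w in windows]
    )


def fit_mop(
    features: np.ndarray,
    chip_signal: Sequence[float],
    seed: int = 0,
    tf_name: str = "",
    C: float = DEFAULT_C,
    epsilon: float = DEFAULT_EPSILON,
) -> MopModel:
    """Fit the epsilon-SVR fusion on a feature matrix.

    The returned model has no submodels attached and an identity
    calibration; :func:`train_mop` assembles the complete predictor.
    ``seed`` is accepted for interface uniformity; the SVR solve itself is
    deterministic.
    """
    F = np.asarray(features, dtype=float)
    y = np.asarray(chip_signal, dtype=float)
    if F.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if not np.all(np.isfinite(F)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite feature or target")
    if F.shape[0] != y.size:
        raise ValueError("feature/target length mismatch")
    if F.shape[0] < 4:
        raise ValueError("too few windows to fit the regression")

    center = F.mean(axis=0)
    scale = F.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)  # constant feature drops out
    Z = (F - center) / scale

    var = Z.var()
    gamma = 1.0 / (Z.shape[1] * var) if var > 0 else 1.0
    svr = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma)
    svr.fit(Z, y)
    return MopModel(
        tf_name=tf_name,
        submodels=[],
        center=center,
        scale=scale,
        support_vectors=svr.support_vectors_.copy(),
        dual_coef=svr.dual_coef_[0].copy(),
        intercept=float(svr.intercept_[0]),
        gamma=float(gamma),
        calibration=LinearCalibration.identity(),
    )


def train_mop(
    windows: Sequence[LabeledWindow],
    pwms: Sequence[Pwm],
    tf_name: str = "",
    reference: Sequence[LabeledWindow] | None = None,
    seed: int = 0,
    **stap_kwargs,
) -> MopModel:
    """Train the full per-TF predictor: one occupancy submodel per motif,
    SVR fusion of their calibrated scores, and the [0, 1] calibration of the
    fused score over the reference window set (default: the training set)."""
    ref = windows if reference is None else reference
    submodels = [
        CalibratedStap.train(windows, pwm, reference=ref, seed=seed, **stap_kwargs)
        for pwm in pwms
    ]
    features = build_feature_matrix(windows, submodels)
    targets = [w.chip_signal for w in windows]
    model = fit_mop(features, targets, seed=seed, tf_name=tf_name)
    model.submodels = list(submodels)
    ref_raw = model.predict_raw(build_feature_matrix(ref, submodels))
    model.calibration = LinearCalibration.from_reference(ref_raw)
    return model


def predict_mop(sequence: str, mop: MopModel) -> float:
    """Calibrated MOP binding score of a sequence."""
    return mop.score(sequence)
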