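"""Shift referencing and systematic coupling offsets.

Raw isotropic shieldings σ (ppm) from electronic-structure calculations
are converted to chemical shifts δ by the linear scaling method: a line
σ = slope·δ + intercept is fitted on reference data by ordinary least
squares, and predictions are referenced by inverting it,
δ = (σ − intercept)/slope.  Computed one-bond couplings can carry a
systematic offset relative to experiment; the constant correction
offset = mean(expt − pred) is fitted and added elementwise.

Both calibrations are optional and sit upstream of training: the pipeline
accepts either raw shieldings plus a fitted scaling, or labels that are
already referenced shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import SHIFT_PARAMS

__all__ = [
    "LinearScaling",
    "OffsetCorrection",
    "fit_scaling",
    "shielding_to_shift",
    "shift_to_shielding",
    "fit_offset",
    "apply_offset",
]


@dataclass(frozen=True)
class LinearScaling:
    """σ = slope·δ + intercept for one shift parameter."""

    param: str
    slope: float
    intercept: float  # ppm

    def __post_init__(self):
        if self.param not in SHIFT_PARAMS:
            raise ValueError(f"scaling applies to shift parameters, not {self.param!r}")
        if self.slope == 0 or not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("slope must be finite and nonzero")


@dataclass(frozen=True)
class OffsetCorrection:
    """Additive correction (Hz) for predicted one-bond couplings."""

    param: str = "j1_CH"
    offset: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.offset):
            raise ValueError("offset must be finite")


def fit_scaling(shieldings, shifts, param: str) -> LinearScaling:
    """OLS fit of shielding on shift: σ = slope·δ + intercept.

    Requires ≥ 2 paired points and non-degenerate shifts (not all equal).
    """
    sig = np.asarray(shieldings, dtype=float)
    dlt = np.asarray(shifts, dtype=float)
    if sig.shape != dlt.shape or sig.ndim != 1:
        raise ValueError("shieldings and shifts must be paired 1-D sequences")
    if len(sig) < 2:
        raise ValueError("need at least 2 calibration points")
    if np.ptp(dlt) == 0:
        raise ValueError("degenerate calibration set: all shifts equal")
    slope, intercept = np.polyfit(dlt, sig, 1)
    return LinearScaling(param, float(slope), float(intercept))


def shielding_to_shift(sigma, sc: LinearScaling):
    """δ = (σ − intercept)/slope; accepts scalars or arrays."""
    return (np.asarray(sigma, dtype=float) - sc.intercept) / sc.slope


def shift_to_shielding(delta, sc: LinearScaling):
    """Exact inverse of :func:`shielding_to_shift`."""
    return np.asarray(delta, dtype=float) * sc.slope + sc.intercept


def fit_offset(pred, expt, param: str = "j1_CH") -> OffsetCorrection:
    """Constant correction offset = mean(expt − pred)."""
    pred = np.asarray(pred, dtype=float)
    expt = np.asarray(expt, dtype=float)
    if pred.shape != expt.shape or pred.ndim != 1 or len(pred) < 1:
        raise ValueError("pred and expt must be non-empty paired 1-D sequences")
    return OffsetCorrection(param, float(np.mean(expt - pred)))


def apply_offset(pred, oc: OffsetCorrection):
    return np.asarray(pred, dtype=float) + oc.offset
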