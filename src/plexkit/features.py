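"""Fiducial points and kinetic features of a fitted amplification curve.

The fitted sigmoid is a smooth stand-in for the raw trace, so every feature
is computed from closed-form F, F' and F'' rather than from noisy finite
differences.  Fiducial points:

* ``x_ms`` — location of the maximum slope; closed form ``Cs + ln(As)/Sc``.
* ``x_s`` / ``x_e`` — the two crossings of ``F'(t) = TH * F'(x_ms)`` that
  bracket ``x_ms``; they mark the start of the exponential phase and of the
  plateau.  TH is a small relative threshold (default 5% of the max slope),
  which keeps the crossings invariant to fluorescence rescaling.
* ``x_p1`` / ``x_p2`` — the positive and negative peaks of F'', linked to
  the accelerating and plateauing periods.

From these, eight derived features describe reaction speed (spans, maximum
slope, curvature peaks) and the asymmetry between the exponential and
plateau phases (span ratio, area ratio via the fundamental-theorem identity
A = F(b) - F(a), curvature ratio).  Together with the five fitted
parameters this gives a 13-dimensional kinetic feature vector whose shape
components are invariant to template concentration (which only shifts Cs)
— the property the downstream selection criteria test explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .curve_model import (
    SigmoidParams,
    eval_first_derivative,
    eval_second_derivative,
    eval_sigmoid,
)

__all__ = [
    "FeatureConfig",
    "FiducialPoints",
    "FEATURE_NAMES",
    "DEFAULT_SELECTED_FEATURES",
    "locate_fiducials",
    "extract_features",
    "standardize_features",
    "destandardize_features",
]

#: canonical feature order: 5 fitted parameters + 8 derived kinetic features
FEATURE_NAMES = (
    "fm",
    "fb",
    "sc",
    "cs",
    "asym",
    "span_exp",
    "span_p",
    "slope_ms",
    "curv_p1",
    "neg_curv_p2",
    "asym_span",
    "asym_area",
    "asym_curv",
)

#: default concentration-robust set used for multi-feature strategies
DEFAULT_SELECTED_FEATURES = ("slope_ms", "curv_p1", "neg_curv_p2", "sc")


@dataclass
class FeatureConfig:
    th_fraction: float = 0.05
    selected_features: tuple[str, ...] = DEFAULT_SELECTED_FEATURES

    def __post_init__(self) -> None:
        if not (0.0 < self.th_fraction < 1.0):
            raise ValueError(f"th_fraction must be in (0, 1), got {self.th_fraction}")
        unknown = set(self.selected_features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature name(s): {sorted(unknown)}")


@dataclass
class FiducialPoints:
    x_s: float
    x_ms: float
    x_e: float
    x_p1: float
    x_p2: float
    slope_ms: float
    curv_p1: float
    curv_p2: float


class FiducialError(RuntimeError):
    """Raised when a fiducial point cannot be bracketed."""


def _bracket_outward(fprime, th_abs: float, x_ms: float, step: float, direction: int) -> float:
    """Walk outward from x_ms until F' falls below the threshold."""
    x = x_ms
    for _ in range(200):
        x += direction * step
        if fprime(x) < th_abs:
            return x
        step *= 1.5
    raise FiducialError(
        f"could not bracket the TH crossing on the "
        f"{'left' if direction < 0 else 'right'} of x_ms"
    )


def locate_fiducials(params: SigmoidParams, config: FeatureConfig | None = None) -> FiducialPoints:
    """Locate the five fiducial points of a fitted curve.

    ``x_ms`` uses the closed form; the TH crossings are found by bracketed
    root-finding on each side, and the second-derivative peaks by bounded
    1-D optimization on either side of ``x_ms``.
    """
    config = config or FeatureConfig()
    sc, asym = params.sc, params.asym
    x_ms = params.cs + math.log(asym) / sc
    slope_ms = eval_first_derivative(params, x_ms)
    if not slope_ms > 0:
        raise FiducialError("maximum slope is not positive; degenerate parameters")
    th_abs = config.th_fraction * slope_ms

    fprime = lambda t: eval_first_derivative(params, t)
    step = 1.0 / sc
    left = _bracket_outward(fprime, th_abs, x_ms, step, -1)
    right = _bracket_outward(fprime, th_abs, x_ms, step, +1)
    x_s = brentq(lambda t: fprime(t) - th_abs, left, x_ms, xtol=1e-12, rtol=1e-14)
    x_e = brentq(lambda t: fprime(t) - th_abs, x_ms, right, xtol=1e-12, rtol=1e-14)

    f2 = lambda t: eval_second_derivative(params, t)
    span = 60.0 / sc
    res1 = minimize_scalar(lambda t: -f2(t), bounds=(x_ms - span, x_ms), method="bounded",
                           options={"xatol": 1e-10})
    res2 = minimize_scalar(f2, bounds=(x_ms, x_ms + span), method="bounded",
                           options={"xatol": 1e-10})
    if not (res1.success and res2.success):
        raise FiducialError("bounded optimization of the curvature peaks failed")
    x_p1, x_p2 = float(res1.x), float(res2.x)
    curv_p1, curv_p2 = f2(x_p1), f2(x_p2)
    if not (curv_p1 > 0 and curv_p2 < 0):
        raise FiducialError("curvature peaks have unexpected signs; degenerate parameters")

    pts = FiducialPoints(x_s=float(x_s), x_ms=float(x_ms), x_e=float(x_e),
                         x_p1=x_p1, x_p2=x_p2,
                         slope_ms=float(slope_ms), curv_p1=float(curv_p1),
                         curv_p2=float(curv_p2))
    if not (pts.x_s < pts.x_ms < pts.x_e and pts.x_p1 < pts.x_ms < pts.x_p2):
        raise FiducialError("fiducial ordering violated; degenerate parameters")
    return pts


def extract_features(params: SigmoidParams, config: FeatureConfig | None = None) -> dict[str, float]:
    """Compute the named kinetic feature vector for one fitted curve.

    Returns a mapping containing the 13 canonical features plus the two
    phase areas ``a1`` (fluorescence rise over [x_s, x_ms]) and ``a2``
    (rise over [x_ms, x_e]) used by the area-asymmetry ratio.
    """
    pts = locate_fiducials(params, config)
    f = lambda t: eval_sigmoid(params, t)
    a1 = f(pts.x_ms) - f(pts.x_s)
    a2 = f(pts.x_e) - f(pts.x_ms)
    feats = {
        "fm": params.fm,
        "fb": params.fb,
        "sc": params.sc,
        "cs": params.cs,
        "asym": params.asym,
        "span_exp": pts.x_e - pts.x_s,
        "span_p": pts.x_p2 - pts.x_p1,
        "slope_ms": pts.slope_ms,
        "curv_p1": pts.curv_p1,
        "neg_curv_p2": -pts.curv_p2,
        "asym_span": (pts.x_e - pts.x_ms) / (pts.x_ms - pts.x_s),
        "asym_area": a2 / a1,
        "asym_curv": -pts.curv_p1 / pts.curv_p2,
        "a1": a1,
        "a2": a2,
    }
    bad = [k for k, v in feats.items() if not np.isfinite(v)]
    if bad:
        raise FiducialError(f"non-finite feature value(s): {bad}")
    return feats


def standardize_features(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Standardize each feature column to mean 0, population std 1.

    Returns ``(standardized, mean, std)``.  Population (ddof=0) convention.
    Raises on fewer than two rows or on a zero-variance column, naming it.
    """
    if len(matrix) < 2:
        raise ValueError("standardization needs at least 2 curves")
    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0, ddof=0)
    zero = std.index[std == 0].tolist()
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    return (matrix - mean) / std, mean, std


def destandardize_features(standardized: pd.DataFrame, mean: pd.Series, std: pd.Series) -> pd.DataFrame:
    """Inverse of :func:`standardize_features`."""
    return standardized * std + mean
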