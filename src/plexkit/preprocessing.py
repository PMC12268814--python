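"""Curve-level quality filtering before feature extraction.

Removes the reaction classes that carry no target-specific kinetic
information: no-template controls and flat traces, low-gain traces,
curves the sigmoid cannot fit, and low-efficiency reactions (shallow
slope).  Three configurable gates, applied in order:

1. relative gain ``(max - min) / min >= gain_min``;
2. fit converged with ``r_squared >= r2_min``;
3. fitted slope coefficient ``Sc >= sc_min``.

This is a deterministic, auditable re-specification of the role of
unsupervised adaptive-mapping filtering used on digital-PCR panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curve_model import AmplificationCurve, FitResult

__all__ = ["FilterConfig", "FilterReport", "filter_curves"]

#: gain below which a curve is called flat rather than merely low-gain
_FLAT_GAIN = 0.02


@dataclass
class FilterConfig:
    gain_min: float = 0.10
    r2_min: float = 0.99
    sc_min: float = 0.1


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    rejected: list[tuple[str, str]]  # (curve_id, reason)

    def __post_init__(self) -> None:
        assert self.n_kept + len(self.rejected) == self.n_input


def _reject_reason(curve: AmplificationCurve, fit: FitResult, cfg: FilterConfig) -> str | None:
    f = curve.fluorescence
    f_min, f_max = float(np.min(f)), float(np.max(f))
    gain = (f_max - f_min) / max(f_min, 1e-12)
    if gain < cfg.gain_min:
        return "flat" if gain < _FLAT_GAIN else "low_gain"
    if not fit.converged or fit.r_squared < cfg.r2_min:
        return "poor_fit"
    if fit.params.sc < cfg.sc_min:
        return "low_efficiency"
    return None


def filter_curves(
    curves: list[AmplificationCurve],
    fits: dict[str, FitResult] | list[FitResult],
    config: FilterConfig | None = None,
) -> tuple[list[AmplificationCurve], FilterReport]:
    """Apply the three quality gates; returns kept curves and a report.

    ``fits`` maps ``curve_id`` to the curve's fit attempt (a parallel list
    is also accepted).  Every curve must have a fit attempt.
    """
    config = config or FilterConfig()
    if not isinstance(fits, dict):
        if len(fits) != len(curves):
            raise ValueError("fits list must parallel curves")
        fits = {c.curve_id: r for c, r in zip(curves, fits)}
    missing = [c.curve_id for c in curves if c.curve_id not in fits]
    if missing:
        raise ValueError(f"curves without a fit attempt: {missing[:5]}")

    kept: list[AmplificationCurve] = []
    rejected: list[tuple[str, str]] = []
    for curve in curves:
        reason = _reject_reason(curve, fits[curve.curve_id], config)
        if reason is None:
            kept.append(curve)
        else:
            rejected.append((curve.curve_id, reason))
    return kept, FilterReport(n_input=len(curves), n_kept=len(kept), rejected=rejected)
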