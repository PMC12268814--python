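"""Five-parameter asymmetric sigmoid model for real-time amplification curves.

The fluorescence of a PCR amplification curve is modelled as

    F(t) = Fm / (1 + exp(-Sc (t - Cs)))**As + Fb

where ``t`` is the cycle index (or time stamp), ``Fm`` the maximum
fluorescence rise above baseline, ``Fb`` the baseline fluorescence, ``Sc``
a slope coefficient governing the maximum reaction speed, ``Cs`` the curve
centre linked to the cycle threshold (Ct), and ``As`` a dimensionless
asymmetry index (``As = 1`` recovers the symmetric logistic).

The first and second derivatives have closed forms (with
``u = exp(-Sc (t - Cs))``):

    F'(t)  = Fm Sc As u / (1 + u)**(As + 1)
    F''(t) = Fm Sc^2 As u (As u - 1) / (1 + u)**(As + 2)

All evaluations are overflow-safe: they are computed in log space so that
deep tails return the exact asymptote instead of a numeric fault.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SigmoidParams",
    "AmplificationCurve",
    "FitConfig",
    "FitResult",
    "eval_sigmoid",
    "eval_first_derivative",
    "eval_second_derivative",
    "fit_curve",
]

PARAM_NAMES = ("fm", "fb", "sc", "cs", "asym")


@dataclass(frozen=True)
class SigmoidParams:
    """Parameter vector of the 5-parameter sigmoid.

    Attributes
    ----------
    fm : float
        Maximum fluorescence above baseline (a.u.); must be > 0.
    fb : float
        Baseline fluorescence (a.u.).
    sc : float
        Slope coefficient (per cycle); must be > 0.
    cs : float
        Curve centre (cycles), linked to the cycle threshold.
    asym : float
        Asymmetry index (dimensionless); must be > 0.
    """

    fm: float
    fb: float
    sc: float
    cs: float
    asym: float

    def __post_init__(self) -> None:
        if not (self.fm > 0):
            raise ValueError(f"fm must be > 0, got {self.fm}")
        if not (self.sc > 0):
            raise ValueError(f"sc must be > 0, got {self.sc}")
        if not (self.asym > 0):
            raise ValueError(f"asym must be > 0, got {self.asym}")

    def as_array(self) -> np.ndarray:
        return np.array([self.fm, self.fb, self.sc, self.cs, self.asym])

    @classmethod
    def from_array(cls, p: Sequence[float]) -> "SigmoidParams":
        fm, fb, sc, cs, asym = (float(v) for v in p)
        return cls(fm=fm, fb=fb, sc=sc, cs=cs, asym=asym)

    def to_dict(self) -> dict[str, float]:
        return {"fm": self.fm, "fb": self.fb, "sc": self.sc, "cs": self.cs, "asym": self.asym}


@dataclass
class AmplificationCurve:
    """One well's (or partition's) cycle-indexed fluorescence trace."""

    curve_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    target: str | None = None
    primer_set: str | None = None
    concentration: float | str | None = None
    panel_id: str | None = None
    reaction_type: str | None = None  # singleplex | multiplex | ntc

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.shape != self.fluorescence.shape:
            raise ValueError(
                f"curve {self.curve_id!r}: cycles and fluorescence have different "
                f"lengths ({self.cycles.size} vs {self.fluorescence.size})"
            )
        if self.cycles.size < 20:
            raise ValueError(
                f"curve {self.curve_id!r}: need at least 20 cycles, got {self.cycles.size}"
            )
        if not np.all(np.diff(self.cycles) > 0):
            raise ValueError(f"curve {self.curve_id!r}: cycles must be strictly increasing")


@dataclass
class FitConfig:
    """Nonlinear least-squares settings for :func:`fit_curve`."""

    ftol: float = 1e-10
    max_nfev: int = 5000


@dataclass
class FitResult:
    params: SigmoidParams | None
    rss: float
    r_squared: float
    converged: bool
    n_iter: int = 0


def _log1p_exp(z: np.ndarray) -> np.ndarray:
    """log(1 + exp(z)), overflow-safe."""
    return np.logaddexp(0.0, z)


def eval_sigmoid(params: SigmoidParams, t) -> np.ndarray | float:
    """Evaluate F(t); returns the exact asymptotes in both tails."""
    t_arr = np.asarray(t, dtype=float)
    z = params.sc * (t_arr - params.cs)  # note: u = exp(-z)
    # (1+e^{-z})^{-As} = exp(-As * log1p(e^{-z}))
    val = params.fm * np.exp(-params.asym * _log1p_exp(-z)) + params.fb
    return val if np.ndim(t) else float(val)


def eval_first_derivative(params: SigmoidParams, t) -> np.ndarray | float:
    """Closed-form F'(t) = Fm Sc As u / (1+u)^(As+1), u = e^{-Sc(t-Cs)}."""
    t_arr = np.asarray(t, dtype=float)
    z = -params.sc * (t_arr - params.cs)  # u = exp(z)
    log_term = z - (params.asym + 1.0) * _log1p_exp(z)
    val = params.fm * params.sc * params.asym * np.exp(log_term)
    return val if np.ndim(t) else float(val)


def eval_second_derivative(params: SigmoidParams, t) -> np.ndarray | float:
    """Closed-form F''(t) = Fm Sc^2 As u (As u - 1) / (1+u)^(As+2)."""
    t_arr = np.asarray(t, dtype=float)
    asym = params.asym
    z = -params.sc * (t_arr - params.cs)  # u = exp(z)
    lse = _log1p_exp(z)
    # split u(As u - 1)/(1+u)^(As+2) into two stable exponentials
    val = (
        params.fm
        * params.sc**2
        * asym
        * (asym * np.exp(2.0 * z - (asym + 2.0) * lse) - np.exp(z - (asym + 2.0) * lse))
    )
    return val if np.ndim(t) else float(val)


def _model(p: np.ndarray, t: np.ndarray) -> np.ndarray:
    fm, fb, sc, cs, asym = p
    z = -sc * (t - cs)
    return fm * np.exp(-asym * _log1p_exp(z)) + fb


def _jacobian(p: np.ndarray, t: np.ndarray, f: np.ndarray) -> np.ndarray:
    fm, fb, sc, cs, asym = p
    z = -sc * (t - cs)  # u = exp(z)
    lse = _log1p_exp(z)
    e_term = np.exp(-asym * lse)  # (1+u)^{-As}
    dE_dz = -asym * np.exp(z - (asym + 1.0) * lse)  # d(1+u)^{-As}/dz
    jac = np.empty((t.size, 5))
    jac[:, 0] = e_term  # d/dFm
    jac[:, 1] = 1.0  # d/dFb
    jac[:, 2] = fm * dE_dz * (-(t - cs))  # d/dSc via dz/dSc
    jac[:, 3] = fm * dE_dz * sc  # d/dCs via dz/dCs
    jac[:, 4] = -fm * e_term * lse  # d/dAs
    return jac


def fit_curve(curve: AmplificationCurve, config: FitConfig | None = None) -> FitResult:
    """Fit the 5-parameter sigmoid to one curve by nonlinear least squares.

    Initialization is data-driven (baseline from the minimum, amplitude from
    the range, centre from the half-maximum crossing, slope from the maximal
    finite-difference gradient) and the optimizer runs inside bounds that
    exclude degenerate regimes while admitting strong asymmetry. On failure
    (flat curve, optimizer breakdown) a non-converged :class:`FitResult` is
    returned; exceptions are raised only for malformed input.
    """
    config = config or FitConfig()
    t = curve.cycles
    f = curve.fluorescence

    f_min, f_max = float(np.min(f)), float(np.max(f))
    f_range = f_max - f_min
    if f_range <= 0 or not np.isfinite(f_range):
        return FitResult(params=None, rss=float(np.sum((f - f.mean()) ** 2)),
                         r_squared=0.0, converged=False)

    # half-maximum crossing for the centre
    half = (f_max + f_min) / 2.0
    above = np.nonzero(f >= half)[0]
    cs0 = float(t[above[0]]) if above.size else float(t[t.size // 2])
    grad = np.gradient(f, t)
    sc0 = float(np.clip(4.0 * np.max(grad) / f_range, 1e-3, 10.0))
    x0 = np.array([f_range, f_min, sc0, cs0, 1.0])

    lower = np.array([1e-9 * f_range, f_min - f_range, 1e-6, t[0] - 10.0, 0.01])
    upper = np.array([10.0 * f_range, f_max, 10.0, t[-1] + 10.0, 20.0])
    x0 = np.clip(x0, lower, upper)

    try:
        sol = least_squares(
            lambda p: _model(p, t) - f,
            x0,
            jac=lambda p: _jacobian(p, t, f),
            bounds=(lower, upper),
            method="trf",
            ftol=config.ftol,
            xtol=config.ftol,
            gtol=None,
            max_nfev=config.max_nfev,
        )
    except Exception:
        return FitResult(params=None, rss=math.inf, r_squared=-math.inf, converged=False)

    rss = float(np.sum(sol.fun**2))
    tss = float(np.sum((f - f.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else 0.0
    converged = bool(sol.success) and np.isfinite(r_squared)
    params = SigmoidParams.from_array(sol.x) if converged else None
    return FitResult(params=params, rss=rss, r_squared=r_squared,
                     converged=converged, n_iter=int(sol.nfev))
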