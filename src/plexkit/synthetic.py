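"""Seeded generator of amplification-curve datasets.

Emulates the statistical structure of real-time digital-PCR dilution
series without any wet-lab data:

* each (target, primer set) has a characteristic mean sigmoid parameter
  vector; per-curve parameters jitter around it lognormally at small
  coefficients of variation (positivity-preserving);
* template concentration only shifts the curve centre ``Cs`` by
  ``ct_shift_per_log10`` cycles per 10-fold dilution (default 3.32, the
  perfect-efficiency value); the shape parameters (``Sc``, ``As``) are
  drawn independently of concentration, which is precisely the property
  the concentration-robustness criterion tests;
* multiplex reactions attenuate ``Fm`` and ``Sc`` by fixed factors with a
  small multiplicative jitter, producing the near-linear
  singleplex-to-multiplex feature relationship the transferability
  criterion requires;
* contaminants — flat/NTC traces, low-gain traces and low-efficiency
  (shallow-slope) curves — are generated with ground-truth type labels so
  the quality filter can be audited.

Fluorescence noise is additive Gaussian with standard deviation
``noise_sigma_rel * Fm`` (default 0.5%).  A fixed seed makes every output
byte-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curve_model import AmplificationCurve, SigmoidParams, eval_sigmoid

__all__ = [
    "TargetKineticProfile",
    "ScenarioConfig",
    "generate_singleplex",
    "generate_multiplex",
    "generate_contaminants",
    "preset_7plex",
    "curves_to_frames",
]

DEFAULT_CV = {"fm": 0.05, "fb": 0.02, "sc": 0.03, "cs": 0.01, "asym": 0.05}


@dataclass
class TargetKineticProfile:
    target: str
    primer_sets: dict[str, SigmoidParams]  # primer-set id -> mean parameters
    cv: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CV))
    ct_shift_per_log10: float = 3.32

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cv.values()):
            raise ValueError("coefficients of variation must be >= 0")


@dataclass
class ScenarioConfig:
    profiles: list[TargetKineticProfile]
    concentrations: list[float] = field(default_factory=lambda: [1e2, 1e3, 1e4, 1e5])
    ref_concentration: float = 1e5
    n_curves: int = 10  # per (target, primer set, concentration)
    n_cycles: int = 45
    noise_sigma_rel: float = 0.005
    alpha_fm: float = 0.8  # multiplex Fm attenuation
    beta_sc: float = 0.8  # multiplex Sc attenuation
    attenuation_jitter: float = 0.02
    contamination: dict[str, float] = field(
        default_factory=lambda: {"flat": 0.0, "low_gain": 0.0, "low_efficiency": 0.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("scenario needs at least one target profile")
        if not (0 < self.alpha_fm <= 1 and 0 < self.beta_sc <= 1):
            raise ValueError("attenuation factors must lie in (0, 1]")
        if any(not (0 <= f <= 1) for f in self.contamination.values()):
            raise ValueError("contamination fractions must lie in [0, 1]")

    @property
    def cycle_grid(self) -> np.ndarray:
        return np.arange(1, self.n_cycles + 1, dtype=float)

    def targets(self) -> list[str]:
        return [p.target for p in self.profiles]

    def primer_sets(self) -> dict[str, list[str]]:
        return {p.target: sorted(p.primer_sets) for p in self.profiles}


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with the requested CV."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def _draw_params(
    rng: np.random.Generator,
    mean: SigmoidParams,
    cv: dict[str, float],
    cs_shift: float,
) -> SigmoidParams:
    vals = {
        name: getattr(mean, name) * _lognormal_factor(rng, cv.get(name, 0.0))
        for name in ("fm", "fb", "sc", "cs", "asym")
    }
    vals["cs"] += cs_shift
    return SigmoidParams(**vals)


def _synthesize(
    rng: np.random.Generator,
    params: SigmoidParams,
    grid: np.ndarray,
    noise_sigma_rel: float,
) -> np.ndarray:
    f = eval_sigmoid(params, grid)
    if noise_sigma_rel > 0:
        f = f + rng.normal(0.0, noise_sigma_rel * params.fm, size=grid.size)
    return f


def _generate(
    scenario: ScenarioConfig,
    reaction_type: str,
    assignment: dict[str, str] | None,
    seed_offset: int,
) -> tuple[list[AmplificationCurve], pd.DataFrame]:
    rng = np.random.default_rng(scenario.seed + seed_offset)
    grid = scenario.cycle_grid
    curves: list[AmplificationCurve] = []
    meta_rows: list[dict] = []
    tag = "sp" if reaction_type == "singleplex" else "mp"
    for profile in scenario.profiles:
        sets = sorted(profile.primer_sets)
        if assignment is not None:
            sets = [assignment[profile.target]]
        for primer_set in sets:
            mean = profile.primer_sets[primer_set]
            if reaction_type == "multiplex":
                jit = scenario.attenuation_jitter
                mean = replace(
                    mean,
                    fm=mean.fm * scenario.alpha_fm * (1.0 + jit * rng.standard_normal()),
                    sc=mean.sc * scenario.beta_sc * (1.0 + jit * rng.standard_normal()),
                )
            for conc in scenario.concentrations:
                shift = profile.ct_shift_per_log10 * np.log10(
                    scenario.ref_concentration / conc
                )
                for i in range(scenario.n_curves):
                    p = _draw_params(rng, mean, profile.cv, shift)
                    f = _synthesize(rng, p, grid, scenario.noise_sigma_rel)
                    cid = f"{tag}_{profile.target}_{primer_set}_c{conc:g}_{i:03d}"
                    curves.append(
                        AmplificationCurve(
                            curve_id=cid,
                            cycles=grid.copy(),
                            fluorescence=f,
                            target=profile.target,
                            primer_set=primer_set,
                            concentration=conc,
                            panel_id=f"{tag}_{profile.target}_c{conc:g}",
                            reaction_type=reaction_type,
                        )
                    )
                    meta_rows.append(
                        {
                            "curve_id": cid,
                            "target": profile.target,
                            "primer_set": primer_set,
                            "concentration": conc,
                            "panel_id": f"{tag}_{profile.target}_c{conc:g}",
                            "reaction_type": reaction_type,
                        }
                    )
    return curves, pd.DataFrame(meta_rows)


def generate_singleplex(scenario: ScenarioConfig) -> tuple[list[AmplificationCurve], pd.DataFrame]:
    """Singleplex dilution-series curves for every (target, primer set)."""
    return _generate(scenario, "singleplex", None, seed_offset=0)


def generate_multiplex(
    scenario: ScenarioConfig, candidate
) -> tuple[list[AmplificationCurve], pd.DataFrame]:
    """Multiplex curves for one candidate mix, with kinetic attenuation."""
    assignment = dict(candidate.assignment)
    missing = [t for t in assignment if t not in {p.target for p in scenario.profiles}]
    if missing:
        raise ValueError(f"candidate targets not covered by scenario: {missing}")
    return _generate(scenario, "multiplex", assignment, seed_offset=1)


def generate_contaminants(scenario: ScenarioConfig) -> tuple[list[AmplificationCurve], pd.DataFrame]:
    """Flat/NTC, low-gain and low-efficiency curves with ground-truth labels.

    Counts are ``fraction * total clean singleplex curves`` per type.
    """
    rng = np.random.default_rng(scenario.seed + 2)
    grid = scenario.cycle_grid
    n_clean = (
        sum(len(p.primer_sets) for p in scenario.profiles)
        * len(scenario.concentrations)
        * scenario.n_curves
    )
    typical_fm = float(np.mean([ps.fm for p in scenario.profiles for ps in p.primer_sets.values()]))
    typical_fb = float(np.mean([ps.fb for p in scenario.profiles for ps in p.primer_sets.values()]))
    curves: list[AmplificationCurve] = []
    meta_rows: list[dict] = []
    for kind in ("flat", "low_gain", "low_efficiency"):
        n = int(round(scenario.contamination.get(kind, 0.0) * n_clean))
        for i in range(n):
            if kind == "flat":
                f = typical_fb + rng.normal(0.0, 0.002 * typical_fb, size=grid.size)
            elif kind == "low_gain":
                # full sigmoid whose amplitude is a few % of its baseline
                p = SigmoidParams(
                    fm=0.06 * typical_fb, fb=typical_fb, sc=0.6,
                    cs=grid[-1] * 0.7, asym=1.0,
                )
                f = _synthesize(rng, p, grid, scenario.noise_sigma_rel)
            else:  # low_efficiency: shallow slope, far below any real assay
                p = SigmoidParams(
                    fm=typical_fm, fb=typical_fb, sc=0.03,
                    cs=grid[-1] * 0.6, asym=1.0,
                )
                f = _synthesize(rng, p, grid, scenario.noise_sigma_rel)
            cid = f"cont_{kind}_{i:03d}"
            curves.append(
                AmplificationCurve(
                    curve_id=cid, cycles=grid.copy(), fluorescence=f,
                    target=None, primer_set=None, concentration=None,
                    panel_id=None, reaction_type="ntc",
                )
            )
            meta_rows.append(
                {
                    "curve_id": cid, "target": "", "primer_set": "",
                    "concentration": "", "panel_id": "",
                    "reaction_type": "ntc", "contaminant": kind,
                }
            )
    return curves, pd.DataFrame(meta_rows)


def preset_7plex(seed: int = 0, n_curves: int = 10) -> ScenarioConfig:
    """Bundled 7-target respiratory-panel-like scenario.

    Seven targets, two candidate primer sets each (2^7 = 128 candidate
    mixes), four concentrations spanning three decades.  Kinetic means are
    spread so targets are separable on the shape features while primer
    sets of one target differ moderately — the regime the ranking
    strategies are designed to discriminate in.
    """
    targets = ["FluA", "FluB", "RSV", "AdV", "PIV", "hMPV", "RV"]
    base_sc = [0.55, 0.68, 0.80, 0.92, 1.05, 1.18, 1.32]
    base_fm = [900.0, 1150.0, 1400.0, 1700.0, 2050.0, 2450.0, 2900.0]
    base_as = [0.7, 0.95, 1.25, 1.6, 2.0, 2.5, 3.1]
    base_cs = [24.0, 25.0, 23.5, 26.0, 24.5, 25.5, 23.0]
    profiles = []
    for i, t in enumerate(targets):
        mean_a = SigmoidParams(
            fm=base_fm[i], fb=100.0, sc=base_sc[i], cs=base_cs[i], asym=base_as[i]
        )
        # the second primer set is a slightly less efficient variant
        mean_b = SigmoidParams(
            fm=0.9 * base_fm[i], fb=100.0, sc=0.93 * base_sc[i],
            cs=base_cs[i] + 0.8, asym=1.08 * base_as[i],
        )
        profiles.append(
            TargetKineticProfile(target=t, primer_sets={"A": mean_a, "B": mean_b})
        )
    return ScenarioConfig(profiles=profiles, seed=seed, n_curves=n_curves)


def attenuation_10set_scenario(seed: int = 0, n_curves: int = 20) -> ScenarioConfig:
    """Five targets x two primer sets (10 sets) at a fixed concentration.

    Used to probe the singleplex-to-multiplex transferability of features:
    the multiplex generator attenuates Fm and Sc by 0.8 with 2%
    multiplicative jitter, so per-set median-curve features should stay
    strongly linearly correlated between the two conditions.  A single
    concentration keeps each set's per-cycle median curve well defined
    (no Ct shift within a set).
    """
    profiles = [
        TargetKineticProfile(
            target=f"t{i}",
            primer_sets={
                "A": SigmoidParams(fm=800 + 250 * i, fb=100.0, sc=0.5 + 0.15 * i,
                                   cs=23.0 + 0.7 * i, asym=0.8 + 0.35 * i),
                "B": SigmoidParams(fm=700 + 230 * i, fb=100.0, sc=0.45 + 0.17 * i,
                                   cs=24.0 + 0.6 * i, asym=0.9 + 0.3 * i),
            },
        )
        for i in range(5)
    ]
    return ScenarioConfig(profiles=profiles, n_curves=n_curves, concentrations=[1e5],
                          alpha_fm=0.8, beta_sc=0.8, attenuation_jitter=0.02, seed=seed)


def overlap_3plex_features(seed: int = 0, n_per_cluster: int = 40) -> pd.DataFrame:
    """Feature table for a 3-plex where one candidate looks good only by medians.

    Three targets with two primer sets each.  Set ``A`` clusters are tight
    (small within-target spread, moderate median separation); set ``B``
    clusters have the farthest-apart medians of any set but a within-target
    spread of the same order as the gaps, so the clusters overlap heavily.
    Median-based scoring (S1/S2) therefore rewards the all-``B`` candidate
    while silhouette-based scoring (S3) demotes it — the scenario that
    motivates clustering-based distances.
    """
    rng = np.random.default_rng(seed)
    spec = {
        # (target, primer_set): (median, spread) of the 1-D `sc` feature
        ("T1", "A"): (0.40, 0.02), ("T2", "A"): (0.70, 0.02), ("T3", "A"): (1.00, 0.02),
        ("T1", "B"): (0.20, 0.80), ("T2", "B"): (1.00, 0.80), ("T3", "B"): (1.80, 0.80),
    }
    rows = []
    for (target, primer_set), (mu, sd) in spec.items():
        vals = mu + sd * rng.standard_normal(n_per_cluster)
        for i, v in enumerate(vals):
            rows.append(
                {
                    "curve_id": f"{target}_{primer_set}_{i:03d}",
                    "target": target,
                    "primer_set": primer_set,
                    "reaction_type": "singleplex",
                    "concentration": 1e4,
                    "sc": v,
                    "slope_ms": v,
                    "curv_p1": v,
                    "neg_curv_p2": v,
                }
            )
    return pd.DataFrame(rows)


def curves_to_frames(curves: list[AmplificationCurve]) -> pd.DataFrame:
    """Long-format DataFrame (curve_id, cycle, fluorescence) for CSV export."""
    return pd.concat(
        [
            pd.DataFrame(
                {"curve_id": c.curve_id, "cycle": c.cycles, "fluorescence": c.fluorescence}
            )
            for c in curves
        ],
        ignore_index=True,
    )
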