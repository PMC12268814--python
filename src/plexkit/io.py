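"""CSV readers and writers for curves, metadata and per-stage artifacts.

Curve files are long-format UTF-8 CSV with a header row:
``curve_id, cycle, fluorescence``.  Metadata files carry one row per
curve: ``curve_id, target, primer_set, concentration, panel_id,
reaction_type``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .curve_model import AmplificationCurve, FitResult, SigmoidParams

__all__ = [
    "read_curves",
    "write_curves",
    "write_fits",
    "read_fits",
    "write_filter_report",
]

CURVE_COLUMNS = ("curve_id", "cycle", "fluorescence")
META_COLUMNS = ("curve_id", "target", "primer_set", "concentration", "panel_id", "reaction_type")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def read_curves(
    curves_path: str | Path, metadata_path: str | Path | None = None
) -> list[AmplificationCurve]:
    """Assemble validated curves from a long-format CSV, joining metadata.

    Rows whose ``curve_id`` has no metadata carry null metadata and emit a
    warning; duplicate (curve_id, cycle) pairs are an error.
    """
    df = pd.read_csv(curves_path)
    _require_columns(df, CURVE_COLUMNS, str(curves_path))
    if df.duplicated(subset=["curve_id", "cycle"]).any():
        dup = df[df.duplicated(subset=["curve_id", "cycle"])]["curve_id"].unique()
        raise ValueError(f"duplicate (curve_id, cycle) rows for {dup[:5].tolist()}")

    meta: dict[str, dict] = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path)
        _require_columns(mdf, ("curve_id",), str(metadata_path))
        meta = mdf.set_index("curve_id").to_dict(orient="index")

    curves = []
    unmatched = []
    for cid, grp in df.groupby("curve_id", sort=True):
        grp = grp.sort_values("cycle")
        m = meta.get(cid)
        if metadata_path is not None and m is None:
            unmatched.append(cid)
            m = {}
        m = m or {}

        def _get(key):
            v = m.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        curves.append(
            AmplificationCurve(
                curve_id=str(cid),
                cycles=grp["cycle"].to_numpy(dtype=float),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
                target=_get("target"),
                primer_set=_get("primer_set"),
                concentration=_get("concentration"),
                panel_id=_get("panel_id"),
                reaction_type=_get("reaction_type"),
            )
        )
    if unmatched:
        warnings.warn(f"{len(unmatched)} curve(s) without metadata: {unmatched[:5]}")
    return curves


def write_curves(
    curves: list[AmplificationCurve],
    curves_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    from .synthetic import curves_to_frames

    curves_to_frames(curves).to_csv(curves_path, index=False)
    if metadata_path is not None:
        rows = [
            {
                "curve_id": c.curve_id,
                "target": c.target,
                "primer_set": c.primer_set,
                "concentration": c.concentration,
                "panel_id": c.panel_id,
                "reaction_type": c.reaction_type,
            }
            for c in curves
        ]
        pd.DataFrame(rows, columns=list(META_COLUMNS)).to_csv(metadata_path, index=False)


def write_fits(fits: dict[str, FitResult], path: str | Path) -> None:
    rows = []
    for cid, fit in sorted(fits.items()):
        row = {"curve_id": cid, "converged": fit.converged,
               "rss": fit.rss, "r_squared": fit.r_squared, "n_iter": fit.n_iter}
        if fit.params is not None:
            row.update(fit.params.to_dict())
        rows.append(row)
    cols = ["curve_id", "fm", "fb", "sc", "cs", "asym", "rss", "r_squared", "converged", "n_iter"]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)


def read_fits(path: str | Path) -> dict[str, FitResult]:
    df = pd.read_csv(path)
    _require_columns(df, ("curve_id", "converged"), str(path))
    fits = {}
    for _, row in df.iterrows():
        params = None
        if bool(row["converged"]) and np.isfinite(row.get("fm", np.nan)):
            params = SigmoidParams(fm=row["fm"], fb=row["fb"], sc=row["sc"],
                                   cs=row["cs"], asym=row["asym"])
        fits[str(row["curve_id"])] = FitResult(
            params=params,
            rss=float(row.get("rss", np.nan)),
            r_squared=float(row.get("r_squared", np.nan)),
            converged=bool(row["converged"]),
            n_iter=int(row.get("n_iter", 0)),
        )
    return fits


def write_filter_report(report, path: str | Path) -> None:
    rows = [{"curve_id": cid, "kept": False, "reason": reason} for cid, reason in report.rejected]
    pd.DataFrame(rows, columns=["curve_id", "kept", "reason"]).to_csv(path, index=False)
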