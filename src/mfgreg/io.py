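"""Readers and writers: long-format curve tables and structured result files.

Curves arrive as long-format delimited text with columns
``subject_id, predictor_id, time, value`` (header required, UTF-8, '.'
decimal); the scalar responses in a separate table with columns
``subject_id, y``.  A fitted model is serialized to a single JSON artifact
(basis spec, centering offsets, coefficients, diagnostics) sufficient for
prediction without the training data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import (BasisSystem, BlockStructure, CoordinateVector,
                    build_basis)
from .model import CVResult, SparseFit, extract_coefficients

__all__ = [
    "read_long_format",
    "write_long_format",
    "write_fit",
    "read_fit",
    "write_coefficient_curves",
    "write_path_summary",
    "write_cv",
    "write_scenario_table",
]

_CURVE_COLS = ["subject_id", "predictor_id", "time", "value"]


def read_long_format(curves_path, response_path):
    """Parse long-format curve and response tables into per-curve records.

    Returns ``(subjects, predictors, curves, y)`` where ``curves[i][j]`` is a
    ``(times, values)`` pair sorted by time.  Every subject must supply every
    predictor; duplicate ``(subject, predictor, time)`` rows are an error.
    """
    df = pd.read_csv(curves_path, sep=None, engine="python")
    missing = [c for c in _CURVE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"curve table is missing columns: {missing}")
    resp = pd.read_csv(response_path, sep=None, engine="python")
    if not {"subject_id", "y"}.issubset(resp.columns):
        raise ValueError("response table needs columns subject_id, y")
    dup = df.duplicated(subset=["subject_id", "predictor_id", "time"])
    if dup.any():
        rows = df.loc[dup, ["subject_id", "predictor_id", "time"]].head(5)
        raise ValueError(f"duplicate (subject, predictor, time) rows, e.g.\n{rows}")

    subjects = sorted(df["subject_id"].unique().tolist())
    predictors = sorted(df["predictor_id"].unique().tolist())
    resp = resp.set_index("subject_id")["y"]
    missing_y = [s for s in subjects if s not in resp.index]
    if missing_y:
        raise ValueError(f"subjects without response values: {missing_y}")

    grouped = {k: g for k, g in df.groupby(["subject_id", "predictor_id"])}
    offenders = [(s, p) for s in subjects for p in predictors if (s, p) not in grouped]
    if offenders:
        raise ValueError(f"missing (subject, predictor) curves: {offenders}")

    curves = []
    for s in subjects:
        row = []
        for p in predictors:
            g = grouped[(s, p)].sort_values("time")
            row.append((g["time"].to_numpy(float), g["value"].to_numpy(float)))
        curves.append(row)
    y = np.array([resp.loc[s] for s in subjects], dtype=float)
    return subjects, predictors, curves, y


def write_long_format(curves, y, curves_path, response_path,
                      subjects=None, predictors=None) -> None:
    """Inverse of :func:`read_long_format` for nested (times, values) curves."""
    n, p = len(curves), len(curves[0])
    subjects = subjects or list(range(n))
    predictors = predictors or list(range(p))
    rows = []
    for i, s in enumerate(subjects):
        for j, pr in enumerate(predictors):
            t, v = curves[i][j]
            for tt, vv in zip(t, v):
                rows.append((s, pr, float(tt), float(vv)))
    pd.DataFrame(rows, columns=_CURVE_COLS).to_csv(curves_path, index=False)
    pd.DataFrame({"subject_id": subjects, "y": np.asarray(y, float)}).to_csv(
        response_path, index=False)


# ---------------------------------------------------------------------------
# model artifacts
# ---------------------------------------------------------------------------

def _basis_spec(basis: BasisSystem) -> dict:
    return {"kind": basis.kind, "m": basis.m,
            "domain": [basis.domain[0], basis.domain[1]],
            "order": basis.order}


def write_fit(fit_: SparseFit, path) -> None:
    """Single-file JSON artifact with deterministic field ordering."""
    payload = {
        "format": "mfgreg-fit-v1",
        "solver": fit_.solver,
        "lambda": fit_.lambda_,
        "alpha": fit_.alpha,
        "lambda_der": fit_.lambda_der,
        "active_set": sorted(int(j) for j in fit_.active_set),
        "bases": [_basis_spec(b) for b in fit_.bases],
        "y_mean": fit_.y_mean,
        "x_means": np.asarray(fit_.x_means, float).tolist(),
        "beta_b": fit_.beta_b.values.tolist(),
        "diagnostics": {k: (v if not isinstance(v, (np.floating, np.integer))
                            else float(v))
                        for k, v in sorted(fit_.diagnostics.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_fit(path) -> SparseFit:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "mfgreg-fit-v1":
        raise ValueError(f"{path} is not an mfgreg fit artifact")
    bases = [build_basis(b["kind"], b["m"], b["domain"], b.get("order") or 4)
             for b in payload["bases"]]
    struct = BlockStructure(tuple(b.m for b in bases))
    beta = CoordinateVector(np.asarray(payload["beta_b"], float), struct, tag="B")
    return SparseFit(
        beta_b=beta,
        active_set=list(payload["active_set"]),
        lambda_=payload["lambda"],
        alpha=payload["alpha"],
        lambda_der=payload["lambda_der"],
        solver=payload["solver"],
        bases=bases,
        y_mean=payload["y_mean"],
        x_means=np.asarray(payload["x_means"], float),
        diagnostics=dict(payload.get("diagnostics", {})),
    )


def write_coefficient_curves(fit_: SparseFit, path, n_points: int = 200) -> None:
    """CSV of the p coefficient curves sampled on a uniform grid (time, beta_1..beta_p)."""
    a = min(b.domain[0] for b in fit_.bases)
    b_ = max(b.domain[1] for b in fit_.bases)
    t = np.linspace(a, b_, n_points)
    curves = extract_coefficients(fit_, t)
    df = pd.DataFrame({"time": t})
    for j in range(fit_.p):
        df[f"beta_{j + 1}"] = curves[j]
    df.to_csv(path, index=False)


def write_path_summary(path_result, out_path) -> None:
    """CSV path summary: lambda, active-set size, objective, sweeps."""
    rows = [{
        "lambda": f.lambda_,
        "n_active": len(f.active_set),
        "objective": f.objective,
        "sweeps": f.sweeps,
        "kkt_violations": f.kkt_violations,
    } for f in path_result.fits]
    pd.DataFrame(rows).to_csv(out_path, index=False)


def write_cv(cv: CVResult, path) -> None:
    alpha, lder, lam = cv.best
    payload = {
        "format": "mfgreg-cv-v1",
        "solver": cv.solver,
        "k": cv.k,
        "seed": cv.seed,
        "best": {"alpha": alpha, "lambda_der": lder, "lambda": lam,
                 "mean_mse": cv.best_mse()},
        "surface": [
            {"alpha": a, "lambda_der": d, "lambda": l,
             "mean_mse": m, "sd_mse": s}
            for (a, d, l), (m, s) in sorted(cv.error_surface.items())
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def write_scenario_table(result, path) -> None:
    """CSV selection/RMSE summary table for one scenario."""
    pd.DataFrame(result.table_rows()).to_csv(path, index=False)
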