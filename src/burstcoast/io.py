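"""CSV/JSON interchange for trajectories, kick tables and factor tables.

Trajectory CSV: ``time_s, fish_id, x_mm, y_mm`` at a uniform rate
(50 Hz default).  Kick-table CSV: one row per decision with kinematics,
wall frame and (two fish) pair frame.  Factor CSV: long format
``function_name, bin_center, value [, weight]``.  Header row mandatory,
comma separated, decimal point.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import KICK_TABLE_COLUMNS, TRAJECTORY_COLUMNS
from .inference import FactorizationResult

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_kicks",
    "write_kicks",
    "write_factors",
    "read_factors",
    "write_diagnostics",
]


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return df


def write_trajectory(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_kicks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(KICK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"kick-table CSV missing columns: {sorted(missing)}")
    return df


def write_kicks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_factors(result: FactorizationResult, path) -> None:
    rows = []
    dim_of = _factor_dims(result)
    for name, values in result.factors.items():
        centers = result.mesh.centers(dim_of[name])
        weights = result.bin_weights.get(name)
        for i, (c, v) in enumerate(zip(centers, values)):
            rows.append(
                {
                    "function_name": name,
                    "bin_center": c,
                    "value": v,
                    "weight": float(weights[i]) if weights is not None else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _factor_dims(result: FactorizationResult) -> dict:
    if set(result.factors) == {"f", "O"}:
        return {"f": 0, "O": 1}
    return {
        "F_att": 0, "O_att": 1, "E_att": 2,
        "F_ali": 0, "O_ali": 2, "E_ali": 1,
    }


def read_factors(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for name, grp in df.groupby("function_name"):
        grp = grp.sort_values("bin_center")
        out[name] = {
            "bin_center": grp["bin_center"].to_numpy(),
            "value": grp["value"].to_numpy(),
            "weight": grp["weight"].to_numpy() if "weight" in grp else None,
        }
    return out


def write_diagnostics(result: FactorizationResult, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "iterations": result.iterations,
                "final_error": result.error,
                "converged": result.converged,
                "degenerate": result.degenerate,
                "damping": result.damping,
                "tol": result.tol,
            },
            indent=2,
        )
    )
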