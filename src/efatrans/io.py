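"""CSV / JSON interchange for the pipeline stages.

Observation files are plain UTF-8 CSV with a header and '.' decimals:
column ``x`` (μg/ml) or ``t`` (h) plus ``value``.  Fit reports mirror an
nls summary (parameter, estimate, std_error, t_value, p_value); numeric
output is written with 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult

__all__ = [
    "read_observations",
    "write_observations",
    "write_fit_report",
    "read_fit_report",
    "write_table",
    "write_summary_json",
]

FLOAT_FORMAT = "%.6g"


def read_observations(path: str | Path, var: str) -> tuple[np.ndarray, np.ndarray]:
    """Read an observation CSV with columns ``var`` ('x' or 't') and ``value``."""
    if var not in ("x", "t"):
        raise ValueError(f"var must be 'x' or 't', got {var!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ValueError(f"malformed observation CSV {path}: {exc}") from exc
    missing = {var, "value"} - set(frame.columns)
    if missing:
        raise ValueError(
            f"observation CSV {path} lacks required column(s) {sorted(missing)}"
        )
    if frame.empty:
        raise ValueError(f"observation CSV {path} contains no rows")
    iv = pd.to_numeric(frame[var], errors="coerce")
    dv = pd.to_numeric(frame["value"], errors="coerce")
    if iv.isna().any() or dv.isna().any():
        raise ValueError(f"observation CSV {path} contains non-numeric entries")
    return iv.to_numpy(float), dv.to_numpy(float)


def write_observations(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table produced by the simulator."""
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_fit_report(result: FitResult, path: str | Path) -> None:
    """Write a fit-inference table (parameter, estimate, std_error, t_value, p_value)."""
    result.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_fit_report(path: str | Path) -> dict[str, float]:
    """Read parameter estimates back from a fit report: name -> estimate."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = {"parameter", "estimate"} - set(frame.columns)
    if missing:
        raise ValueError(f"fit report {path} lacks required column(s) {sorted(missing)}")
    est = pd.to_numeric(frame["estimate"], errors="coerce")
    if est.isna().any():
        raise ValueError(f"fit report {path} contains non-numeric estimates")
    return dict(zip(frame["parameter"].astype(str), est.astype(float)))


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a generic results table (e.g. the phase-classification grid)."""
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _round6(obj):
    if isinstance(obj, dict):
        return {k: _round6(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round6(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def write_summary_json(summary: dict, path: str | Path) -> None:
    """Write the analysis summary (turning points, boundaries, crossings) as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_round6(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
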