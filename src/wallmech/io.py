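"""Curve CSV and summary JSON input/output.

The curve dialect is a plain UTF-8 CSV with header
``time_s,lambda_ax,lambda_tr,force_per_width_N_per_m[,segment]``;
the optional ``segment`` column carries ``<cycle>:loading`` /
``<cycle>:unloading`` labels and promotes the file to a cyclic curve.
All floating-point output is printed with 9 significant digits for
round-trip safety.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import CyclicCurve, RawCurve
from .errors import SchemaError

__all__ = ["CURVE_COLUMNS", "read_curve_csv", "write_curve_csv", "write_summary_json"]

CURVE_COLUMNS = ["time_s", "lambda_ax", "lambda_tr", "force_per_width_N_per_m"]
_FLOAT_FMT = "%.9g"


def read_curve_csv(path) -> RawCurve | CyclicCurve:
    """Read a curve file; a ``segment`` column yields a cyclic curve."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc

    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{','.join(CURVE_COLUMNS)}[,segment]"
        )
    for col in CURVE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at data row {bad[0]}"
            )
        if vals.isna().any():
            raise SchemaError(f"{path}: empty cell in column {col!r}")
        df[col] = vals

    raw = RawCurve(
        time=df["time_s"].to_numpy(),
        lambda_ax=df["lambda_ax"].to_numpy(),
        lambda_tr=df["lambda_tr"].to_numpy(),
        force_per_width=df["force_per_width_N_per_m"].to_numpy(),
        label=path.stem,
    )
    if "segment" not in df.columns:
        return raw

    cycles, phases = [], []
    for i, seg in enumerate(df["segment"].astype(str)):
        try:
            c, ph = seg.split(":")
            c = int(c)
        except ValueError:
            raise SchemaError(
                f"{path}: bad segment label {seg!r} at data row {i}; "
                "expected '<cycle>:loading' or '<cycle>:unloading'"
            ) from None
        if ph not in ("loading", "unloading"):
            raise SchemaError(f"{path}: bad phase {ph!r} at data row {i}")
        cycles.append(c)
        phases.append(ph)
    return CyclicCurve(raw, np.asarray(cycles), np.asarray(phases, dtype=object))


def write_curve_csv(curve: RawCurve | CyclicCurve, path) -> Path:
    """Write a curve in the standard dialect (9 significant digits)."""
    path = Path(path)
    if isinstance(curve, CyclicCurve):
        raw = curve.raw
        segment = [f"{c}:{p}" for c, p in zip(curve.cycle, curve.phase)]
    else:
        raw, segment = curve, None
    df = pd.DataFrame(
        {
            "time_s": raw.time,
            "lambda_ax": raw.lambda_ax,
            "lambda_tr": raw.lambda_tr,
            "force_per_width_N_per_m": raw.force_per_width,
        }
    )
    if segment is not None:
        df["segment"] = segment
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def _round9(obj):
    if isinstance(obj, float):
        return float(f"{obj:.9g}")
    if isinstance(obj, dict):
        return {k: _round9(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round9(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.9g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round9(obj.tolist())
    return obj


def write_summary_json(summary: dict, path) -> Path:
    """Write a summary dict as JSON with stable key order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_round9(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
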