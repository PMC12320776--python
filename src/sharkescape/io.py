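"""CSV schemas, validation and sidecar-parameter files.

Every pipeline artifact is plain CSV with a header row and SI-unit column
suffixes; generators additionally write a ``<name>.params.json`` sidecar
recording the seed and parameters that produced the file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ColumnSpec:
    name: str
    kind: str  # "float" | "int" | "str"
    checks: tuple = ()  # (label, vectorized predicate returning bool mask of OK rows)


@dataclass
class Schema:
    name: str
    columns: list[ColumnSpec]
    frame_checks: tuple = ()  # (label, fn(df) -> bool mask or scalar bool)


def _positive(s):
    return s > 0


def _non_negative(s):
    return s >= 0


def _on_the_hour(s):
    ts = pd.to_datetime(s, errors="coerce")
    return ts.notna() & (ts.dt.minute == 0) & (ts.dt.second == 0)


def _temp_in_bounds(s):
    return (s >= 15.0) & (s <= 40.0)


SCHEMAS: dict[str, Schema] = {
    s.name: s
    for s in [
        Schema(
            "do_trace",
            [
                ColumnSpec("shark_id", "str"),
                ColumnSpec("time_s", "float", (("non-negative", _non_negative),)),
                ColumnSpec("do_mg_per_l", "float", (("non-negative", _non_negative),)),
            ],
            frame_checks=(
                (
                    "time strictly increasing within shark",
                    lambda df: df.groupby("shark_id")["time_s"].diff().fillna(1.0) > 0,
                ),
            ),
        ),
        Schema(
            "aas",
            [
                ColumnSpec("shark_id", "str"),
                ColumnSpec("temperature_c", "float"),
                ColumnSpec("aas", "float", (("non-negative", _non_negative),)),
            ],
        ),
        Schema(
            "mo2_series",
            [
                ColumnSpec("shark_id", "str"),
                ColumnSpec("window_index", "int"),
                ColumnSpec("window_start", "float", (("non-negative", _non_negative),)),
                ColumnSpec("mo2_whole", "float"),
                ColumnSpec("mo2_scaled", "float"),
                ColumnSpec("r_squared", "float"),
            ],
        ),
        Schema(
            "metabolic_summary",
            [
                ColumnSpec("shark_id", "str"),
                ColumnSpec("temperature_c", "float"),
                ColumnSpec("mo2_min", "float"),
                ColumnSpec("mo2_max", "float"),
                ColumnSpec("aas", "float"),
            ],
        ),
        Schema(
            "tracks",
            [
                ColumnSpec("track_id", "str"),
                ColumnSpec("frame", "int", (("non-negative", _non_negative),)),
                ColumnSpec("head_x", "float"),
                ColumnSpec("head_y", "float"),
                ColumnSpec("com_x", "float"),
                ColumnSpec("com_y", "float"),
                ColumnSpec("body_angle_deg", "float"),
            ],
        ),
        Schema(
            "trials",
            [
                ColumnSpec("track_id", "str"),
                ColumnSpec("shark_id", "str"),
                ColumnSpec("trial", "int", (("positive", _positive),)),
                ColumnSpec("temperature_c", "float"),
                ColumnSpec("stimulus_frame", "int", (("non-negative", _non_negative),)),
                ColumnSpec("fps", "float", (("positive", _positive),)),
            ],
        ),
        Schema(
            "escape_metrics",
            [
                ColumnSpec("shark_id", "str"),
                ColumnSpec("temperature_c", "float"),
                ColumnSpec("response_type", "str"),
                ColumnSpec("latency_ms", "float", (("non-negative", _non_negative),)),
                ColumnSpec("omega_s1", "float"),
                ColumnSpec("u_max", "float"),
                ColumnSpec("a_max", "float"),
            ],
        ),
        Schema(
            "fins",
            [
                ColumnSpec("individual_id", "str"),
                ColumnSpec(
                    "life_stage",
                    "str",
                    (("known life stage", lambda s: s.isin(["newborn", "adult"])),),
                ),
                ColumnSpec("fin_height_m", "float", (("positive", _positive),)),
            ],
        ),
        Schema(
            "temperature_log",
            [
                ColumnSpec("site", "str"),
                ColumnSpec("logger_id", "str"),
                ColumnSpec("timestamp", "str", (("on the hour", _on_the_hour),)),
                ColumnSpec("temp_c", "float", (("within 15-40 degC", _temp_in_bounds),)),
            ],
        ),
        Schema(
            "diel_cycle",
            [
                ColumnSpec("site", "str"),
                ColumnSpec("month", "str"),
                ColumnSpec("hour", "float"),
                ColumnSpec("temp_c", "float"),
            ],
        ),
    ]
}


@dataclass
class ValidationReport:
    schema: str
    path: str
    ok: bool
    n_rows: int
    violations: list = field(default_factory=list)  # (line_no, column, message)


def validate_csv(path, schema_name: str) -> ValidationReport:
    """Check a CSV against a registered schema; list row-level violations.

    Line numbers are 1-based file lines (header is line 1).
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed CSV at {path}: {exc}") from exc
    violations = []
    for col in schema.columns:
        if col.name not in df.columns:
            violations.append((1, col.name, "missing column"))
            continue
        s = df[col.name]
        if col.kind in ("float", "int"):
            coerced = pd.to_numeric(s, errors="coerce")
            bad = coerced.isna() & s.notna()
            for i in df.index[bad]:
                violations.append((int(i) + 2, col.name, "not numeric"))
            s = coerced
        for label, fn in col.checks:
            mask = fn(s)
            bad = ~mask.fillna(False) if hasattr(mask, "fillna") else ~mask
            for i in df.index[bad]:
                violations.append((int(i) + 2, col.name, f"failed check: {label}"))
    if not any(v[2] == "missing column" for v in violations):
        for label, fn in schema.frame_checks:
            mask = fn(df)
            bad = ~np.asarray(mask, dtype=bool)
            for i in df.index[bad]:
                violations.append((int(i) + 2, "<frame>", f"failed check: {label}"))
    return ValidationReport(
        schema=schema_name,
        path=str(path),
        ok=not violations,
        n_rows=len(df),
        violations=sorted(violations),
    )


def write_with_sidecar(df: pd.DataFrame, path, params=None) -> None:
    """Write a CSV plus a JSON sidecar recording generator parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if params is not None:
        if is_dataclass(params):
            params = asdict(params)
        sidecar = path.with_suffix(path.suffix + ".params.json")
        sidecar.write_text(json.dumps(_jsonable(params), indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
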