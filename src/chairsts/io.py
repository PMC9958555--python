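"""File formats: flat key-value geometry config, series CSVs, metrics JSON.

All CSVs are plain text with a documented header row and units in column
names; a leading ``#`` provenance comment records the package version,
schema and the seed/config that produced the file. JSON metrics carry a
``schema_version`` field.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import AngleSeries, ChairGeometry, DistanceSeries
from .synthetic import MarkerSeries

__all__ = [
    "read_geometry", "write_geometry",
    "read_series", "write_distances", "write_angles", "write_markers",
    "write_metrics_json", "read_metrics_json",
]

SCHEMA_VERSION = 1

_GEOM_KEYS = ("phi_s1", "l_s1", "l_offset", "phi_s2", "l_seat", "l_s2",
              "l_thigh", "seat_height", "sensor_max_range")

_DIST_COLS = ["t", "d_thigh_mm", "d_trunk_mm", "valid"]
_ANGLE_COLS = ["t", "theta_trunk_deg", "theta_thigh_deg", "source", "valid"]
_MARKER_COLS = ["t"] + [
    f"{m}_{ax}_mm"
    for m in ("c7", "sacrum", "greater_trochanter", "lateral_femoral_condyle")
    for ax in ("x", "y")
]


def _provenance(seed=None, extra: dict | None = None) -> str:
    fields = {"schema": SCHEMA_VERSION}
    if seed is not None:
        fields["seed"] = seed
    if extra:
        fields.update(extra)
    body = " ".join(f"{k}={v}" for k, v in fields.items())
    return f"# chairsts {body}\n"


# -- geometry config --------------------------------------------------------

def write_geometry(geom: ChairGeometry, path: str | Path) -> None:
    """Flat ``key = value`` config, one field per line, keys as documented."""
    lines = [_provenance()]
    for key in _GEOM_KEYS:
        lines.append(f"{key} = {getattr(geom, key)}\n")
    Path(path).write_text("".join(lines))


def read_geometry(path: str | Path) -> ChairGeometry:
    values: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _GEOM_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown geometry key {key!r}")
        values[key] = float(val)
    missing = set(_GEOM_KEYS) - set(values)
    if missing:
        raise ValueError(f"{path}: missing geometry keys: {sorted(missing)}")
    return ChairGeometry(**values)


# -- series CSV -------------------------------------------------------------

def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; header must be "
                         f"{required}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    bad = np.flatnonzero(~np.isfinite(df["t"].to_numpy(dtype=float)))
    if bad.size:
        raise ValueError(f"{path}: non-numeric time at data row(s) {bad[:5] + 1}")
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
        raise ValueError(f"{path}: time not strictly increasing at data row {row}")
    numeric = df.select_dtypes(include=[float, int])
    nan_frac = float(numeric.isna().to_numpy().mean()) if numeric.size else 0.0
    if nan_frac > 0.20:
        raise ValueError(f"{path}: {nan_frac:.0%} missing values (> 20% limit)")
    return df


def _infer_fs(t: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 30.0


def read_series(path: str | Path, kind: str):
    """Read a ``distance``, ``angle`` or ``marker`` CSV into its series type."""
    if kind == "distance":
        df = _read_csv(path, _DIST_COLS)
        t = df["t"].to_numpy(dtype=float)
        return DistanceSeries(
            t, df["d_thigh_mm"].to_numpy(dtype=float),
            df["d_trunk_mm"].to_numpy(dtype=float),
            df["valid"].to_numpy(dtype=bool), fs=_infer_fs(t),
        )
    if kind == "angle":
        df = _read_csv(path, _ANGLE_COLS)
        t = df["t"].to_numpy(dtype=float)
        source = str(df["source"].iloc[0])
        return AngleSeries(
            t, df["theta_trunk_deg"].to_numpy(dtype=float),
            df["theta_thigh_deg"].to_numpy(dtype=float),
            source=source, valid=df["valid"].to_numpy(dtype=bool),
            fs=_infer_fs(t),
        )
    if kind == "marker":
        df = _read_csv(path, _MARKER_COLS)
        t = df["t"].to_numpy(dtype=float)
        get = lambda m: df[[f"{m}_x_mm", f"{m}_y_mm"]].to_numpy(dtype=float)
        return MarkerSeries(t, get("c7"), get("sacrum"),
                            get("greater_trochanter"),
                            get("lateral_femoral_condyle"), fs=_infer_fs(t))
    raise ValueError(f"unknown series kind {kind!r}")


def _write_csv(df: pd.DataFrame, path: str | Path, seed, extra) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance(seed, extra))
        df.to_csv(fh, index=False)


def write_distances(series: DistanceSeries, path: str | Path,
                    seed=None, extra: dict | None = None) -> None:
    df = pd.DataFrame({
        "t": series.t, "d_thigh_mm": series.d_thigh,
        "d_trunk_mm": series.d_trunk, "valid": series.valid,
    })
    _write_csv(df, path, seed, extra)


def write_angles(series: AngleSeries, path: str | Path,
                 seed=None, extra: dict | None = None) -> None:
    df = pd.DataFrame({
        "t": series.t, "theta_trunk_deg": series.theta_trunk,
        "theta_thigh_deg": series.theta_thigh,
        "source": series.source, "valid": series.valid,
    })
    _write_csv(df, path, seed, extra)


def write_markers(series: MarkerSeries, path: str | Path,
                  seed=None, extra: dict | None = None) -> None:
    data = {"t": series.t}
    for m in ("c7", "sacrum", "greater_trochanter", "lateral_femoral_condyle"):
        arr = getattr(series, m)
        data[f"{m}_x_mm"] = arr[:, 0]
        data[f"{m}_y_mm"] = arr[:, 1]
    _write_csv(pd.DataFrame(data), path, seed, extra)


# -- metrics JSON -----------------------------------------------------------

def write_metrics_json(payload: dict, path: str | Path, seed=None,
                       config: dict | None = None) -> None:
    doc = {"schema_version": SCHEMA_VERSION, "seed": seed}
    if config is not None:
        doc["config"] = config
    doc.update(payload)
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonable) + "\n")


def read_metrics_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
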