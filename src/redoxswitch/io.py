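"""CSV / key-value file formats.

Traces are CSV with ``#key=value`` metadata header lines, UTF-8, '.'
decimal separator; numeric columns are written at full float precision so
write-then-read round-trips are lossless.  Ground-truth parameters go to a
separate sidecar file, never into the trace itself.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .fitting import FitResult, KineticTrace
from .network import Trajectory
from .stoichiometry import InactivationSeries, fraction_irreversible

__all__ = [
    "write_trace",
    "read_trace",
    "write_truth",
    "read_truth",
    "write_trajectory",
    "write_fit_report",
    "write_series",
    "read_series",
    "read_config",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


def _parse_value(raw: str):
    raw = raw.strip()
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    if raw in ("True", "False"):
        return raw == "True"
    return raw


def _write_header(fh, meta: Dict[str, object]) -> None:
    for k, v in meta.items():
        fh.write(f"#{k}={v}\n")


def _read_header(path: Path) -> Dict[str, object]:
    meta: Dict[str, object] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, raw = line[1:].partition("=")
            meta[key.strip()] = _parse_value(raw)
    return meta


def write_trace(path, trace: KineticTrace) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _write_header(fh, trace.meta)
        fh.write("time_s,signal\n")
        for t, s in zip(trace.times, trace.signal):
            fh.write(f"{t:.17g},{s:.17g}\n")


def read_trace(path) -> KineticTrace:
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "time_s" not in df.columns or "signal" not in df.columns:
        raise ValueError(f"{path} is not a trace CSV (need time_s,signal columns)")
    return KineticTrace(df["time_s"].to_numpy(), df["signal"].to_numpy(), meta)


def write_truth(path, truth: Dict[str, object]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in truth.items():
            fh.write(f"{k}={v}\n")


def read_truth(path) -> Dict[str, object]:
    out = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            out[key] = _parse_value(raw)
    return out


def write_trajectory(path, traj: Trajectory, meta: Optional[Dict[str, object]] = None) -> None:
    path = Path(path)
    df = traj.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        _write_header(fh, meta or {})
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_fit_report(path, result: FitResult, extra: Optional[Dict[str, object]] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(result.summary() + "\n")
        for k, v in (extra or {}).items():
            fh.write(f"{k}={v}\n")


def write_series(
    path,
    times: np.ndarray,
    activity_dtt: np.ndarray,
    h2o2_remaining: np.ndarray,
    native_activity: float,
    b0: float,
    tetramer_conc: float,
) -> None:
    """Raw inactivation-series CSV: time_s,activity_dtt,h2o2_remaining_M with
    the normalization constants in the header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _write_header(fh, {"native_activity": native_activity, "b0_M": b0,
                           "tetramer_conc_M": tetramer_conc})
        fh.write("time_s,activity_dtt,h2o2_remaining_M\n")
        for t, a, b in zip(times, activity_dtt, h2o2_remaining):
            fh.write(f"{t:.17g},{a:.17g},{b:.17g}\n")


def read_series(path) -> InactivationSeries:
    """Read a raw series CSV and convert to paired (x, y) fractions.

    x = (P0 - P')/P0 from the DTT-protected activities; y = (B0 - B')
    normalized by the total consumable H2O2, eight equivalents per
    tetramer.
    """
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    need = {"time_s", "activity_dtt", "h2o2_remaining_M"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path} is not a series CSV (need columns {sorted(need)})")
    for key in ("native_activity", "b0_M", "tetramer_conc_M"):
        if key not in meta:
            raise ValueError(f"series file missing header constant {key}")
    p0 = float(meta["native_activity"])
    b0 = float(meta["b0_M"])
    consumable = 8.0 * float(meta["tetramer_conc_M"])
    x = np.array([fraction_irreversible(a, p0) for a in df["activity_dtt"]])
    y = np.clip((b0 - df["h2o2_remaining_M"].to_numpy()) / consumable, 0.0, 1.0)
    return InactivationSeries(x=x, y=y)


def read_config(path) -> Dict[str, object]:
    """Read a TOML run configuration."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def write_manifest(path, config: Dict[str, object], seed: Optional[int]) -> None:
    from . import __version__

    manifest = {"package": "redoxswitch", "version": __version__,
                "seed": seed, "config": config}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n",
                          encoding="utf-8")
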