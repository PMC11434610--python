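"""CSV / JSON input-output with documented schemas.

Canonical plain-text schemas (times in ms, voltages in mV):

* trace:   columns ``t_ms, v_mV`` and optionally ``m, h, n``;
* clamp:   long format, columns ``step_mV, t_ms, i``;
* spikes:  columns ``unit_id, epoch, t_ms`` with epoch in {pre, post};
* report:  JSON object with a ``meta`` block (package version, seed,
  resolved parameters) beside the results.

Floats round-trip at full precision (written with 17 significant digits).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clamp import CurrentTraceSet, StepProtocol
from .errors import EmptyInputError, SchemaError
from .model import VoltageTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_clamp_set",
    "read_clamp_set",
    "write_spikes",
    "read_spikes",
    "write_report",
    "config_hash",
]

_FLOAT_FMT = "%.17g"


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: file is empty") from exc
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return df


def write_trace(trace: VoltageTrace, path) -> None:
    data = {"t_ms": trace.t, "v_mV": trace.v}
    for name in ("m", "h", "n"):
        arr = getattr(trace, name)
        if arr is not None:
            data[name] = arr
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace(path) -> VoltageTrace:
    df = _read_csv(path)
    _require_columns(df, ["t_ms", "v_mV"], path)
    t = df["t_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise SchemaError(f"{path}: a trace needs at least two samples")
    dt = float(t[1] - t[0])
    kwargs = {name: df[name].to_numpy(dtype=float)
              for name in ("m", "h", "n") if name in df.columns}
    return VoltageTrace(dt=dt, v=df["v_mV"].to_numpy(dtype=float), **kwargs)


def write_clamp_set(traces: CurrentTraceSet, path) -> None:
    t = traces.t
    frames = [pd.DataFrame({"step_mV": level, "t_ms": t, "i": row})
              for level, row in zip(traces.protocol.step_levels,
                                    traces.currents)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=_FLOAT_FMT)


def read_clamp_set(path, protocol: StepProtocol) -> CurrentTraceSet:
    """Read a long-format clamp file back against its protocol.

    Rows may appear in any step order; they are matched to
    ``protocol.step_levels``.
    """
    df = _read_csv(path)
    _require_columns(df, ["step_mV", "t_ms", "i"], path)
    rows = []
    dt = None
    for level in protocol.step_levels:
        sub = df[np.isclose(df["step_mV"], level)].sort_values("t_ms")
        if sub.empty:
            raise SchemaError(f"{path}: no rows for step level {level} mV")
        t = sub["t_ms"].to_numpy(dtype=float)
        dt = float(t[1] - t[0])
        rows.append(sub["i"].to_numpy(dtype=float))
    return CurrentTraceSet(protocol=protocol, currents=np.asarray(rows), dt=dt)


def write_spikes(units: dict, path) -> None:
    """Write spike times: ``units`` maps unit_id -> {epoch: times_ms}."""
    records = []
    for uid, epochs in units.items():
        for epoch, times in epochs.items():
            for t in np.asarray(times, dtype=float):
                records.append((uid, epoch, t))
    pd.DataFrame(records, columns=["unit_id", "epoch", "t_ms"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_spikes(path) -> dict:
    df = _read_csv(path)
    _require_columns(df, ["unit_id", "epoch", "t_ms"], path)
    out: dict = {}
    for (uid, epoch), sub in df.groupby(["unit_id", "epoch"]):
        out.setdefault(uid, {})[epoch] = np.sort(
            sub["t_ms"].to_numpy(dtype=float))
    return out


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration dictionary."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(results: dict, path, config: dict | None = None,
                 seed: int | None = None) -> None:
    """Write a JSON report with a reproducibility ``meta`` block."""
    from . import __version__

    meta = {"package": "thzneuro", "version": __version__, "seed": seed}
    if config is not None:
        meta["config"] = config
        meta["config_hash"] = config_hash(config)
    payload = {"meta": meta, "results": results}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)
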