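"""Plain-text file formats for traces, positions, swim events and reports.

Trace dialect: one CSV with a column per channel (header ``RL2,LL2,RL5,LL5``
or any subset), time implicit from the sampling rate, plus a sidecar YAML
metadata file ``<stem>.meta.yaml`` holding ``rate_hz``, ``units``, ``t0_s``
and free-form preparation metadata.  Times are seconds, 0-based from
``t0_s``.

Reports serialize to JSON with sorted keys and repr-exact floats, so a rerun
with the same seed and config is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .behavior import SwimBout
from .trace import Trace

__all__ = [
    "write_traces",
    "read_traces",
    "write_positions",
    "read_positions",
    "write_swim",
    "read_swim",
    "write_report",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.yaml")


def write_traces(traces: dict[str, Trace], path: str | Path, meta: dict | None = None) -> Path:
    """Write a multi-channel trace CSV plus its sidecar metadata file.

    All channels must share rate, length and start time (one recording).
    """
    path = Path(path)
    items = list(traces.items())
    if not items:
        raise ValueError("no channels to write")
    rate = items[0][1].rate
    t0 = items[0][1].t0
    n = len(items[0][1])
    for ch, tr in items:
        if tr.rate != rate or tr.t0 != t0 or len(tr) != n:
            raise ValueError("all channels must share rate, t0 and length")
    df = pd.DataFrame({ch: tr.samples for ch, tr in items})
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {"rate_hz": float(rate), "t0_s": float(t0), "units": "a.u."}
    sidecar.update(meta or {})
    _sidecar(path).write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return path


def read_traces(path: str | Path) -> tuple[dict[str, Trace], dict]:
    """Read a trace CSV and its sidecar; returns (channel -> Trace, metadata)."""
    path = Path(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    rate = float(meta["rate_hz"])
    t0 = float(meta.get("t0_s", 0.0))
    df = pd.read_csv(path, float_precision="round_trip")
    traces = {
        ch: Trace(samples=df[ch].to_numpy(dtype=float), rate=rate, channel=ch, t0=t0)
        for ch in df.columns
    }
    return traces, meta


def write_positions(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_positions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_swim(bout: SwimBout, path: str | Path) -> Path:
    path = Path(path)
    bout.events[["limb", "event", "time_s", "x", "y"]].to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_swim(path: str | Path, frame_rate: float = 100.0, bout_id: str | None = None) -> SwimBout:
    df = pd.read_csv(path, float_precision="round_trip")
    return SwimBout(
        events=df, frame_rate=frame_rate, bout_id=bout_id or Path(path).stem
    )


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else repr(v)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path: str | Path) -> Path:
    """Serialize a report dict to deterministic JSON bytes."""
    path = Path(path)
    text = json.dumps(_jsonify(report), indent=2, sort_keys=True)
    path.write_text(text + "\n")
    return path
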