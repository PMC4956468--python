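"""Plain-text input/output: traces, event tables, configs.

Traces travel as two-column TSV (time_s, current_pA) with an optional JSON
sidecar carrying protocol metadata and the ground-truth scheme; event tables
as CSV; configuration as YAML/JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .idealize import EventTable
from .scheme import GatingScheme
from .simulate import CurrentTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "load_config",
    "write_ground_truth_events",
]


def write_trace(trace: CurrentTrace, path: str, scheme: GatingScheme | None = None) -> None:
    """Write a trace as TSV plus a JSON sidecar (<path>.json) with metadata."""
    df = pd.DataFrame({"time_s": trace.times, "current_pA": trace.samples})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = {
        "dt_s": trace.dt,
        "patch_id": trace.patch_id,
        "segments": [list(s) for s in trace.segments],
    }
    if scheme is not None:
        meta["scheme"] = asdict(scheme)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_trace(path: str) -> CurrentTrace:
    """Read a two-column time/current TSV; sidecar metadata applied if present."""
    df = pd.read_csv(path, sep=None, engine="python")
    t = df.iloc[:, 0].to_numpy(float)
    i = df.iloc[:, 1].to_numpy(float)
    dt = float(np.median(np.diff(t)))
    trace = CurrentTrace(i, dt)
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        trace.segments = [tuple(s) for s in meta.get("segments", [])]
        trace.patch_id = meta.get("patch_id", "")
    return trace


def write_events(events: EventTable, path: str) -> None:
    events.to_frame().to_csv(path, index=False)


def read_events(path: str, **kwargs) -> EventTable:
    return EventTable.from_frame(pd.read_csv(path), **kwargs)


def write_ground_truth_events(paths, patch_id: str, path: str) -> None:
    """Per-channel ground-truth state sequences as CSV."""
    rows = []
    for ch, p in enumerate(paths):
        for state, t_entry, dwell in zip(p.state_labels, p.times, p.dwells):
            rows.append((patch_id, ch, state, t_entry, dwell))
    pd.DataFrame(
        rows, columns=["patch_id", "channel_id", "state", "t_entry_s", "dwell_s"]
    ).to_csv(path, index=False)


def load_config(path: str) -> dict:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
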