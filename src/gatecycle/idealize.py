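"""Idealization of multi-channel patch current records.

Converts a sampled current trace into an event table (open-channel count vs
dwell duration) via digital refiltering at the analysis bandwidth, baseline
subtraction, half-amplitude multi-level thresholding, channel counting from
high-P_o bracket segments, and imposition of a fixed dead time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import CurrentTrace, LevelPath, gaussian_filter

__all__ = [
    "EventTable",
    "AnalysisWindow",
    "refilter",
    "estimate_baseline",
    "idealize_half_amplitude",
    "count_channels",
    "impose_dead_time",
    "select_window",
    "events_from_level_path",
]


@dataclass
class EventTable:
    """Idealized sequence of (conductance level, dwell duration) events."""

    levels: np.ndarray  # integer open-channel counts >= 0
    dwells: np.ndarray  # s, > 0
    patch_id: str = ""
    n_channels: int | None = None
    dead_time: float | None = None  # s, set once imposed
    dt: float | None = None  # sampling interval of the source trace, s

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        self.dwells = np.asarray(self.dwells, dtype=float)
        if self.levels.size != self.dwells.size:
            raise ValueError("levels and dwells must have equal length")
        if np.any(self.dwells <= 0):
            raise ValueError("dwell durations must be positive")

    def __len__(self) -> int:
        return self.levels.size

    @property
    def start_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.dwells)[:-1]])

    @property
    def total_duration(self) -> float:
        return float(self.dwells.sum())

    def to_level_path(self) -> LevelPath:
        n = self.n_channels if self.n_channels is not None else int(self.levels.max())
        return LevelPath(self.levels, self.start_times, self.total_duration, n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patch_id": self.patch_id,
                "event_index": np.arange(len(self)),
                "level": self.levels,
                "dwell_s": self.dwells,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "EventTable":
        return cls(
            df["level"].to_numpy(),
            df["dwell_s"].to_numpy(),
            patch_id=str(df["patch_id"].iloc[0]) if "patch_id" in df and len(df) else "",
            **kwargs,
        )


@dataclass(frozen=True)
class AnalysisWindow:
    """Time window [t_start, t_end) selecting the analyzed stretch."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("window requires t_start < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def refilter(trace: CurrentTrace, fc: float) -> CurrentTrace:
    """Digitally filter a trace at analysis bandwidth ``fc`` (Gaussian, DC gain 1)."""
    if fc >= trace.fs / 2:
        raise ValueError("analysis corner must be below Nyquist")
    out = gaussian_filter(trace.samples, fc, trace.fs)
    return CurrentTrace(out, trace.dt, segments=trace.segments, patch_id=trace.patch_id)


def estimate_baseline(trace: CurrentTrace, zero_segments: list[tuple[float, float]]) -> float:
    """Baseline offset (pA) as the pooled mean over designated zero-current windows."""
    if not zero_segments:
        raise ValueError("need at least one zero-current window")
    chunks = []
    for t0, t1 in zero_segments:
        i0, i1 = int(round(t0 * trace.fs)), int(round(t1 * trace.fs))
        if i1 <= i0:
            raise ValueError(f"empty zero-current window ({t0}, {t1})")
        chunks.append(trace.samples[i0:i1])
    return float(np.concatenate(chunks).mean())


def idealize_half_amplitude(
    trace: CurrentTrace,
    i_unit: float,
    max_level: int,
    baseline: float = 0.0,
    noise_sd: float | None = None,
) -> EventTable:
    """Half-amplitude threshold idealization of a (baseline-subtracted) trace.

    Each sample is assigned the nearest integer conductance level (thresholds
    half-way between adjacent levels), clipped to [0, max_level]; runs of
    equal level become events.
    """
    if noise_sd is not None and abs(i_unit) < 3 * noise_sd:
        warnings.warn("unit current is below the noise floor; idealization unreliable")
    norm = (trace.samples - baseline) / i_unit
    raw = np.rint(norm).astype(int)
    if raw.max(initial=0) > max_level + 1:
        raise ValueError(
            f"observed excursions to level {raw.max()} exceed max_level={max_level}"
        )
    lv = np.clip(raw, 0, max_level)
    change = np.nonzero(np.diff(lv))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [lv.size]])
    return EventTable(
        lv[starts],
        (ends - starts) * trace.dt,
        patch_id=trace.patch_id,
        dt=trace.dt,
    )


def count_channels(bracket_events: EventTable) -> int:
    """Active-channel count: maximum simultaneously open level in the brackets."""
    if len(bracket_events) == 0:
        raise ValueError("empty bracket events")
    n = int(bracket_events.levels.max())
    if n == 0:
        warnings.warn("no channel openings in bracket segments; patch has no active channels")
    return n


def impose_dead_time(events: EventTable, td: float) -> EventTable:
    """Merge events shorter than the dead time ``td`` into their context.

    Each sub-td event is absorbed by concatenation with the preceding event
    (duration added, level kept); adjacent equal-level events are then merged.
    A leading sub-td event (no predecessor) is absorbed forward.  Total
    duration is conserved exactly and all surviving dwells are >= td.
    """
    if td < 0:
        raise ValueError("dead time must be non-negative")
    if events.dt is not None and td <= events.dt:
        warnings.warn("dead time at or below the sampling interval; no events merged")
        return replace(events, dead_time=td)

    out_levels: list[int] = []
    out_dwells: list[float] = []
    for lvl, dw in zip(events.levels, events.dwells):
        if dw < td and out_dwells:
            out_dwells[-1] += dw  # absorbed into the preceding event
        elif out_levels and lvl == out_levels[-1]:
            out_dwells[-1] += dw
        else:
            out_levels.append(int(lvl))
            out_dwells.append(float(dw))
    # a leading run of sub-td events is absorbed forward
    while len(out_dwells) > 1 and out_dwells[0] < td:
        if out_levels[1] == out_levels[0]:
            out_dwells[1] += out_dwells[0]
        else:
            out_dwells[1] += out_dwells[0]
        del out_levels[0], out_dwells[0]
        # absorbing forward may expose equal neighbours
        if len(out_levels) > 1 and out_levels[0] == out_levels[1]:
            out_dwells[0] += out_dwells[1]
            del out_levels[1], out_dwells[1]
    return EventTable(
        np.array(out_levels),
        np.array(out_dwells),
        patch_id=events.patch_id,
        n_channels=events.n_channels,
        dead_time=td,
        dt=events.dt,
    )


def select_window(
    segments: list[tuple[str, float, float]],
    policy: str | tuple[float, float] = "drop-leading",
    segment_label: str = "spontaneous",
    drop_fraction: float = 0.2,
    min_length: float = 1.0,
) -> AnalysisWindow:
    """Select the quasi-steady analysis window of the ATP-free segment.

    The default policy drops a fixed leading fraction (20%) of the segment,
    emulating the slow washout of ATP before spontaneous gating is sampled
    (e.g. the last ~4 min of a 5 min ATP-free exposure).  An explicit
    (t0, t1) policy is returned verbatim.
    """
    if isinstance(policy, tuple):
        w = AnalysisWindow(*policy)
    else:
        match = [s for s in segments if s[0] == segment_label]
        if not match:
            raise ValueError(f"no segment labelled {segment_label!r}")
        _, t0, t1 = match[0]
        w = AnalysisWindow(t0 + drop_fraction * (t1 - t0), t1)
    if w.duration < min_length:
        raise ValueError("analysis window collapsed below the minimum length")
    return w


def events_from_level_path(path: LevelPath, patch_id: str = "") -> EventTable:
    """Ground-truth EventTable from a simulated level path."""
    return EventTable(
        path.levels.astype(int),
        path.dwells,
        patch_id=patch_id,
        n_channels=path.n_channels,
    )
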