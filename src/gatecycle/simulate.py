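"""Exact continuous-time simulation of C-O-B channels and synthetic patch traces.

Generates ground-truth state paths (Gillespie), superimposes independent
channels into open-count level paths, and renders them as recorded currents:
sampling, Gaussian acquisition filtering and additive Gaussian noise, mimicking
an excised inside-out patch digitized at 10 kHz with 2 kHz on-line filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .scheme import STATES, GatingScheme, stationary_distribution

__all__ = [
    "StatePath",
    "SimProtocol",
    "CurrentTrace",
    "simulate_path",
    "superpose",
    "gaussian_kernel",
    "gaussian_filter",
    "synthesize_trace",
]

# -3 dB corner relation for a Gaussian filter: sigma_t = 0.1325 / f_c
_SIGMA_PER_FC = 0.8326 / (2.0 * np.pi)


@dataclass
class StatePath:
    """Piecewise-constant state trajectory of one channel.

    ``states[i]`` (index into C,O,B) holds on ``[times[i], times[i+1])``;
    the final dwell ends at ``duration``.
    """

    states: np.ndarray  # int codes 0=C, 1=O, 2=B
    times: np.ndarray  # entry times, s; times[0] == 0
    duration: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.states) != len(self.times):
            raise ValueError("states and times must have equal length")

    @property
    def dwells(self) -> np.ndarray:
        """Dwell durations, s (last dwell censored by ``duration``)."""
        edges = np.append(self.times, self.duration)
        return np.diff(edges)

    @property
    def state_labels(self) -> list[str]:
        return [STATES[s] for s in self.states]

    def open_indicator_path(self) -> "LevelPath":
        return superpose([self])


@dataclass
class LevelPath:
    """Open-channel count vs time (piecewise constant)."""

    levels: np.ndarray
    times: np.ndarray
    duration: float
    n_channels: int

    @property
    def dwells(self) -> np.ndarray:
        edges = np.append(self.times, self.duration)
        return np.diff(edges)

    def time_average(self) -> float:
        return float(np.dot(self.levels, self.dwells) / self.duration)

    def sample(self, fs: float) -> np.ndarray:
        """Level at sample instants k/fs, k = 0..floor(duration*fs)-1."""
        n = int(np.floor(self.duration * fs))
        t = np.arange(n) / fs
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.levels[idx].astype(float)


@dataclass
class SimProtocol:
    """Recording protocol for one synthetic patch.

    ``seg_durations`` is an ordered list of (scheme_label, duration_s)
    emulating the bracket / ATP-free / bracket exposure sequence.
    """

    n_channels: int = 1
    seg_durations: tuple = (("bracket", 30.0), ("spontaneous", 120.0), ("bracket", 30.0))
    fs: float = 10_000.0
    noise_sd: float | None = None  # pA; defaults to 0.15*|i_unit|
    f_acq: float = 2_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if any(d <= 0 for _, d in self.seg_durations):
            raise ValueError("segment durations must be positive")
        if self.fs <= 2 * self.f_acq:
            raise ValueError("sampling rate must exceed twice the filter corner")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.seg_durations))

    @property
    def segment_edges(self) -> list[tuple[str, float, float]]:
        """(label, t_start, t_end) per segment."""
        out, t = [], 0.0
        for label, d in self.seg_durations:
            out.append((label, t, t + d))
            t += d
        return out


@dataclass
class CurrentTrace:
    """Uniformly sampled current record, pA."""

    samples: np.ndarray
    dt: float
    segments: list = field(default_factory=list)  # (label, t_start, t_end)
    patch_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt


def simulate_path(
    scheme: GatingScheme,
    duration: float,
    seed: int | np.random.Generator = 0,
    init: str | int = "stationary",
) -> StatePath:
    """Gillespie simulation of one C-O-B channel for ``duration`` seconds.

    ``init`` is a state label ("C"/"O"/"B"), a state index, or "stationary"
    to draw the initial state from the stationary distribution.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = scheme.generator
    exit_rates = -np.diag(q)
    # per-state transition targets and probabilities
    targets, probs = [], []
    for i in range(3):
        row = q[i].copy()
        row[i] = 0.0
        tgt = np.nonzero(row)[0]
        targets.append(tgt)
        probs.append(row[tgt] / row[tgt].sum())

    if init == "stationary":
        state = int(rng.choice(3, p=stationary_distribution(scheme)))
    elif isinstance(init, str):
        state = STATES.index(init)
    else:
        state = int(init)

    states, times = [state], [0.0]
    t = 0.0
    while True:
        t += rng.exponential(1.0 / exit_rates[state])
        if t >= duration:
            break
        tgt = targets[state]
        state = int(tgt[0]) if tgt.size == 1 else int(rng.choice(tgt, p=probs[state]))
        states.append(state)
        times.append(t)
    return StatePath(np.array(states), np.array(times), duration)


def simulate_protocol_path(
    schemes: dict[str, GatingScheme],
    protocol: SimProtocol,
    rng: np.random.Generator,
) -> StatePath:
    """One channel's path across the protocol's segments.

    The channel carries its state across segment boundaries; the first
    segment starts from its scheme's stationary distribution.
    """
    all_states: list[int] = []
    all_times: list[float] = []
    t0 = 0.0
    state: str | int = "stationary"
    for label, dur in protocol.seg_durations:
        seg = simulate_path(schemes[label], dur, rng, init=state)
        all_states.extend(seg.states.tolist())
        all_times.extend((seg.times + t0).tolist())
        state = int(seg.states[-1])
        t0 += dur
    # collapse repeated states at the segment joins
    states = np.array(all_states, dtype=np.int8)
    times = np.array(all_times)
    keep = np.ones(states.size, dtype=bool)
    keep[1:] = states[1:] != states[:-1]
    return StatePath(states[keep], times[keep], t0)


def superpose(paths: list[StatePath]) -> LevelPath:
    """Open-channel count vs time for independent channels.

    Change points are the union of per-channel transition times that alter
    the count; consecutive equal levels are merged.
    """
    if not paths:
        raise ValueError("need at least one path")
    duration = paths[0].duration
    if any(abs(p.duration - duration) > 1e-12 for p in paths):
        raise ValueError("all paths must share the same duration")

    events: list[tuple[float, int]] = []  # (time, +1/-1 change in open count)
    level0 = 0
    for p in paths:
        is_open = (p.states == 1).astype(int)
        level0 += is_open[0]
        delta = np.diff(is_open)
        for t, d in zip(p.times[1:], delta):
            if d != 0:
                events.append((float(t), int(d)))
    events.sort()

    times = [0.0]
    levels = [level0]
    lvl = level0
    for t, d in events:
        lvl += d
        if t == times[-1]:
            levels[-1] = lvl
        else:
            times.append(t)
            levels.append(lvl)
    # merge consecutive equal levels (simultaneous +1/-1 cancellations)
    lv = np.array(levels)
    tm = np.array(times)
    keep = np.ones(lv.size, dtype=bool)
    keep[1:] = lv[1:] != lv[:-1]
    return LevelPath(lv[keep], tm[keep], duration, n_channels=len(paths))


def burst_durations(path: StatePath) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth burst and interburst durations of a single-channel path.

    A burst is a maximal interval spent in {O, B} beginning and ending in O
    (flickers are internal); interbursts are the C dwells separating bursts.
    The censored first and last intervals are excluded.
    """
    in_burst = path.states != 0  # O or B
    edges = np.append(path.times, path.duration)
    # maximal runs of in-burst states
    change = np.nonzero(np.diff(in_burst.astype(int)))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(path.states)]])
    bursts, inter = [], []
    for a, b in zip(starts, ends):
        if a == 0 or b == len(path.states):
            continue  # censored at the record edges
        dur = edges[b] - edges[a]
        (bursts if in_burst[a] else inter).append(dur)
    return np.asarray(bursts), np.asarray(inter)


def gaussian_kernel(fc: float, fs: float) -> np.ndarray:
    """FIR Gaussian filter kernel with -3 dB corner ``fc``.

    sigma_t = 0.1325/fc (standard Gaussian-filter corner relation),
    truncated at +/-4 sigma, normalized to unit DC gain.
    """
    sigma = _SIGMA_PER_FC / fc * fs  # in samples
    half = max(1, int(np.ceil(4.0 * sigma)))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_filter(samples: np.ndarray, fc: float, fs: float) -> np.ndarray:
    """Zero-phase Gaussian filtering with edge-value padding."""
    k = gaussian_kernel(fc, fs)
    half = (k.size - 1) // 2
    padded = np.concatenate(
        [np.full(half, samples[0]), samples, np.full(half, samples[-1])]
    )
    return fftconvolve(padded, k, mode="valid")


def synthesize_trace(
    level_path: LevelPath,
    scheme: GatingScheme,
    protocol: SimProtocol,
    rng: np.random.Generator | None = None,
) -> CurrentTrace:
    """Render a level path as a noisy, filtered current record.

    current = level * i_unit sampled at fs, Gaussian-filtered at the
    acquisition corner, then white Gaussian noise added post-filter.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    ideal = level_path.sample(protocol.fs) * scheme.i_unit
    filtered = gaussian_filter(ideal, protocol.f_acq, protocol.fs)
    noise_sd = (
        protocol.noise_sd if protocol.noise_sd is not None else 0.15 * abs(scheme.i_unit)
    )
    if noise_sd > 0:
        filtered = filtered + rng.normal(0.0, noise_sd, filtered.size)
    return CurrentTrace(filtered, dt=1.0 / protocol.fs, segments=protocol.segment_edges)
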