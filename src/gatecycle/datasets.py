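"""Synthetic four-construct patch datasets emulating the study conditions.

Generates labelled patch recordings for the background construct (BG) and
the three mutant-cycle corners (R555K, T1246N, R555K-T1246N), each gating
spontaneously on its own C-O-B scheme during the ATP-free segment and on a
shared high-P_o "bracket" scheme during the flanking ATP exposures.

Default spontaneous schemes share the closing and flicker kinetics
(tau_b = 1.566 s, ~10 ms flickers) and differ only in opening rate, chosen
so the stationary P_o matches each construct's reported mean
(0.15 / 0.034 / 0.044 / 0.11); mutations act predominantly on the opening
rate, leaving closing rates nearly unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .idealize import EventTable, events_from_level_path
from .scheme import GatingScheme
from .simulate import (
    CurrentTrace,
    SimProtocol,
    StatePath,
    simulate_protocol_path,
    superpose,
    synthesize_trace,
)

__all__ = [
    "CONSTRUCTS",
    "default_schemes",
    "bracket_scheme",
    "PatchRecording",
    "make_construct_datasets",
]

CONSTRUCTS = ("BG", "R555K", "T1246N", "R555K-T1246N")

# spontaneous P_o targets per construct (reported means)
_PO_TARGETS = {"BG": 0.15, "R555K": 0.034, "T1246N": 0.044, "R555K-T1246N": 0.11}
# reported patch counts per construct
DEFAULT_PATCH_COUNTS = {"BG": 21, "R555K": 18, "T1246N": 19, "R555K-T1246N": 20}

_R_OC = 1.01 / 1.566  # shared closing rate: tau_b = (1/r_OC)(1 + r_OB/r_BO) = 1.566 s
_R_OB = 1.0  # flicker entry, s^-1
_R_BO = 100.0  # flicker exit: ~10 ms flickers
I_UNIT = -0.64  # pA at -80 mV (~8 pS)


def _r_co_for_po(po: float, r_oc: float = _R_OC, r_ob: float = _R_OB, r_bo: float = _R_BO) -> float:
    """Opening rate giving stationary open probability ``po`` on the C-O-B chain."""
    return r_oc / (1.0 / po - 1.0 - r_ob / r_bo)


def default_schemes() -> dict[str, GatingScheme]:
    """Spontaneous gating schemes of the four constructs."""
    return {
        label: GatingScheme(
            r_CO=_r_co_for_po(po), r_OC=_R_OC, r_OB=_R_OB, r_BO=_R_BO, i_unit=I_UNIT
        )
        for label, po in _PO_TARGETS.items()
    }


def bracket_scheme() -> GatingScheme:
    """High-P_o scheme of the ATP bracket segments (P_o ~= 0.8)."""
    return GatingScheme(r_CO=1.0, r_OC=0.25, r_OB=_R_OB, r_BO=_R_BO, i_unit=I_UNIT)


@dataclass
class PatchRecording:
    """One synthetic patch: the recorded trace plus its ground truth."""

    patch_id: str
    construct: str
    trace: CurrentTrace
    protocol: SimProtocol
    scheme: GatingScheme  # spontaneous-segment scheme (ground truth)
    paths: list[StatePath] = field(default_factory=list)
    true_events: EventTable | None = None  # superposed level path, no dead time

    @property
    def n_channels(self) -> int:
        return self.protocol.n_channels


def make_construct_datasets(
    patch_counts: dict[str, int] | int | None = None,
    schemes: dict[str, GatingScheme] | None = None,
    bracket: GatingScheme | None = None,
    bracket_duration: float = 30.0,
    spontaneous_duration: float = 120.0,
    fs: float = 10_000.0,
    f_acq: float = 2_000.0,
    noise_sd: float | None = None,
    channel_range: tuple[int, int] = (2, 6),
    master_seed: int = 0,
    keep_paths: bool = False,
) -> dict[str, list[PatchRecording]]:
    """Generate the four labelled construct datasets.

    Per-patch seeds and channel counts derive deterministically from
    ``master_seed``.  Each patch records bracket / spontaneous / bracket
    segments; ground-truth events (the superposed level path before any dead
    time) ride along with every trace.
    """
    if schemes is None:
        schemes = default_schemes()
    if bracket is None:
        bracket = bracket_scheme()
    if patch_counts is None:
        counts = dict(DEFAULT_PATCH_COUNTS)
    elif isinstance(patch_counts, int):
        counts = {label: patch_counts for label in schemes}
    else:
        counts = dict(patch_counts)
    if any(n < 2 for n in counts.values()):
        raise ValueError("need at least 2 patches per construct to form an SD")

    seed_rng = np.random.default_rng(master_seed)
    datasets: dict[str, list[PatchRecording]] = {}
    for label, spont in schemes.items():
        patches = []
        for j in range(counts[label]):
            patch_seed = int(seed_rng.integers(0, 2**31 - 1))
            rng = np.random.default_rng(patch_seed)
            n_ch = int(rng.integers(channel_range[0], channel_range[1] + 1))
            protocol = SimProtocol(
                n_channels=n_ch,
                seg_durations=(
                    ("bracket", bracket_duration),
                    ("spontaneous", spontaneous_duration),
                    ("bracket", bracket_duration),
                ),
                fs=fs,
                f_acq=f_acq,
                noise_sd=noise_sd,
                seed=patch_seed,
            )
            seg_schemes = {"bracket": bracket, "spontaneous": spont}
            paths = [
                simulate_protocol_path(seg_schemes, protocol, rng) for _ in range(n_ch)
            ]
            level = superpose(paths)
            pid = f"{label}-{j:02d}"
            trace = synthesize_trace(level, spont, protocol, rng)
            trace.patch_id = pid
            patches.append(
                PatchRecording(
                    patch_id=pid,
                    construct=label,
                    trace=trace,
                    protocol=protocol,
                    scheme=spont,
                    paths=paths if keep_paths else [],
                    true_events=events_from_level_path(level, patch_id=pid),
                )
            )
        datasets[label] = patches
    return datasets
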