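"""In-memory container for one muscle-strip recording.

A recording holds four synchronized channels sampled at a fixed rate --
force (mN), muscle length (um), and the two fura-2 fluorescence channels
(excitation 340 and 380 nm, emission 510 nm) -- together with the stimulus
times and typed protocol events needed to re-analyze the run blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

#: recognized protocol event kinds
EVENT_KINDS = ("stretch_start", "stretch_end", "rest_start", "rest_end",
               "preload_change")


@dataclass(frozen=True)
class Event:
    """Typed protocol marker at an absolute time within the recording."""

    kind: str
    time_s: float
    target_pct: float | None = None   # target preload (% L_max), if relevant

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise DataError(f"unknown event kind {self.kind!r}")


@dataclass
class TraceRecording:
    """Synchronized sampled channels plus annotations for one run."""

    sampling_rate: float            # Hz
    force: np.ndarray               # mN
    length: np.ndarray              # um
    f340: np.ndarray                # a.u.
    f380: np.ndarray                # a.u.
    stimulus_times: np.ndarray      # s, strictly increasing
    events: list = field(default_factory=list)
    f0_reference: float = 1.0       # quiescent, non-stretched fura-2 ratio
    diameter_um: float | None = None
    group_label: str | None = None

    def __post_init__(self):
        self.force = np.asarray(self.force, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        self.f340 = np.asarray(self.f340, dtype=float)
        self.f380 = np.asarray(self.f380, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n = len(self.force)
        for name in ("length", "f340", "f380"):
            if len(getattr(self, name)) != n:
                raise DataError(
                    f"channel {name!r} has {len(getattr(self, name))} samples "
                    f"but force has {n}; all channels must be equal length")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        if self.f0_reference <= 0:
            raise DataError("f0_reference must be positive")
        if self.stimulus_times.size and np.any(
                np.diff(self.stimulus_times) <= 0):
            raise DataError("stimulus_times must be strictly increasing")

    # -- convenience --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.force)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds (implied by index / sampling rate)."""
        return np.arange(self.n_samples) / self.sampling_rate

    def events_of(self, kind: str) -> list:
        return [e for e in self.events if e.kind == kind]
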