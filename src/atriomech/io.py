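"""Trace-file dialect: CSV channels plus a YAML metadata sidecar.

The channel file is plain CSV with header ``time_s,force_mN,length_um,
f340,f380`` and values serialized to 9 significant digits; the sidecar
(`<stem>.meta.yaml`) holds the sampling rate, the quiescent fluorescence
reference F0, the strip geometry, the group label, stimulus times, and
typed protocol events.  ``write_recording`` then ``read_recording`` is the
identity up to float round-trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (DataError, MetadataMismatchError, MissingColumnError,
                     NonUniformTimeError, ParameterError, TraceParseError)
from .recording import Event, TraceRecording

__all__ = ["read_recording", "write_recording", "RunConfig", "sidecar_path"]

COLUMNS = ("time_s", "force_mN", "length_um", "f340", "f380")
#: relative tolerance on time-step uniformity
TIME_TOL = 1e-6
SCHEMA_VERSION = 1


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.yaml")


def write_recording(recording: TraceRecording, path) -> Path:
    """Write the channel CSV and its metadata sidecar; returns the CSV path."""
    path = Path(path)
    t = recording.times()
    frame = pd.DataFrame({
        "time_s": t,
        "force_mN": recording.force,
        "length_um": recording.length,
        "f340": recording.f340,
        "f380": recording.f380,
    })
    frame.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "sampling_rate_hz": float(recording.sampling_rate),
        "f0_reference": float(recording.f0_reference),
        "diameter_um": (None if recording.diameter_um is None
                        else float(recording.diameter_um)),
        "group_label": recording.group_label,
        "stimulus_times_s": [round(float(s), 9)
                             for s in recording.stimulus_times],
        "events": [{"kind": e.kind, "time_s": round(float(e.time_s), 9),
                    "target_pct": (None if e.target_pct is None
                                   else float(e.target_pct))}
                   for e in recording.events],
    }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_recording(path) -> TraceRecording:
    """Read a dialect-conformant recording; raises a distinct error for a
    missing column, a non-uniform time axis, a metadata/CSV inconsistency,
    or a truncated/malformed file (naming the offending line)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise TraceParseError(f"malformed trace file {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise TraceParseError(f"empty trace file {path}") from exc
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise MissingColumnError(
            f"{path}: missing required column(s) {missing}")
    for c in COLUMNS:
        if frame[c].isna().any():
            line = int(frame[c].isna().idxmax()) + 2   # header + 1-based
            raise TraceParseError(
                f"{path}: non-numeric or missing value in column {c!r} "
                f"at line {line}")

    t = frame["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise TraceParseError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if dt0 <= 0 or np.any(np.abs(dt - dt0) > TIME_TOL * max(dt0, 1.0)):
        raise NonUniformTimeError(
            f"{path}: time column is not uniform to 1 ppm")

    meta_file = sidecar_path(path)
    if not meta_file.exists():
        raise MetadataMismatchError(f"missing metadata sidecar {meta_file}")
    with open(meta_file) as fh:
        meta = yaml.safe_load(fh)
    fs = float(meta["sampling_rate_hz"])
    if not math.isclose(1.0 / fs, dt0, rel_tol=1e-6):
        raise MetadataMismatchError(
            f"{meta_file}: sampling_rate_hz = {fs} inconsistent with the "
            f"time column step {dt0}")
    events = [Event(d["kind"], float(d["time_s"]),
                    None if d.get("target_pct") is None
                    else float(d["target_pct"]))
              for d in meta.get("events", [])]
    return TraceRecording(
        sampling_rate=fs,
        force=frame["force_mN"].to_numpy(dtype=float),
        length=frame["length_um"].to_numpy(dtype=float),
        f340=frame["f340"].to_numpy(dtype=float),
        f380=frame["f380"].to_numpy(dtype=float),
        stimulus_times=np.array(meta.get("stimulus_times_s", []), dtype=float),
        events=events,
        f0_reference=float(meta["f0_reference"]),
        diameter_um=meta.get("diameter_um"),
        group_label=meta.get("group_label"))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"protocol", "group", "seed", "overrides", "analysis",
               "outdir", "sampling_rate_hz"}
_KNOWN_ANALYSIS = {"pre_window_ms", "smooth_ms", "end_window", "alpha",
                   "ensemble_beats"}


@dataclass
class RunConfig:
    """Structured configuration for a simulate/analyze run."""

    protocol: dict = field(default_factory=dict)   # {"kind": ..., params...}
    group: str = "CONT"
    seed: int | None = None
    overrides: dict = field(default_factory=dict)  # MuscleParams overrides
    analysis: dict = field(default_factory=dict)
    outdir: str = "."
    sampling_rate_hz: float = 1000.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ParameterError(
                f"unknown config key(s): {sorted(unknown)}")
        bad = set(raw.get("analysis", {})) - _KNOWN_ANALYSIS
        if bad:
            raise ParameterError(
                f"unknown analysis option(s): {sorted(bad)}")
        cfg = cls(**raw)
        if cfg.seed is None and not cfg.overrides.get("noise_sd_force") == 0:
            # a seed is mandatory for any stochastic run; enforced again at
            # simulation time where the effective noise SDs are known
            pass
        return cfg
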