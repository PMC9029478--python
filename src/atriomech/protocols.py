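"""Protocol-level analyses: force-length, slow force response, post-rest
potentiation.

All slow-response outputs are ratios (percent of a within-run reference
twitch), which makes them invariant to rescaling of the raw force channel
and independent of the strip cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ProtocolError
from .features import (BeatWindow, CaTFeatures, MuscleGeometry,
                       TwitchFeatures, ensemble_average, extract_cat,
                       extract_twitch, segment_beats)
from .recording import TraceRecording

__all__ = ["LmaxEstimate", "FLResult", "SFRResult", "PRPResult",
           "find_lmax", "analyze_fl", "analyze_sfr", "analyze_prp"]

#: beats averaged per preload in the force-length protocol
ENSEMBLE_BEATS = 30
#: amplitude drift tolerated over a trailing 10-beat window before a beat
#: is considered unequilibrated (fraction of the segment median)
DRIFT_TOL = 0.02
DRIFT_WINDOW = 10


# ---------------------------------------------------------------------------
# L_max from a stepwise-stretch series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LmaxEstimate:
    l_max: float
    index: int
    reached: bool                  # False if active tension was still rising


def find_lmax(lengths, active_amplitudes) -> LmaxEstimate:
    """Length of maximal active amplitude from a stepwise stretch.

    If the amplitude is still rising at the final step the maximum is not
    interior and the estimate is flagged as not reached.
    """
    lengths = np.asarray(lengths, dtype=float)
    amps = np.asarray(active_amplitudes, dtype=float)
    if lengths.size != amps.size or lengths.size < 3:
        raise DataError("need >= 3 (length, amplitude) steps")
    if np.any(np.diff(lengths) <= 0):
        raise DataError("lengths must be strictly increasing")
    i = int(np.argmax(amps))
    reached = i < lengths.size - 1
    return LmaxEstimate(float(lengths[i]), i, reached)


# ---------------------------------------------------------------------------
# Force-length
# ---------------------------------------------------------------------------

@dataclass
class FLResult:
    """Per-preload ensemble twitch/CaT features and tension-length curves."""

    preloads: np.ndarray
    twitch: dict                    # preload -> TwitchFeatures
    cat: dict                       # preload -> CaTFeatures
    table: pd.DataFrame             # tidy, one row per preload

    def active_curve(self) -> np.ndarray:
        return np.array([self.twitch[p].active_amplitude
                         for p in self.preloads])

    def passive_curve(self) -> np.ndarray:
        return np.array([self.twitch[p].passive_tension
                         for p in self.preloads])


def _stable_beats(beats: list[BeatWindow]) -> list[BeatWindow]:
    """Drop beats whose trailing amplitude drift exceeds DRIFT_TOL per
    DRIFT_WINDOW beats (equilibration criterion)."""
    if len(beats) <= DRIFT_WINDOW:
        return beats
    amps = np.array([float(np.max(b.force[b.stim_index:])
                           - np.mean(b.force[:b.stim_index]))
                     for b in beats])
    med = np.median(amps)
    if med <= 0:
        return beats
    keep = []
    for i, b in enumerate(beats):
        lo = max(0, i - DRIFT_WINDOW + 1)
        window = amps[lo:i + 1]
        drift = (window[-1] - window[0]) / med
        if i < DRIFT_WINDOW or abs(drift) <= DRIFT_TOL:
            keep.append(b)
    return keep if keep else beats


def analyze_fl(recording: TraceRecording,
               geometry: MuscleGeometry | None = None,
               ensemble_beats: int = ENSEMBLE_BEATS,
               **extract_kwargs) -> FLResult:
    """Ensemble-averaged twitch and CaT characteristics per preload.

    Beats overlapping a preload change are excluded, unequilibrated beats
    are dropped, the last ``ensemble_beats`` stable beats at each preload
    are averaged, and tension is normalized by the elliptic cross-section.
    """
    if geometry is None:
        if recording.diameter_um is None:
            raise ProtocolError("geometry (strip diameter) is required")
        geometry = MuscleGeometry(recording.diameter_um)
    beats = segment_beats(recording)
    by_pct: dict[float, list[BeatWindow]] = {}
    for b in beats:
        if b.preload_pct is None or b.tags:
            continue
        by_pct.setdefault(b.preload_pct, []).append(b)
    if len(by_pct) < 2:
        raise ProtocolError("force-length analysis needs >= 2 preloads")
    for pct in by_pct:
        if not 75.0 <= pct <= 100.0:
            raise ProtocolError(f"preload {pct}% outside the 75-100% range")

    twitch, cat, rows = {}, {}, []
    for pct in sorted(by_pct):
        stable = _stable_beats(by_pct[pct])
        if len(stable) < 5:
            raise ProtocolError(
                f"fewer than 5 steady beats at preload {pct}%")
        avg = ensemble_average(stable[-ensemble_beats:])
        tw = extract_twitch(avg, geometry, **extract_kwargs)
        ct = extract_cat(avg, **extract_kwargs)
        twitch[pct], cat[pct] = tw, ct
        rows.append({
            "preload_pct": pct, "n_beats": len(stable[-ensemble_beats:]),
            "passive_tension_mN_mm2": tw.passive_tension,
            "active_tension_mN_mm2": tw.active_amplitude,
            "peak_total_tension_mN_mm2": tw.peak_total_tension,
            "force_ttp_ms": tw.ttp, "force_t50_ms": tw.t50_relax,
            "force_max_norm_rise_per_s": tw.max_norm_rise,
            "force_max_norm_decline_per_s": tw.max_norm_decline,
            "cat_diastolic_F_F0": ct.diastolic_level,
            "cat_amplitude_F_F0": ct.amplitude,
            "cat_ttp_ms": ct.ttp, "cat_t50_ms": ct.t50_decay,
            "cat_max_norm_rise_per_s": ct.max_norm_rise,
            "cat_max_norm_decay_per_s": ct.max_norm_decay,
        })
    preloads = np.array(sorted(by_pct))
    return FLResult(preloads=preloads, twitch=twitch, cat=cat,
                    table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Slow force response
# ---------------------------------------------------------------------------

#: series emitted by analyze_sfr, as (name, channel attribute) pairs
_SFR_SERIES = (
    ("force_amplitude", "twitch", "active_amplitude"),
    ("force_ttp", "twitch", "ttp"),
    ("force_t50", "twitch", "t50_relax"),
    ("cat_diastolic", "cat", "diastolic_level"),
    ("cat_amplitude", "cat", "amplitude"),
    ("cat_t50", "cat", "t50_decay"),
)


@dataclass
class SFRResult:
    """Twitch-by-twitch percent time courses after a rapid stretch.

    Every series is expressed as % of the first post-stretch twitch, so the
    series start at 100% by construction.  ``sfr_magnitude`` is the mean
    force amplitude over the final ``end_window`` beats as % of the first
    post-stretch twitch.
    """

    beat_times_s: np.ndarray
    series: dict                    # name -> % array
    sfr_magnitude: float
    end_values: dict                # name -> mean % over the end window
    end_window: int


def analyze_sfr(recording: TraceRecording, end_window: int = 10,
                geometry: MuscleGeometry | None = None,
                **extract_kwargs) -> SFRResult:
    """Per-beat SFR time courses and the end-of-response magnitude."""
    stretch_end = recording.events_of("stretch_end")
    if not stretch_end:
        raise ProtocolError("recording has no stretch_end event")
    t_se = stretch_end[0].time_s
    if geometry is None:
        geometry = MuscleGeometry(recording.diameter_um or 250.0)

    beats = [b for b in segment_beats(recording)
             if b.stimulus_time >= t_se
             and not {"stretch_start", "stretch_end"} & b.tags]
    if not beats:
        raise ProtocolError("no post-stretch beats in recording")
    if beats[-1].stimulus_time - beats[0].stimulus_time < 60.0:
        raise ProtocolError("need >= 60 s of post-stretch beats")

    feats = [(extract_twitch(b, geometry, **extract_kwargs),
              extract_cat(b, **extract_kwargs)) for b in beats]
    series = {}
    for name, which, attr in _SFR_SERIES:
        vals = np.array([getattr(tw if which == "twitch" else ct, attr)
                         for tw, ct in feats])
        ref = vals[0]
        if not np.isfinite(ref) or ref == 0:
            raise DataError(f"degenerate first post-stretch beat ({name})")
        series[name] = 100.0 * vals / ref
    end_values = {name: float(np.mean(v[-end_window:]))
                  for name, v in series.items()}
    return SFRResult(
        beat_times_s=np.array([b.stimulus_time - t_se for b in beats]),
        series=series,
        sfr_magnitude=end_values["force_amplitude"],
        end_values=end_values,
        end_window=end_window)


# ---------------------------------------------------------------------------
# Post-rest potentiation
# ---------------------------------------------------------------------------

@dataclass
class PRPResult:
    """Post-pause percent series relative to the last pre-pause twitch."""

    pre_reference: dict             # feature name -> pre-pause value
    series: dict                    # name -> % array over post-pause beats
    prp_extent: float               # max force amplitude % in first 10 beats
    cat_first_beat_pct: float
    recovery_beats: int | None      # beats to return within 5% of pre-pause


def analyze_prp(recording: TraceRecording, search_beats: int = 10,
                recovery_tol: float = 5.0,
                geometry: MuscleGeometry | None = None,
                **extract_kwargs) -> PRPResult:
    """Potentiation extent and recovery after a pacing pause.

    The reference is the last complete pre-pause twitch; the maximal effect
    is searched over the first ``search_beats`` post-pause beats.
    """
    starts = recording.events_of("rest_start")
    ends = recording.events_of("rest_end")
    if not starts or not ends:
        raise ProtocolError("recording has no rest event")
    t0, t1 = starts[0].time_s, ends[0].time_s
    if t1 - t0 < 10.0:
        raise ProtocolError(f"rest period is too short ({t1 - t0:.1f} s)")
    if geometry is None:
        geometry = MuscleGeometry(recording.diameter_um or 250.0)

    beats = segment_beats(recording)
    pre = [b for b in beats if b.stimulus_time < t0 and not b.tags]
    post = [b for b in beats if b.stimulus_time >= t1]
    if len(pre) < 10 or len(post) < 20:
        raise ProtocolError("need >= 10 pre-pause and >= 20 post-pause beats")

    ref_tw = extract_twitch(pre[-1], geometry, **extract_kwargs)
    ref_ct = extract_cat(pre[-1], **extract_kwargs)
    if ref_tw.degenerate or ref_ct.degenerate:
        raise DataError("degenerate pre-pause reference twitch")
    pre_reference = {
        "force_amplitude": ref_tw.active_amplitude,
        "cat_diastolic": ref_ct.diastolic_level,
        "cat_amplitude": ref_ct.amplitude,
    }

    post_tw = [extract_twitch(b, geometry, **extract_kwargs) for b in post]
    post_ct = [extract_cat(b, **extract_kwargs) for b in post]
    series = {
        "force_amplitude": 100.0 * np.array(
            [t.active_amplitude for t in post_tw]) / ref_tw.active_amplitude,
        "cat_diastolic": 100.0 * np.array(
            [c.diastolic_level for c in post_ct]) / ref_ct.diastolic_level,
        "cat_amplitude": 100.0 * np.array(
            [c.amplitude for c in post_ct]) / ref_ct.amplitude,
    }
    force_pct = series["force_amplitude"]
    prp_extent = float(np.max(force_pct[:search_beats]))
    within = np.nonzero(np.abs(force_pct - 100.0) <= recovery_tol)[0]
    recovery = int(within[0]) + 1 if within.size else None
    return PRPResult(pre_reference=pre_reference, series=series,
                     prp_extent=prp_extent,
                     cat_first_beat_pct=float(series["cat_amplitude"][0]),
                     recovery_beats=recovery)
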