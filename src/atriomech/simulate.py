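"""Forward model of atrial muscle-strip recordings.

The per-beat Ca transient is a two-exponential waveform (closed-form peak
time, monotone decay), and isometric force follows a first-order activation
ODE driven by a Hill function of the Ca level above diastole:

    dA/dt = k_act * H(Ca) * (1 - A) - k_rel * A,
    H(c)  = (c/K)^n / (1 + (c/K)^n),      K = hill_k / sens_mult,
    F(t)  = passive(preload) + f_ref * fl_active(preload) * A(t).

Slow phenomena act as per-beat multiplicative envelopes on the Ca-transient
amplitude, the diastolic level, and the myofilament sensitivity:

* SFR (after a rapid stretch): mono-exponential approach to a plateau with
  shared time constant ``sfr_tau``;
* PRP (after a pacing pause): a rest-duration-dependent first-beat gain that
  decays geometrically back to steady state with ratio ``prp_recirc``,
  plus a small transient diastolic dip/overshoot.

All randomness (measurement noise, inter-muscle variability) is seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError, ProtocolError, ResolutionError
from .params import DEFAULTS, PACING_HZ, DEFAULT_FS, FL_GRID, MuscleParams
from .recording import Event, TraceRecording

__all__ = [
    "FLProtocol", "SFRProtocol", "PRPProtocol",
    "cat_peak_time", "simulate_cat_beat", "simulate_force_beat",
    "simulate_protocol", "make_cohort",
]

#: fractional modulation depth of the F380 channel per unit normalized Ca
_F380_DEPTH = 0.10
#: baseline intensity of the F380 channel (a.u.)
_F380_BASE = 500.0
#: PRP diastolic transient: dip depth, number of dipped beats, overshoot,
#: and beat-count constant of the recovery (magnitudes are not reported in
#: the source protocols; chosen small, see docs/methods.md)
_PRP_DIA_DIP = 0.02
_PRP_DIA_DIP_BEATS = 3
_PRP_DIA_OVERSHOOT = 0.01
_PRP_DIA_TAU_BEATS = 5.0


# ---------------------------------------------------------------------------
# Protocol specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FLProtocol:
    """Isometric force-length run: steady pacing at each preload in turn."""

    preload_grid: tuple = FL_GRID
    beats_per_preload: int = 36
    gap_s: float = 1.0          # unpaced gap at each preload change

    def __post_init__(self):
        bad = [p for p in self.preload_grid if p not in FL_GRID]
        if bad:
            raise ProtocolError(
                f"FL preloads must lie on the grid {FL_GRID}, got {bad}")
        if len(self.preload_grid) < 1:
            raise ProtocolError("FL grid must not be empty")


@dataclass(frozen=True)
class SFRProtocol:
    """Rapid stretch followed by continuous twitch-by-twitch recording."""

    from_pct: float = 85.0
    to_pct: float = 95.0
    ramp_ms: float = 100.0
    pre_beats: int = 30
    duration_s: float = 180.0   # post-stretch recording length


@dataclass(frozen=True)
class PRPProtocol:
    """Pacing pause (rest) at fixed preload, then resumed stimulation."""

    rest_s: float = 60.0
    preload_pct: float = 95.0
    pre_beats: int = 60
    post_beats: int = 60


# ---------------------------------------------------------------------------
# Per-beat waveforms
# ---------------------------------------------------------------------------

def cat_peak_time(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Closed-form peak time (ms after stimulus) of the two-exponential
    Ca transient, t* = tau_r*tau_d/(tau_d - tau_r) * ln(tau_d/tau_r)."""
    tr, td = float(tau_rise_ms), float(tau_decay_ms)
    if not 0 < tr < td:
        raise ParameterError("need 0 < tau_rise < tau_decay")
    return tr * td / (td - tr) * math.log(td / tr)


def _cat_shape(t_s: np.ndarray, tau_r_ms: float, tau_d_ms: float) -> np.ndarray:
    """Unit-free transient shape exp(-t/tau_d) - exp(-t/tau_r), t in s."""
    tr, td = tau_r_ms / 1e3, tau_d_ms / 1e3
    return np.exp(-t_s / td) - np.exp(-t_s / tr)


def _cat_shape_peak(tau_r_ms: float, tau_d_ms: float) -> float:
    t_star = cat_peak_time(tau_r_ms, tau_d_ms) / 1e3
    return float(_cat_shape(np.array([t_star]), tau_r_ms, tau_d_ms)[0])


def simulate_cat_beat(params: MuscleParams, t_grid: np.ndarray,
                      amp_mult: float = 1.0,
                      dia_mult: float = 1.0) -> np.ndarray:
    """Noise-free Ca transient (F/F0) for one beat on ``t_grid`` (s after
    stimulus): diastole plus an amplitude-normalized two-exponential."""
    if amp_mult < 0:
        raise ParameterError(f"amp_mult must be >= 0, got {amp_mult}")
    if dia_mult <= 0:
        raise ParameterError(f"dia_mult must be > 0, got {dia_mult}")
    t = np.asarray(t_grid, dtype=float)
    s = _cat_shape(t, params.tau_ca_rise, params.tau_ca_decay)
    s_peak = _cat_shape_peak(params.tau_ca_rise, params.tau_ca_decay)
    return params.ca_dia * dia_mult + params.ca_amp * amp_mult * (s / s_peak)


def _hill(x_pow_n: np.ndarray) -> np.ndarray:
    return x_pow_n / (1.0 + x_pow_n)


def _integrate_activation(drive: np.ndarray, drive_half: np.ndarray,
                          k_act: float, k_rel: float, dt: float,
                          a0=0.0) -> np.ndarray:
    """RK4 integration of dA/dt = k_act*H*(1-A) - k_rel*A.

    ``drive`` is H sampled on the grid, shape (..., n); ``drive_half`` is H
    at the midpoints, shape (..., n-1).  Vectorized over leading axes.
    """
    a_max = float(np.max(drive, initial=0.0))
    if dt * (k_act * a_max + k_rel) > 2.0:
        raise ResolutionError(
            "time grid too coarse for stable activation integration: "
            f"dt*(k_act*Hmax + k_rel) = {dt * (k_act * a_max + k_rel):.2f} > 2")

    def f(h, a):
        return k_act * h * (1.0 - a) - k_rel * a

    n = drive.shape[-1]
    out = np.empty_like(drive)
    a = np.full(drive.shape[:-1], float(a0)) if drive.ndim > 1 else float(a0)
    out[..., 0] = a
    for i in range(n - 1):
        h0 = drive[..., i]
        hh = drive_half[..., i]
        h1 = drive[..., i + 1]
        k1 = f(h0, a)
        k2 = f(hh, a + 0.5 * dt * k1)
        k3 = f(hh, a + 0.5 * dt * k2)
        k4 = f(h1, a + dt * k3)
        a = a + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[..., i + 1] = a
    return out


def simulate_force_beat(params: MuscleParams, ca_waveform: np.ndarray,
                        t_grid: np.ndarray, preload_pct: float,
                        sens_mult: float = 1.0,
                        dia_level: float | None = None) -> np.ndarray:
    """Isometric force (mN) for one beat, driven by a sampled Ca waveform.

    ``dia_level`` is the diastolic Ca of this beat (defaults to the first
    sample); only Ca above diastole drives the myofilaments.
    """
    if sens_mult <= 0:
        raise ParameterError(f"sens_mult must be > 0, got {sens_mult}")
    if not 75.0 <= preload_pct <= 100.0:
        raise ParameterError(
            f"preload_pct must lie in [75, 100], got {preload_pct}")
    ca = np.asarray(ca_waveform, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if ca.shape != t.shape or ca.ndim != 1 or len(ca) < 3:
        raise ParameterError("ca_waveform and t_grid must be equal-length 1-D")
    dt = float(t[1] - t[0])
    if dia_level is None:
        dia_level = float(ca[0])
    c = np.clip(ca - dia_level, 0.0, None)
    x = (c * sens_mult / params.hill_k) ** params.hill_n
    x_half = (0.5 * (c[:-1] + c[1:]) * sens_mult / params.hill_k) ** params.hill_n
    a = _integrate_activation(_hill(x), _hill(x_half),
                              params.k_act, params.k_rel, dt)
    active = params.f_ref * params.active_scale(preload_pct) * a
    return params.passive_force_mN(preload_pct) + active


# ---------------------------------------------------------------------------
# Vectorized paced-segment synthesis
# ---------------------------------------------------------------------------

def _beat_grid(fs: float):
    period = 1.0 / PACING_HZ
    spb = int(round(period * fs))
    if abs(spb / fs - period) > 1e-9:
        raise ProtocolError("sampling_rate must resolve the pacing period")
    t = np.arange(spb) / fs
    return t, spb


def _paced_activation(params: MuscleParams, fs: float,
                      amp_m: np.ndarray, dia_m: np.ndarray,
                      sens_m: np.ndarray):
    """Activation and Ca matrices for ``len(amp_m)`` beats, shape
    (n_beats, samples per beat); the stimulus sits at each row start.

    The activation depends only on the per-beat multipliers (not on the
    preload), so force at any preload is passive + f_ref*fl_active*A.
    """
    t, spb = _beat_grid(fs)
    dt = 1.0 / fs
    s = _cat_shape(t, params.tau_ca_rise, params.tau_ca_decay)
    s_half = _cat_shape(t[:-1] + 0.5 * dt, params.tau_ca_rise,
                        params.tau_ca_decay)
    s_peak = _cat_shape_peak(params.tau_ca_rise, params.tau_ca_decay)
    sn, sn_half = s / s_peak, s_half / s_peak

    camp = params.ca_amp * np.asarray(amp_m, dtype=float)      # (n_beats,)
    u = (camp * np.asarray(sens_m) / params.hill_k) ** params.hill_n
    x = u[:, None] * sn[None, :] ** params.hill_n
    x_half = u[:, None] * sn_half[None, :] ** params.hill_n
    a = _integrate_activation(_hill(x), _hill(x_half),
                              params.k_act, params.k_rel, dt)
    ca = (params.ca_dia * np.asarray(dia_m)[:, None]
          + camp[:, None] * sn[None, :])
    return a, ca


class _Assembler:
    """Accumulates spans of samples plus stimulus/event annotations."""

    def __init__(self, params: MuscleParams, fs: float):
        self.params = params
        self.fs = fs
        self.force, self.ca, self.length = [], [], []
        self.stims, self.events = [], []
        self.t = 0.0

    def _n(self, duration_s):
        return int(round(duration_s * self.fs))

    def quiet(self, duration_s, pct, dia_mult=1.0, dia_mult_end=None,
              settle_tau_s=10.0):
        """Unpaced span at constant length; diastolic Ca may relax
        exponentially from ``dia_mult`` to ``dia_mult_end``."""
        n = self._n(duration_s)
        if n == 0:
            return
        p = self.params
        tt = np.arange(n) / self.fs
        if dia_mult_end is None or dia_mult_end == dia_mult:
            dia = np.full(n, p.ca_dia * dia_mult)
        else:
            w = np.exp(-tt / settle_tau_s)
            dia = p.ca_dia * (dia_mult_end + (dia_mult - dia_mult_end) * w)
        self.force.append(np.full(n, p.passive_force_mN(pct)))
        self.ca.append(dia)
        self.length.append(np.full(n, pct / 100.0 * p.L_max))
        self.t += n / self.fs

    @staticmethod
    def _check_multipliers(amp_m, dia_m, sens_m):
        amp_m = np.atleast_1d(np.asarray(amp_m, dtype=float))
        dia_m = np.atleast_1d(np.asarray(dia_m, dtype=float))
        sens_m = np.atleast_1d(np.asarray(sens_m, dtype=float))
        if np.any(amp_m < 0) or np.any(dia_m <= 0) or np.any(sens_m <= 0):
            raise ParameterError("per-beat multipliers must be positive "
                                 "(amplitude may be zero)")
        return amp_m, dia_m, sens_m

    def paced(self, pct, amp_m, dia_m, sens_m):
        amp_m, dia_m, sens_m = self._check_multipliers(amp_m, dia_m, sens_m)
        p = self.params
        a, ca = _paced_activation(p, self.fs, amp_m, dia_m, sens_m)
        force = (p.passive_force_mN(pct)
                 + p.f_ref * p.active_scale(pct) * a)
        n_beats = len(amp_m)
        period = 1.0 / PACING_HZ
        self.stims.extend(self.t + period * b for b in range(n_beats))
        self.force.append(force.ravel())
        self.ca.append(ca.ravel())
        self.length.append(np.full(force.size,
                                   pct / 100.0 * self.params.L_max))
        self.t += n_beats * period

    def ramp_beat(self, pct_from, pct_to, ramp_start_s, ramp_dur_s):
        """One paced beat during which the preload ramps between preloads.

        Active force scales with fl_active of the instantaneous preload, so
        the beat's tail is sample-identical to a steady beat at the target
        preload (the immediate Frank-Starling step happens at the ramp).
        """
        p = self.params
        a, ca = _paced_activation(p, self.fs, np.ones(1), np.ones(1),
                                  np.ones(1))
        a = a[0]
        t = np.arange(a.size) / self.fs
        pcts = np.interp(t, [ramp_start_s, ramp_start_s + ramp_dur_s],
                         [pct_from, pct_to])
        # piecewise composition keeps the post-ramp samples bit-identical
        # to the steady-state expression at pct_to
        force = np.empty_like(a)
        for pct, mask in ((pct_from, t < ramp_start_s),
                          (pct_to, t >= ramp_start_s + ramp_dur_s)):
            force[mask] = (p.passive_force_mN(pct)
                           + p.f_ref * p.active_scale(pct) * a[mask])
        mid = (t >= ramp_start_s) & (t < ramp_start_s + ramp_dur_s)
        force[mid] = (np.asarray(p.passive_tension(pcts[mid]))
                      * p.cross_section_mm2()
                      + p.f_ref * np.asarray(p.active_scale(pcts[mid]))
                      * a[mid])
        self.stims.append(self.t)
        self.force.append(force)
        self.ca.append(ca[0])
        self.length.append(pcts / 100.0 * p.L_max)
        self.t += 1.0 / PACING_HZ

    def event(self, kind, time_s, target_pct=None):
        self.events.append(Event(kind, time_s, target_pct))

    def finish(self, seed, rng_required) -> TraceRecording:
        p = self.params
        force = np.concatenate(self.force)
        ca = np.concatenate(self.ca)
        length = np.concatenate(self.length)
        f0 = 1.0
        f380 = _F380_BASE * (1.0 - _F380_DEPTH * (ca - p.ca_dia) / p.ca_amp)
        f340 = ca * f0 * f380
        if rng_required:
            if seed is None:
                raise ParameterError(
                    "seed is required when noise SDs are non-zero")
            rng = np.random.default_rng(seed)
            if p.noise_sd_force > 0:
                force = force + rng.normal(0.0, p.noise_sd_force, len(force))
            if p.noise_sd_fluor > 0:
                f340 = f340 + rng.normal(0.0, p.noise_sd_fluor, len(f340))
                f380 = f380 + rng.normal(0.0, p.noise_sd_fluor, len(f380))
        return TraceRecording(
            sampling_rate=self.fs, force=force, length=length,
            f340=f340, f380=f380,
            stimulus_times=np.array(self.stims), events=self.events,
            f0_reference=f0, diameter_um=p.diameter,
            group_label=p.group_label)


# ---------------------------------------------------------------------------
# Protocol-level simulation
# ---------------------------------------------------------------------------

def _sfr_envelopes(params: MuscleParams, t_after_stretch: np.ndarray):
    """Slow-response multipliers as a function of time since stretch end."""
    w = 1.0 - np.exp(-t_after_stretch / params.sfr_tau)
    return (1.0 + params.sfr_gain_ca * w,
            1.0 + params.sfr_dia_gain * w,
            1.0 + params.sfr_gain_sens * w)


def _prp_multipliers(params: MuscleParams, rest_s: float, n_beats: int):
    """Post-pause per-beat multipliers: geometric amplitude recovery plus a
    transient diastolic dip that recovers above the pre-pause level."""
    load = 1.0 - math.exp(-rest_s / params.prp_load_tau)
    m1 = 1.0 + params.prp_load_gain * load
    k = np.arange(n_beats)
    amp_m = 1.0 + (m1 - 1.0) * params.prp_recirc ** k
    # scale the diastolic transient with the same rest-duration saturation so
    # that a zero-length rest leaves every multiplier at exactly 1
    sat = load / (1.0 - math.exp(-60.0 / params.prp_load_tau))
    dia_dev = np.where(
        k < _PRP_DIA_DIP_BEATS,
        -_PRP_DIA_DIP,
        _PRP_DIA_OVERSHOOT - (_PRP_DIA_OVERSHOOT + _PRP_DIA_DIP)
        * np.exp(-(k - _PRP_DIA_DIP_BEATS) / _PRP_DIA_TAU_BEATS))
    dia_m = 1.0 + sat * dia_dev
    sens_m = np.ones(n_beats)
    return amp_m, dia_m, sens_m, m1


def simulate_protocol(params: MuscleParams, protocol, seed: int | None = None,
                      sampling_rate: float = DEFAULT_FS) -> TraceRecording:
    """Simulate one full protocol run and return an annotated recording."""
    if not isinstance(protocol, (FLProtocol, SFRProtocol, PRPProtocol)):
        raise ProtocolError(
            f"unknown protocol specification {type(protocol).__name__!r}")
    asm = _Assembler(params, sampling_rate)
    noisy = params.noise_sd_force > 0 or params.noise_sd_fluor > 0
    period = 1.0 / PACING_HZ
    ones = np.ones

    if isinstance(protocol, FLProtocol):
        first = True
        for pct in protocol.preload_grid:
            gap = 0.5 if first else protocol.gap_s
            asm.event("preload_change", asm.t + gap / 2.0, target_pct=pct)
            asm.quiet(gap, pct)
            n = protocol.beats_per_preload
            asm.paced(pct, ones(n), ones(n), ones(n))
            first = False

    elif isinstance(protocol, SFRProtocol):
        pre, post = protocol.from_pct, protocol.to_pct
        asm.event("preload_change", 0.25, target_pct=pre)
        asm.quiet(0.5, pre)
        n_pre = protocol.pre_beats
        asm.paced(pre, ones(n_pre), ones(n_pre), ones(n_pre))
        # pacing continues through the stretch: the ramp bisects one twitch
        # (tagged and excluded from analysis) late in its relaxation
        ramp_s = protocol.ramp_ms / 1e3
        lead = 0.30
        asm.event("stretch_start", asm.t + lead)
        t_stretch_end = asm.t + lead + ramp_s
        asm.event("stretch_end", t_stretch_end, target_pct=post)
        asm.ramp_beat(pre, post, lead, ramp_s)
        n_post = int(round(protocol.duration_s * PACING_HZ))
        t_env = (asm.t - t_stretch_end) + period * np.arange(n_post)
        amp_m, dia_m, sens_m = _sfr_envelopes(params, t_env)
        asm.paced(post, amp_m, dia_m, sens_m)

    else:  # PRPProtocol
        pct = protocol.preload_pct
        asm.event("preload_change", 0.25, target_pct=pct)
        asm.quiet(0.5, pct)
        n_pre = protocol.pre_beats
        asm.paced(pct, ones(n_pre), ones(n_pre), ones(n_pre))
        amp_m, dia_m, sens_m, _ = _prp_multipliers(
            params, protocol.rest_s, protocol.post_beats)
        asm.event("rest_start", asm.t)
        asm.quiet(protocol.rest_s, pct, dia_mult=1.0, dia_mult_end=dia_m[0])
        asm.event("rest_end", asm.t)
        asm.paced(pct, amp_m, dia_m, sens_m)

    return asm.finish(seed, rng_required=noisy)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: parameters receiving lognormal inter-muscle multipliers, by CV class
_GAIN_FIELDS = ("sfr_gain_ca", "sfr_gain_sens", "sfr_dia_gain",
                "prp_load_gain")
_KINETIC_FIELDS = ("tau_ca_rise", "tau_ca_decay", "k_act", "k_rel",
                   "sfr_tau", "prp_load_tau", "ca_amp")


def _lognormal_mult(rng, cv, size):
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2),
                         size=size)


def make_cohort(group: str, n: int, seed: int,
                base: MuscleParams | None = None) -> list[MuscleParams]:
    """Draw ``n`` per-muscle parameter sets around the group defaults.

    Slow-response gains receive lognormal multipliers with CV
    ``cv_inter_muscle``; kinetic constants receive multipliers with the
    (smaller) CV ``cv_kinetics``.  Multipliers have unit mean, so group means
    equal the defaults up to Monte-Carlo error, and positivity/sign of every
    parameter is preserved.  Deterministic given the seed.
    """
    if n < 1:
        raise ParameterError(f"cohort size must be >= 1, got {n}")
    base = base if base is not None else DEFAULTS[group.upper()]
    rng = np.random.default_rng(seed)
    gains = {f: _lognormal_mult(rng, base.cv_inter_muscle, n)
             for f in _GAIN_FIELDS}
    kin = {f: _lognormal_mult(rng, base.cv_kinetics, n)
           for f in _KINETIC_FIELDS}
    cohort = []
    for i in range(n):
        upd = {f: getattr(base, f) * gains[f][i] for f in _GAIN_FIELDS}
        upd.update({f: getattr(base, f) * kin[f][i] for f in _KINETIC_FIELDS})
        cohort.append(replace(base, **upd))
    return cohort
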