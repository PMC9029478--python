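"""Feature-extraction tests: ratiometric conversion, geometry, beat
segmentation, scalar descriptors against closed-form oracles, ensemble
averaging, and self-normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriomech import (DataError, ParameterError, cross_section,
                       ensemble_average, extract_cat, extract_twitch,
                       fura_ratio, segment_beats, self_normalize,
                       simulate_cat_beat, simulate_protocol)
from atriomech.errors import DegenerateTwitchError
from atriomech.features import MuscleGeometry
from atriomech.simulate import SFRProtocol, PRPProtocol

from conftest import make_beat, synthetic_beat

GEO = MuscleGeometry(200.0)


class TestFuraRatio:
    def test_equal_channels_unity(self):
        x = np.ones(100)
        assert np.allclose(fura_ratio(x, x, 1.0), 1.0)

    def test_normalization_cancels(self):
        f380 = np.linspace(1.0, 2.0, 50)
        assert np.allclose(fura_ratio(2.0 * f380, f380, 2.0), 1.0)

    def test_round_trip_from_known_waveform(self, cont_nf):
        # construct channels from a known F/F0 waveform and recover it
        t = np.arange(400) / 1000.0
        ca = simulate_cat_beat(cont_nf, t)
        f0 = 1.7
        f380 = 480.0 * (1.0 - 0.08 * (ca - ca[0]))
        f340 = ca * f0 * f380
        assert np.allclose(fura_ratio(f340, f380, f0), ca, rtol=1e-12)

    def test_nonpositive_f380_rejected(self):
        with pytest.raises(DataError):
            fura_ratio(np.ones(3), np.array([1.0, 0.0, 1.0]), 1.0)
        with pytest.raises(ParameterError):
            fura_ratio(np.ones(3), np.ones(3), 0.0)


class TestCrossSection:
    def test_printed_formula(self):
        # S = pi d^2 / 12; d = 100 um -> 2.61799e-3 mm^2
        assert cross_section(100.0) == pytest.approx(2.61799e-3, rel=1e-5)

    def test_quadratic_scaling(self):
        assert cross_section(200.0) == pytest.approx(4 * cross_section(100.0))

    def test_exact_against_independent_evaluation(self):
        d = 173.2
        assert cross_section(d) == math.pi * d * d / 12.0 * 1e-6

    def test_invalid_diameter(self):
        with pytest.raises(ParameterError):
            cross_section(0.0)


class TestSegmentation:
    def test_paced_run_produces_one_window_per_stimulus(self, cont_nf):
        rec = simulate_protocol(cont_nf, SFRProtocol(duration_s=61,
                                                     pre_beats=10))
        beats = segment_beats(rec)
        assert len(beats) == len(rec.stimulus_times)
        spb = int(rec.sampling_rate / 2.0)
        full = [b for b in beats[1:-1]]
        assert all(len(b.force) == spb + b.stim_index for b in full[:-1])

    def test_no_windows_during_rest(self, cont_nf):
        rec = simulate_protocol(cont_nf, PRPProtocol(pre_beats=12,
                                                     post_beats=25))
        t0 = rec.events_of("rest_start")[0].time_s
        t1 = rec.events_of("rest_end")[0].time_s
        beats = segment_beats(rec)
        inside = [b for b in beats if t0 < b.stimulus_time < t1]
        assert inside == []
        # pre-pause windows are capped at the pacing period, not stretched
        # across the rest
        last_pre = max((b for b in beats if b.stimulus_time < t0),
                       key=lambda b: b.stimulus_time)
        assert len(last_pre.force) <= int(0.55 * rec.sampling_rate)

    def test_first_post_stretch_beat_identified(self, cont_nf):
        rec = simulate_protocol(cont_nf, SFRProtocol(duration_s=61))
        t_se = rec.events_of("stretch_end")[0].time_s
        beats = segment_beats(rec)
        post = [b for b in beats if b.stimulus_time >= t_se]
        expected = min(s for s in rec.stimulus_times if s >= t_se)
        assert post[0].stimulus_time == expected
        # the twitch bisected by the ramp carries the stretch tags
        bisected = [b for b in beats if "stretch_start" in b.tags]
        assert len(bisected) == 1

    def test_overlapping_stimuli_rejected(self, cont_nf):
        rec = simulate_protocol(cont_nf, SFRProtocol(duration_s=61))
        rec.stimulus_times = np.sort(np.append(rec.stimulus_times,
                                               rec.stimulus_times[0] + 1e-3))
        with pytest.raises(DataError):
            segment_beats(rec)


class TestTwitchFeatures:
    def test_exponential_rise_rate_oracle(self):
        # y = A(1 - e^(-t/tau)), tau = 50 ms: max dy/dt / A = 1/tau = 20/s
        beat = synthetic_beat(lambda t: 2.0 * (1 - np.exp(-t / 0.050)))
        tw = extract_twitch(beat, GEO)
        assert tw.max_norm_rise == pytest.approx(20.0, rel=0.05)

    def test_exponential_decay_t50_oracle(self):
        # y = A e^(-t/tau), tau = 80 ms: t50 = tau ln 2 = 55.45 ms
        beat = synthetic_beat(lambda t: 1.5 * np.exp(-t / 0.080))
        tw = extract_twitch(beat, GEO, smooth_ms=0.0)
        assert tw.ttp == pytest.approx(0.0, abs=1.0)
        assert tw.t50_relax == pytest.approx(80.0 * math.log(2), abs=1.0)

    def test_two_exponential_ttp_oracle(self, cont_nf):
        # frozen closed-form peak time for (20, 100) ms is 40.24 ms
        p = cont_nf.replace(tau_ca_rise=20.0, tau_ca_decay=100.0)
        beat = synthetic_beat(lambda t: simulate_cat_beat(p, t) - p.ca_dia,
                              baseline=1.0)
        cat = extract_cat(beat)
        assert cat.ttp == pytest.approx(40.24, abs=1.0)

    def test_amplitude_scale_invariance(self):
        f = lambda t: np.exp(-t / 0.08) - np.exp(-t / 0.02)
        b1 = synthetic_beat(lambda t: 1.0 * f(t), baseline=0.5)
        b2 = synthetic_beat(lambda t: 10.0 * f(t), baseline=0.5)
        t1, t2 = extract_twitch(b1, GEO), extract_twitch(b2, GEO)
        assert t1.ttp == t2.ttp
        assert t1.t50_relax == pytest.approx(t2.t50_relax, rel=1e-9)
        assert t1.max_norm_rise == pytest.approx(t2.max_norm_rise, rel=1e-9)
        assert t2.active_amplitude == pytest.approx(
            10.0 * t1.active_amplitude, rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(a=st.floats(0.05, 50.0), b=st.floats(-3.0, 3.0))
    def test_affine_invariance_of_timing_features(self, a, b):
        # timing and normalized-rate descriptors are invariant under
        # y -> a*y + b with a > 0
        f = lambda t: np.exp(-t / 0.09) - np.exp(-t / 0.025)
        base = synthetic_beat(f, baseline=1.0)
        scaled = make_beat(force=a * base.force + b)
        t0 = extract_twitch(base, GEO)
        t1 = extract_twitch(scaled, GEO)
        assert t1.ttp == t0.ttp
        assert t1.t50_relax == pytest.approx(t0.t50_relax, rel=1e-9)
        assert t1.max_norm_rise == pytest.approx(t0.max_norm_rise, rel=1e-6)
        assert t1.max_norm_decline == pytest.approx(t0.max_norm_decline,
                                                    rel=1e-6)

    def test_t50_interpolation_against_oversampled_oracle(self, cont_nf):
        # linear interpolation at 1 kHz lands within one sample interval of
        # a 100x-oversampled measurement, across a tau grid
        for tr, td in [(10.0, 60.0), (20.0, 100.0), (30.0, 80.0)]:
            p = cont_nf.replace(tau_ca_rise=tr, tau_ca_decay=td)
            coarse = synthetic_beat(
                lambda t: simulate_cat_beat(p, t) - p.ca_dia,
                baseline=1.0, fs=1000.0)
            fine = synthetic_beat(
                lambda t: simulate_cat_beat(p, t) - p.ca_dia,
                baseline=1.0, fs=100_000.0)
            c = extract_cat(coarse, smooth_ms=0.0)
            f = extract_cat(fine, smooth_ms=0.0)
            assert c.t50_decay == pytest.approx(f.t50_decay, abs=1.0)

    def test_decay_constant_recovery_asymptotics(self, cont_nf):
        # t50/ln2 -> tau_decay as tau_decay/tau_rise grows; within 5% once
        # the separation reaches ~30x, and monotonically converging
        errs = []
        for ratio in (5.0, 10.0, 30.0):
            tr = 2.0
            p = cont_nf.replace(tau_ca_rise=tr, tau_ca_decay=tr * ratio)
            beat = synthetic_beat(
                lambda t: simulate_cat_beat(p, t) - p.ca_dia,
                baseline=1.0, fs=20000.0)
            cat = extract_cat(beat, smooth_ms=0.0)
            est = cat.t50_decay / math.log(2)
            errs.append(abs(est - tr * ratio) / (tr * ratio))
        assert errs == sorted(errs, reverse=True)
        assert errs[-1] < 0.05

    def test_flat_trace_flagged_degenerate(self):
        beat = make_beat(force=np.full(500, 2.0))
        tw = extract_twitch(beat, GEO)
        assert tw.degenerate and math.isnan(tw.ttp)

    def test_sub_noise_amplitude_flagged(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0.0, 1.0, 500)
        y[60:70] += 0.5     # bump well under 3x noise SD
        tw = extract_twitch(make_beat(force=y), GEO)
        assert tw.degenerate


class TestEnsembleAverage:
    def test_identical_beats_average_to_input(self):
        f = lambda t: np.exp(-t / 0.08) - np.exp(-t / 0.02)
        beats = [synthetic_beat(f) for _ in range(30)]
        avg = ensemble_average(beats)
        assert np.allclose(avg.force, beats[0].force)

    def test_noise_reduction_follows_clt(self):
        rng = np.random.default_rng(5)
        sigma = 0.2
        f = lambda t: np.exp(-t / 0.08) - np.exp(-t / 0.02)
        clean = synthetic_beat(f)
        beats = [make_beat(force=clean.force
                           + rng.normal(0, sigma, len(clean.force)))
                 for _ in range(30)]
        avg = ensemble_average(beats)
        resid_sd = np.std(avg.force - clean.force)
        assert resid_sd == pytest.approx(sigma / math.sqrt(30), rel=0.2)

    def test_mixed_preloads_rejected(self):
        f = lambda t: np.exp(-t / 0.08) - np.exp(-t / 0.02)
        a = synthetic_beat(f)
        b = synthetic_beat(f)
        a.preload_pct, b.preload_pct = 85.0, 95.0
        with pytest.raises(DataError):
            ensemble_average([a] * 5 + [b] * 5)

    def test_few_beats_warns(self):
        f = lambda t: np.exp(-t / 0.08) - np.exp(-t / 0.02)
        with pytest.warns(UserWarning):
            ensemble_average([synthetic_beat(f) for _ in range(3)])


class TestSelfNormalize:
    def test_peak_exactly_one(self):
        f = lambda t: 3.1 * (np.exp(-t / 0.08) - np.exp(-t / 0.02))
        norm = self_normalize(synthetic_beat(f, baseline=2.0))
        assert norm.force.max() == pytest.approx(1.0, abs=1e-12)
        assert np.mean(norm.force[:norm.stim_index]) == pytest.approx(
            0.0, abs=1e-12)

    def test_idempotent(self):
        f = lambda t: np.exp(-t / 0.08) - np.exp(-t / 0.02)
        once = self_normalize(synthetic_beat(f, baseline=1.0))
        twice = self_normalize(once)
        assert np.allclose(once.force, twice.force, atol=1e-12)

    def test_degenerate_beat_rejected(self):
        with pytest.raises(DegenerateTwitchError):
            self_normalize(make_beat(force=np.zeros(500)))

    def test_mct_normalized_twitch_wider(self, cont_nf, mct_nf):
        # half-maximum width ordering of the normalized CaT: MCT wider
        widths = {}
        for p in (cont_nf, mct_nf):
            beat = synthetic_beat(
                lambda t: simulate_cat_beat(p, t) - p.ca_dia, baseline=1.0)
            norm = self_normalize(beat)
            above = np.nonzero(norm.ca >= 0.5)[0]
            widths[p.group_label] = (above[-1] - above[0]) / beat.sampling_rate
        assert widths["MCT"] > widths["CONT"]
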