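"""Forward-model tests: waveform closed forms, ODE behavior, protocol
assembly, and cohort generation."""

import numpy as np
import pytest

from atriomech import (ParameterError, ProtocolError, ResolutionError,
                       cat_peak_time, make_cohort, simulate_cat_beat,
                       simulate_force_beat, simulate_protocol)
from atriomech.params import MuscleParams
from atriomech.simulate import FLProtocol, PRPProtocol, SFRProtocol

from conftest import noise_free


@pytest.fixture(scope="module")
def t_grid():
    return np.arange(500) / 1000.0


class TestCaTBeat:
    def test_peak_time_closed_form(self):
        # t* = tau_r tau_d/(tau_d-tau_r) ln(tau_d/tau_r); frozen value for
        # (20, 100) ms computed from the closed form
        assert cat_peak_time(20.0, 100.0) == pytest.approx(40.236, abs=1e-3)

    def test_simulated_peak_matches_closed_form(self, cont_nf):
        # on a fine grid the sampled argmax lies within one sample of t*
        fs = 10000.0
        t = np.arange(int(0.5 * fs)) / fs
        for tr, td in [(20.0, 100.0), (10.0, 30.0), (40.0, 90.0)]:
            p = cont_nf.replace(tau_ca_rise=tr, tau_ca_decay=td)
            ca = simulate_cat_beat(p, t)
            t_peak = t[np.argmax(ca)] * 1e3
            assert t_peak == pytest.approx(cat_peak_time(tr, td),
                                           abs=1e3 / fs)

    def test_zero_amplitude_is_flat_diastole(self, cont_nf, t_grid):
        ca = simulate_cat_beat(cont_nf, t_grid, amp_mult=0.0)
        assert np.allclose(ca, cont_nf.ca_dia)

    def test_amplitude_above_baseline(self, cont_nf, t_grid):
        ca = simulate_cat_beat(cont_nf, t_grid, amp_mult=1.3, dia_mult=1.1)
        assert ca.max() - ca[0] == pytest.approx(1.3 * cont_nf.ca_amp,
                                                 rel=1e-3)
        assert ca[0] == pytest.approx(1.1 * cont_nf.ca_dia)

    def test_mct_time_to_peak_slower(self, cont_nf, mct_nf):
        # pulmonary-hypertensive kinetics: CaT peaks later than in controls
        ttp_c = cat_peak_time(cont_nf.tau_ca_rise, cont_nf.tau_ca_decay)
        ttp_m = cat_peak_time(mct_nf.tau_ca_rise, mct_nf.tau_ca_decay)
        assert ttp_m > ttp_c
        # calibrated prolongation: 42.6% relative and 14.2 ms absolute
        assert ttp_m / ttp_c == pytest.approx(1.426, abs=0.01)
        assert ttp_m - ttp_c == pytest.approx(14.2, abs=0.3)

    def test_negative_multiplier_rejected(self, cont_nf, t_grid):
        with pytest.raises(ParameterError):
            simulate_cat_beat(cont_nf, t_grid, amp_mult=-0.1)
        with pytest.raises(ParameterError):
            simulate_cat_beat(cont_nf, t_grid, dia_mult=0.0)


class TestForceBeat:
    def test_clamped_ca_gives_constant_passive(self, cont_nf, t_grid):
        flat = np.full_like(t_grid, cont_nf.ca_dia)
        f = simulate_force_beat(cont_nf, flat, t_grid, preload_pct=90.0)
        assert np.allclose(f, cont_nf.passive_force_mN(90.0))

    def test_sensitivity_raises_peak_force(self, cont_nf, t_grid):
        ca = simulate_cat_beat(cont_nf, t_grid)
        f1 = simulate_force_beat(cont_nf, ca, t_grid, 90.0, sens_mult=1.0)
        f2 = simulate_force_beat(cont_nf, ca, t_grid, 90.0, sens_mult=2.0)
        assert f2.max() > f1.max()

    def test_force_peak_lags_ca_peak(self, cont_nf, mct_nf, t_grid):
        for p in (cont_nf, mct_nf):
            ca = simulate_cat_beat(p, t_grid)
            f = simulate_force_beat(p, ca, t_grid, 95.0)
            assert t_grid[np.argmax(f)] > t_grid[np.argmax(ca)]

    def test_relaxation_complete_within_cycle(self, cont_nf, mct_nf, t_grid):
        # at 2 Hz the twitch must return to within 1% of passive force
        for p in (cont_nf, mct_nf):
            ca = simulate_cat_beat(p, t_grid)
            f = simulate_force_beat(p, ca, t_grid, 95.0)
            passive = p.passive_force_mN(95.0)
            active_peak = f.max() - passive
            assert abs(f[-1] - passive) < 0.01 * active_peak

    def test_mct_force_ttp_slower_at_any_preload(self, cont_nf, mct_nf,
                                                 t_grid):
        for pct in (75.0, 90.0, 100.0):
            tt = {}
            for p in (cont_nf, mct_nf):
                ca = simulate_cat_beat(p, t_grid)
                f = simulate_force_beat(p, ca, t_grid, pct)
                tt[p.group_label] = t_grid[np.argmax(f)]
            assert tt["MCT"] > tt["CONT"]

    def test_coarse_grid_raises_resolution_error(self, cont_nf):
        p = cont_nf.replace(k_rel=500.0)
        t = np.arange(75) / 150.0
        ca = simulate_cat_beat(p, t)
        with pytest.raises(ResolutionError):
            simulate_force_beat(p, ca, t, 90.0)


class TestProtocols:
    def test_seed_determinism_bit_exact(self, cont):
        r1 = simulate_protocol(cont, PRPProtocol(post_beats=20), seed=11)
        r2 = simulate_protocol(cont, PRPProtocol(post_beats=20), seed=11)
        for ch in ("force", "length", "f340", "f380"):
            assert np.array_equal(getattr(r1, ch), getattr(r2, ch))
        assert np.array_equal(r1.stimulus_times, r2.stimulus_times)

    def test_seed_required_when_noisy(self, cont):
        with pytest.raises(ParameterError):
            simulate_protocol(cont, SFRProtocol(duration_s=61))

    def test_unknown_protocol_rejected(self, cont):
        with pytest.raises(ProtocolError):
            simulate_protocol(cont, object())

    def test_fl_grid_validated(self):
        with pytest.raises(ProtocolError):
            FLProtocol(preload_grid=(77.0,))

    def test_zero_gain_sfr_beats_identical(self, cont_nf):
        p = cont_nf.replace(sfr_gain_ca=0.0, sfr_gain_sens=0.0,
                            sfr_dia_gain=0.0)
        rec = simulate_protocol(p, SFRProtocol(duration_s=62, pre_beats=4))
        spb = int(rec.sampling_rate / 2.0)
        t_se = rec.events_of("stretch_end")[0].time_s
        post = [s for s in rec.stimulus_times if s >= t_se]
        i0 = int(round(post[0] * rec.sampling_rate))
        first = rec.force[i0:i0 + spb]
        for s in post[1:][::10]:
            i = int(round(s * rec.sampling_rate))
            beat = rec.force[i:i + spb]
            if len(beat) == spb:
                assert np.array_equal(beat, first)

    def test_prp_zero_rest_leaves_multipliers_at_one(self, cont_nf):
        from atriomech.simulate import _prp_multipliers
        amp, dia, sens, m1 = _prp_multipliers(cont_nf, 0.0, 20)
        assert m1 == 1.0
        assert np.allclose(amp, 1.0) and np.allclose(dia, 1.0)
        assert np.allclose(sens, 1.0)

    def test_prp_diastolic_dips_then_overshoots(self, cont_nf):
        from atriomech.simulate import _prp_multipliers
        _, dia, _, _ = _prp_multipliers(cont_nf, 60.0, 60)
        assert dia[0] < 1.0
        assert dia[-1] > 1.0

    def test_recording_annotations_support_blind_reanalysis(self, cont_nf):
        rec = simulate_protocol(cont_nf, SFRProtocol(duration_s=61))
        assert rec.events_of("stretch_start") and rec.events_of("stretch_end")
        diffs = np.diff(rec.stimulus_times)
        # paced spacing is exactly the 2 Hz period except across the ramp
        assert np.isclose(np.median(diffs), 0.5)
        assert rec.f380.min() > 0


class TestCohort:
    def test_zero_cv_reproduces_defaults(self, cont):
        base = cont.replace(cv_inter_muscle=0.0, cv_kinetics=0.0)
        cohort = make_cohort("CONT", 5, seed=1, base=base)
        for m in cohort:
            assert m.sfr_gain_ca == base.sfr_gain_ca
            assert m.tau_ca_rise == base.tau_ca_rise

    def test_same_seed_same_cohort(self):
        a = make_cohort("MCT", 8, seed=42)
        b = make_cohort("MCT", 8, seed=42)
        assert all(x == y for x, y in zip(a, b))

    def test_lognormal_cv_recovered(self, cont):
        # moment check: sample CV of a gain across 10^4 muscles ~ nominal CV
        base = cont.replace(cv_inter_muscle=0.2)
        cohort = make_cohort("CONT", 10_000, seed=7, base=base)
        g = np.array([m.sfr_gain_ca for m in cohort])
        cv = np.std(g) / abs(np.mean(g))
        assert cv == pytest.approx(0.2, rel=0.05)

    def test_group_mean_near_defaults(self, cont):
        cohort = make_cohort("CONT", 4000, seed=3)
        g = np.mean([m.prp_load_gain for m in cohort])
        assert g == pytest.approx(cont.prp_load_gain, rel=0.02)

    def test_invalid_size_rejected(self):
        with pytest.raises(ParameterError):
            make_cohort("CONT", 0, seed=1)


class TestParamInvariants:
    def test_tau_ordering_enforced(self, cont):
        with pytest.raises(ParameterError):
            cont.replace(tau_ca_rise=80.0, tau_ca_decay=20.0)

    def test_recirculation_bounded(self, cont):
        with pytest.raises(ParameterError):
            cont.replace(prp_recirc=1.0)

    def test_fl_active_must_peak_at_lmax(self, cont):
        with pytest.raises(ParameterError):
            cont.replace(fl_active=((75.0, 0.5), (100.0, 0.4)))

    def test_passive_exceeds_active_at_high_preload(self, cont, mct):
        # calibrated resting-tension law: passive >= peak active tension at
        # 95 and 100% L_max
        for p in (cont, mct):
            for pct in (95.0, 100.0):
                active = 2.0 * p.active_scale(pct)
                assert p.passive_tension(pct) >= active
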