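"""Periodogram, onsets, entrainment/phase metrics, and masking analyses."""

import numpy as np
import pytest

import polysom as ps
from polysom.io import DARK, LIGHT, NREM, REM, WAKE


def square_wave_trace(period_h=24.0, n_days=10, high=20.0, low=0.0, seed=None):
    n = n_days * 1440
    t = np.arange(n)
    phase = (t % (period_h * 60)) / (period_h * 60)
    counts = np.where(phase >= 0.5, high, low)
    if seed is not None:
        counts = counts + np.random.default_rng(seed).poisson(1.0, n)
    return ps.ActivityTrace(counts, dd=True)


class TestChi2Periodogram:
    def test_noiseless_square_wave_exact_period(self):
        res = ps.chi2_periodogram(square_wave_trace(24.0))
        assert res.best_period_h == pytest.approx(24.0)

    def test_affine_invariance_exact(self):
        trace = square_wave_trace(24.0, seed=0)
        a = ps.chi2_periodogram(trace)
        b = ps.chi2_periodogram(ps.ActivityTrace(trace.counts * 3 + 7, dd=True))
        np.testing.assert_allclose(a.qp, b.qp, rtol=1e-9)

    def test_null_exceedance_near_alpha(self):
        fracs = []
        for seed in range(50):
            x = np.random.default_rng(seed).poisson(5.0, 8 * 1440).astype(float)
            res = ps.chi2_periodogram(ps.ActivityTrace(x, dd=True), alpha=0.01)
            fracs.append(np.mean(res.qp > res.threshold))
        assert 0.0 <= np.mean(fracs) <= 0.02

    def test_constant_trace_rejected(self):
        with pytest.raises(ps.PolysomError, match="variance"):
            ps.chi2_periodogram(ps.ActivityTrace(np.full(10 * 1440, 3.0), dd=True))

    def test_short_trace_rejected(self):
        with pytest.raises(ps.PolysomError):
            ps.chi2_periodogram(ps.ActivityTrace(np.ones(1440), dd=True))

    def test_recovers_free_running_period(self):
        errs = []
        for seed in range(5):
            tr = ps.simulate_activity(ps.SimConfig(tau_dd_h=24.4), 10, "DD",
                                      seed=seed)
            errs.append(ps.chi2_periodogram(tr).best_period_h - 24.4)
        assert np.max(np.abs(errs)) < 0.1


class TestAmplitude:
    def test_qp_scale_invariant_but_waveform_doubles(self):
        trace = square_wave_trace(24.0, seed=1)
        doubled = ps.ActivityTrace(trace.counts * 2, dd=True)
        a = ps.amplitude(ps.chi2_periodogram(trace))
        b = ps.amplitude(ps.chi2_periodogram(doubled))
        assert b["peak_excess"] == pytest.approx(a["peak_excess"], rel=1e-6)
        assert b["peak_to_nadir"] == pytest.approx(2 * a["peak_to_nadir"], rel=1e-6)

    def test_no_peak_is_an_error(self):
        x = np.random.default_rng(2).poisson(5.0, 8 * 1440).astype(float)
        res = ps.chi2_periodogram(ps.ActivityTrace(x, dd=True))
        if res.best_period_h is None:
            with pytest.raises(ps.PolysomError):
                ps.amplitude(res)

    def test_waveform_amplitude_monotone_in_configured_amplitude(self):
        vals = []
        for amp in (4.0, 12.0, 36.0):
            p2n = []
            for seed in range(5):
                tr = ps.simulate_activity(ps.SimConfig(activity_amp=amp), 8,
                                          "DD", seed=seed)
                p2n.append(ps.amplitude(ps.chi2_periodogram(tr))["peak_to_nadir"])
            vals.append(np.mean(p2n))
        assert vals[0] < vals[1] < vals[2]


class TestOnsets:
    def test_step_activity_found_daily(self):
        trace = square_wave_trace(24.0, n_days=8)
        trace = ps.ActivityTrace(trace.counts, schedule=ps.LightSchedule.ld_12_12(8 * 86400))
        onsets = ps.detect_onsets(trace)
        assert len(onsets) == 8
        assert np.allclose(onsets % 1440, 720, atol=1.0)

    def test_all_zero_trace_has_no_onsets(self):
        trace = ps.ActivityTrace(np.zeros(5 * 1440))
        assert len(ps.detect_onsets(trace)) == 0

    def test_jitter_recovered(self, config):
        ests = []
        for seed in range(5):
            tr = ps.simulate_activity(config, 14, "LD", seed=seed)
            ests.append(ps.onset_variability(ps.detect_onsets(tr)))
        assert np.mean(ests) == pytest.approx(config.onset_jitter_sd_min, abs=4.0)


class TestPhaseAngle:
    def make_trace(self):
        return ps.ActivityTrace(np.ones(3 * 1440),
                                schedule=ps.LightSchedule.ld_12_12(3 * 86400))

    def test_mean_of_differences(self):
        onsets = np.array([12.2, 24 + 12.4, 48 + 11.9]) * 60.0
        mean, _ = ps.phase_angle(onsets, self.make_trace())
        assert mean == pytest.approx(1 / 6, abs=1e-9)

    def test_exact_lights_off_is_zero(self):
        onsets = np.array([12.0, 36.0, 60.0]) * 60.0
        mean, _ = ps.phase_angle(onsets, self.make_trace())
        assert mean == pytest.approx(0.0)

    def test_dd_trace_rejected(self):
        with pytest.raises(ps.PolysomError):
            ps.phase_angle(np.array([720.0, 2160.0, 3600.0]),
                           ps.ActivityTrace(np.ones(3 * 1440), dd=True))


class TestOnsetVariability:
    def test_perfectly_periodic_is_zero(self):
        onsets = 720 + np.arange(10) * 1440.0
        assert ps.onset_variability(onsets) == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_residuals_recovered(self):
        ests = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            onsets = 720 + np.arange(14) * 1440.0 + rng.normal(0, 10, 14)
            ests.append(ps.onset_variability(onsets))
        assert np.mean(ests) == pytest.approx(10.0, rel=0.4)

    def test_free_running_drift_absorbed(self):
        drift = 720 + np.arange(14) * (1440.0 + 24.0)  # tau = 24.4 h
        assert ps.onset_variability(drift) == pytest.approx(0.0, abs=1e-6)

    def test_too_few_onsets_rejected(self):
        with pytest.raises(ps.PolysomError):
            ps.onset_variability(np.array([720.0, 2160.0]))


class TestPhaseShift:
    def test_identical_lines_zero_shift(self):
        onsets = 720 + np.arange(16) * 1440.0
        pre, post = onsets[:7], onsets
        assert ps.phase_shift(pre, post, pulse_day=7) == pytest.approx(0.0)

    def test_displaced_post_line(self):
        onsets = 720 + np.arange(16) * 1440.0
        pre = onsets[:7]
        post = onsets + 30.0        # post onsets 0.5 h later = 0.5 h delay
        assert ps.phase_shift(pre, post, pulse_day=7) == pytest.approx(-0.5)

    def test_insufficient_onsets_rejected(self):
        with pytest.raises(ps.PolysomError):
            ps.phase_shift(np.array([720.0] * 2), np.array([720.0] * 20),
                           pulse_day=1)


class TestPulseMasking:
    def test_identical_days_all_zero(self, config):
        hyp, _ = ps.simulate_hypnogram(config, 24, seed=4)
        d = ps.pulse_masking(hyp, hyp, (14, 15))
        assert all(v == 0 for v in d.values())

    def test_full_swap_is_plus_minus_100(self):
        base = ps.Hypnogram((WAKE,) * 8640)
        pulse = ps.Hypnogram(tuple(
            NREM if 14 * 360 <= i < 15 * 360 else WAKE for i in range(8640)))
        d = ps.pulse_masking(pulse, base, (14, 15))
        assert d[NREM] == pytest.approx(100.0)
        assert d[WAKE] == pytest.approx(-100.0)


class TestUltradian:
    sched = ps.LightSchedule.ultradian_1h(86400.0)

    def test_constant_state_splits_evenly(self):
        hyp = ps.Hypnogram((NREM,) * 8640)
        s = ps.ultradian_summary(hyp, self.sched)
        assert s["light_min"][NREM] == pytest.approx(720.0)
        assert s["dark_min"][NREM] == pytest.approx(720.0)

    def test_perfect_segregation(self):
        labels = []
        for h in range(24):
            labels += [NREM if h % 2 == 0 else WAKE] * 360
        s = ps.ultradian_summary(ps.Hypnogram(tuple(labels)), self.sched)
        assert s["light_min"][NREM] == pytest.approx(720.0)
        assert s["dark_min"][WAKE] == pytest.approx(720.0)
        assert s["light_share_pct"][NREM] == pytest.approx(100.0)

    def test_24h_conservation_exact(self, config):
        hyp, _ = ps.simulate_hypnogram(config, 24, seed=5, schedule=self.sched)
        s = ps.ultradian_summary(hyp, self.sched)
        assert sum(s["total_min"].values()) == pytest.approx(1440.0)

    def test_non_hourly_schedule_rejected(self):
        hyp = ps.Hypnogram((WAKE,) * 8640)
        with pytest.raises(ps.PolysomError):
            ps.ultradian_summary(hyp, ps.LightSchedule.ld_12_12(86400.0))

    def test_masking_shifts_sleep_into_light_segments(self, config):
        shares = []
        for seed in range(20):
            hyp, _ = ps.simulate_hypnogram(config, 24, seed=seed,
                                           schedule=self.sched)
            shares.append(ps.ultradian_summary(hyp, self.sched)
                          ["light_share_pct"][NREM])
        assert np.mean(shares) > 55.0


class TestSustainedMasking:
    sched = ps.LightSchedule.ld_12_12(86400.0)

    def test_identical_architecture_zero_differences(self, config):
        hyp, _ = ps.simulate_hypnogram(config, 24, seed=6)
        out = ps.sustained_masking(hyp, self.sched, hyp, period_h=24.0)
        assert out["nrem_masking_diff_min"] == pytest.approx(0.0)
        assert out["wake_masking_diff_min"] == pytest.approx(0.0)

    def test_requires_period_estimate(self, config):
        hyp, _ = ps.simulate_hypnogram(config, 24, seed=7)
        with pytest.raises(ps.PolysomError):
            ps.sustained_masking(hyp, self.sched, hyp, period_h=None)

    def test_rem_free_dd_day_still_defined(self):
        hyp_ld = ps.Hypnogram((NREM,) * 4320 + (WAKE,) * 4320)
        hyp_dd = ps.Hypnogram((WAKE, NREM) * 4320)
        out = ps.sustained_masking(hyp_ld, self.sched, hyp_dd, period_h=24.0)
        assert np.isfinite(out["nrem_masking_diff_min"])
        assert np.isfinite(out["wake_masking_diff_min"])
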