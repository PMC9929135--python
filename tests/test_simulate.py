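"""Ground-truth generator: chain statistics, homeostat, signals, activity."""

import dataclasses

import numpy as np
import pytest

import polysom as ps
from polysom.io import DARK, LIGHT, NREM, REM, WAKE


def embedded_chain_fractions(config, phase):
    """Analytic stationary time-in-state of the configured semi-Markov chain.

    Visit rates of the embedded transition chain (WAKE->NREM always,
    NREM->REM w.p. p else WAKE, REM->WAKE w.p. q else NREM) solved by
    hand, weighted by the phase's mean bout durations.
    """
    p = min(config.rem_entry_prob * config.rem_entry_factor, 1.0)
    q = config.rem_to_wake_prob
    n = 1.0
    r = p * n
    w = n * (1 - p) + r * q
    dur = {
        WAKE: config.bout_mean_s[WAKE][phase] * config.wake_bout_factor
        / config.transition_rate_factor,
        NREM: config.bout_mean_s[NREM][phase] / config.transition_rate_factor,
        REM: config.bout_mean_s[REM][phase],
    }
    t = {WAKE: w * dur[WAKE], NREM: n * dur[NREM], REM: r * dur[REM]}
    total = sum(t.values())
    return {s: v / total for s, v in t.items()}


class TestHypnogramChain:
    def test_no_rem_when_entry_prob_zero(self, config):
        cfg = dataclasses.replace(config, rem_entry_prob=0.0)
        hyp, _ = ps.simulate_hypnogram(cfg, 24, seed=1)
        assert REM not in hyp.labels

    def test_stationary_fractions_match_embedded_chain(self):
        # uniform phases and no circadian modulation so the embedded-chain
        # stationary distribution is exact, not phase-averaged
        cfg = ps.SimConfig(bout_mean_s={
            WAKE: {LIGHT: 400.0, DARK: 400.0},
            NREM: {LIGHT: 400.0, DARK: 400.0},
            REM: {LIGHT: 100.0, DARK: 100.0},
        }, circadian_amp=0.0)
        expected = embedded_chain_fractions(cfg, LIGHT)
        fracs = {s: [] for s in (WAKE, NREM, REM)}
        for seed in range(50):
            hyp, _ = ps.simulate_hypnogram(cfg, 24, seed=seed)
            for s in fracs:
                fracs[s].append(np.mean([l == s for l in hyp.labels]))
        for s in fracs:
            assert abs(np.mean(fracs[s]) - expected[s]) < 0.03, s

    def test_wake_bout_factor_halves_wake_bouts(self, config):
        # stratified by phase: pooling phases would re-weight them because
        # shorter cycles produce more bouts per hour
        cfg_half = dataclasses.replace(config, wake_bout_factor=0.5)
        means = []
        for cfg in (config, cfg_half):
            durs = []
            for seed in range(50):
                hyp, _ = ps.simulate_hypnogram(cfg, 24, seed=seed)
                zts = hyp.epoch_zt_s() / 3600.0
                durs += [b.duration_s for b in ps.episodes(hyp)
                         if b.state == WAKE and zts[b.start_epoch] < 12.0]
            means.append(np.mean(durs))
        assert means[1] / means[0] == pytest.approx(0.5, rel=0.10)

    def test_rem_entered_only_from_nrem(self, default_day):
        hyp, _ = default_day
        for i in range(1, len(hyp)):
            if hyp.labels[i] == REM and hyp.labels[i - 1] != REM:
                assert hyp.labels[i - 1] == NREM

    def test_degenerate_config_rejected(self):
        with pytest.raises(ps.PolysomError):
            ps.SimConfig(bout_mean_s={WAKE: {LIGHT: 0.0, DARK: 0.0},
                                      NREM: {LIGHT: 0.0, DARK: 0.0},
                                      REM: {LIGHT: 0.0, DARK: 0.0}})


class TestHomeostat:
    def test_s_stays_in_unit_interval(self, config):
        for s0 in (0.0, 0.5, 1.0):
            cfg = dataclasses.replace(config, s0=s0, tau_decay_h=0.3,
                                      tau_rise_h=0.3)
            _, s = ps.simulate_hypnogram(cfg, 48, seed=3)
            assert s.min() >= 0.0 and s.max() <= 1.0

    def test_s_rises_in_wake_and_decays_in_nrem(self):
        s = ps.simulate_process_s([WAKE] * 10 + [NREM] * 10, 10.0, 8.0, 2.0, 0.5)
        assert np.all(np.diff(s[:10]) > 0)
        assert np.all(np.diff(s[10:]) < 0)


class TestDeterminism:
    def test_identical_seed_bit_identical(self, config):
        a_hyp, a_s = ps.simulate_hypnogram(config, 6, seed=9)
        b_hyp, b_s = ps.simulate_hypnogram(config, 6, seed=9)
        assert a_hyp.labels == b_hyp.labels
        np.testing.assert_array_equal(a_s, b_s)
        ra = ps.simulate_signals(a_hyp, a_s, config, seed=9)
        rb = ps.simulate_signals(b_hyp, b_s, config, seed=9)
        np.testing.assert_array_equal(ra.eeg, rb.eeg)
        ta = ps.simulate_activity(config, 3, "LD", seed=9)
        tb = ps.simulate_activity(config, 3, "LD", seed=9)
        np.testing.assert_array_equal(ta.counts, tb.counts)


class TestSignals:
    def test_all_nrem_delta_dominates_theta(self, config):
        hyp = ps.Hypnogram((NREM,) * 120)
        s = np.full(120, 0.5)
        rec = ps.simulate_signals(hyp, s, config, seed=4)
        spec = ps.epoch_spectrogram(rec)
        delta = ps.band_power(spec.power, ps.band("delta"), spec.bin_centers)
        theta = ps.band_power(spec.power, ps.band("theta"), spec.bin_centers)
        assert np.mean(delta > theta) >= 0.95

    def test_rem_emg_below_wake_emg(self, config):
        hyp = ps.Hypnogram((REM,) * 30 + (WAKE,) * 30)
        rec = ps.simulate_signals(hyp, np.full(60, 0.5), config, seed=5)
        feats = ps.compute_epoch_features(rec)
        rem_rms = feats["emg_rms"][:30]
        wake_rms = feats["emg_rms"][30:]
        # tones differ >3x -> separation in every epoch (boundary epochs
        # blend over the 0.5 s crossfade only)
        assert rem_rms.max() < wake_rms.min()

    def test_zero_gain_decorrelates_delta_from_pressure(self):
        cfg = ps.SimConfig(gain=0.0)
        hyp = ps.Hypnogram((NREM,) * 1000)
        rng = np.random.default_rng(6)
        s = rng.uniform(0, 1, 1000)
        spec = ps.spectrogram_from_templates(hyp, s, cfg, seed=6)
        delta = ps.band_power(spec.power, ps.band("delta"), spec.bin_centers)
        assert abs(np.corrcoef(delta, s)[0, 1]) < 0.1

    def test_positive_gain_couples_delta_to_pressure(self, config):
        hyp = ps.Hypnogram((NREM,) * 1000)
        rng = np.random.default_rng(6)
        s = rng.uniform(0, 1, 1000)
        spec = ps.spectrogram_from_templates(hyp, s, config, seed=6)
        delta = ps.band_power(spec.power, ps.band("delta"), spec.bin_centers)
        assert np.corrcoef(delta, s)[0, 1] > 0.8

    def test_component_above_nyquist_rejected(self, config):
        cfg = dataclasses.replace(config, fs=16.0)
        hyp = ps.Hypnogram((REM,) * 6)
        with pytest.raises(ps.PolysomError, match="fs"):
            ps.simulate_signals(hyp, np.zeros(6), cfg, seed=0)


class TestSDProtocol:
    def test_zero_leak_removes_all_window_sleep(self, config):
        cfg = dataclasses.replace(config, sd_leak=0.0)
        exp = ps.simulate_sd_experiment(cfg, 0.0, 6.0, "NONE", seed=7,
                                        with_spectra=False)
        zt = exp.test_hyp.epoch_zt_s() / 3600.0
        window = [l for l, t in zip(exp.test_hyp.labels, zt) if t < 6.0]
        assert all(l == WAKE for l in window)

    def test_negative_valence_rebounds_more_than_positive(self, config):
        rec = {"POSITIVE": [], "NEGATIVE": []}
        for seed in range(25):
            for val in rec:
                exp = ps.simulate_sd_experiment(config, 0.0, 4.0, val,
                                                seed=seed, with_spectra=False)
                rec[val].append(ps.recovery_nrem(exp))
        from scipy import stats
        t = stats.mannwhitneyu(rec["NEGATIVE"], rec["POSITIVE"],
                               alternative="greater")
        assert t.pvalue < 0.01

    def test_neutral_valence_leaves_wake_spectra_at_baseline(self, config):
        from scipy import stats
        pvals = []
        for seed in range(9):
            exp = ps.simulate_sd_experiment(config, 0.0, 4.0, "NONE", seed=seed)
            zt = exp.test_hyp.epoch_zt_s() / 3600.0
            win = np.array([l == WAKE for l in exp.test_hyp.labels]) & (zt < 4)
            base_w = np.array([l == WAKE for l in exp.baseline_hyp.labels]) & (
                exp.baseline_hyp.epoch_zt_s() / 3600.0 < 4)
            c = exp.test_spec.bin_centers
            r_test = ps.band_power(exp.test_spec.power[win],
                                   ps.band("low_theta"), c)
            r_base = ps.band_power(exp.baseline_spec.power[base_w],
                                   ps.band("low_theta"), c)
            pvals.append(stats.ks_2samp(r_test, r_base).pvalue)
        assert np.median(pvals) > 0.05

    def test_window_outside_day_rejected(self, config):
        with pytest.raises(ps.PolysomError):
            ps.simulate_sd_experiment(config, 20.0, 6.0, "NONE", seed=0)


class TestActivity:
    def test_dd_without_jitter_has_exact_period(self):
        cfg = ps.SimConfig(tau_dd_h=24.4, onset_jitter_sd_min=0.0)
        trace = ps.simulate_activity(cfg, 10, "DD", seed=8)
        onsets = ps.detect_onsets(trace, period_h=24.4)
        assert np.allclose(np.diff(onsets), 24.4 * 60, atol=1.0)

    def test_flat_rhythm_rarely_beats_the_chi2_line(self):
        cfg = ps.SimConfig(activity_amp=0.0, activity_base=5.0)
        n_sig = 0
        for seed in range(20):
            trace = ps.simulate_activity(cfg, 5, "DD", seed=seed)
            res = ps.chi2_periodogram(trace, alpha=0.01)
            n_sig += res.best_period_h is not None
        assert n_sig <= 1

    def test_bad_free_running_period_rejected(self):
        with pytest.raises(ps.PolysomError):
            ps.simulate_activity(ps.SimConfig(tau_dd_h=30.0), 5, "DD", seed=0)

    def test_too_few_days_rejected(self, config):
        with pytest.raises(ps.PolysomError):
            ps.simulate_activity(config, 2, "LD", seed=0)


class TestGeneratedTargetsRecovered:
    def test_fraction_and_bout_targets_within_10pct(self, config):
        """48 h simulations recover configured NREM/REM fractions and means."""
        light = embedded_chain_fractions(config, LIGHT)
        dark = embedded_chain_fractions(config, DARK)
        expected = {s: (light[s] + dark[s]) / 2 for s in light}
        fracs = {s: [] for s in (NREM, REM)}
        nrem_durs = []
        for seed in range(25):
            hyp, _ = ps.simulate_hypnogram(config, 48, seed=seed)
            labs = hyp.labels
            for s in fracs:
                fracs[s].append(np.mean([l == s for l in labs]))
            nrem_durs += [b.duration_s for b in ps.episodes(hyp)
                          if b.state == NREM]
        for s in fracs:
            assert np.mean(fracs[s]) == pytest.approx(expected[s], rel=0.10)
        # configured NREM bout mean, light/dark average
        cfg_mean = np.mean([config.bout_mean_s[NREM][LIGHT],
                            config.bout_mean_s[NREM][DARK]])
        assert np.mean(nrem_durs) == pytest.approx(cfg_mean, rel=0.10)
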