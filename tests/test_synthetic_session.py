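"""Synthetic session generator: behavior, gaze, LFP, and spiking ground truth."""

import numpy as np
import pytest
from scipy import stats

from navgam import behavior as bh
from navgam import synthetic_session as synth


class TestGenerateBehavior:
    def test_target_distribution(self, behavior_session):
        _, trials = behavior_session
        r = np.array([t.target_r for t in trials])
        th = np.array([t.target_theta for t in trials])
        assert r.min() >= 100 and r.max() <= 400
        assert th.min() >= -40 and th.max() <= 40
        assert stats.kstest(r, stats.uniform(100, 300).cdf).pvalue > 0.01
        assert stats.kstest(th, stats.uniform(-40, 80).cdf).pvalue > 0.01

    def test_unit_gains_no_noise_all_rewarded(self):
        cfg = synth.SessionConfig(
            n_trials=40, gain_radial=1.0, gain_angular=1.0,
            endpoint_noise_r=0.0, endpoint_noise_theta=0.0,
            frac_near_origin=0.0, frac_no_stop=0.0,
        )
        trials = synth.generate_behavior(cfg, seed=0)
        assert all(t.rewarded for t in trials)
        t_r = np.array([t.target_r for t in trials])
        e_r = np.array([t.endpoint_r for t in trials])
        slope, _ = bh.bias_slopes(t_r, e_r)
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_gain_recovery_with_noise(self, behavior_session):
        cfg, trials = behavior_session
        summ = bh.summarize_session(trials)
        assert summ.slope_radial == pytest.approx(cfg.gain_radial, abs=0.05)
        assert summ.slope_angular == pytest.approx(cfg.gain_angular, abs=0.05)

    def test_iti_distribution(self, behavior_session):
        _, trials = behavior_session
        itis = [
            trials[i + 1].t_start - (trials[i].t_start + trials[i].duration)
            for i in range(len(trials) - 1)
        ]
        itis = np.array(itis)
        assert itis.min() >= 0.2 - 1e-9 and itis.max() <= 2.0 + 1e-9
        assert np.mean(itis) == pytest.approx(0.5, abs=0.1)

    def test_infeasible_gains_rejected(self):
        cfg = synth.SessionConfig(gain_radial=100.0)
        with pytest.raises(ValueError, match="infeasible"):
            synth.generate_behavior(cfg, seed=0)


class TestGenerateGaze:
    def test_quality_one_exact(self):
        cfg = synth.SessionConfig(n_trials=5, frac_no_stop=0.0, frac_near_origin=0.0)
        trials = synth.generate_behavior(cfg, seed=1)
        trials = synth.generate_gaze(trials, 1.0, seed=1)
        idx = [bh.trial_tracking_index(t) for t in trials]
        assert np.allclose(idx, 1.0)

    def test_quality_zero_near_zero(self):
        cfg = synth.SessionConfig(n_trials=30, frac_no_stop=0.0, frac_near_origin=0.0)
        trials = synth.generate_behavior(cfg, seed=2)
        trials = synth.generate_gaze(trials, 0.0, seed=2)
        idx = np.array([bh.trial_tracking_index(t) for t in trials])
        assert np.nanmean(idx) < 0.25  # slow drift keeps single-trial noise high

    def test_quality_sweep_monotone(self):
        cfg = synth.SessionConfig(n_trials=40, frac_no_stop=0.0, frac_near_origin=0.0)
        trials = synth.generate_behavior(cfg, seed=3)
        means = []
        for q in (0.2, 0.5, 0.8):
            tq = synth.generate_gaze(trials, q, seed=3)
            means.append(np.nanmean([bh.trial_tracking_index(t) for t in tq]))
        assert means[0] < means[1] < means[2]

    def test_invalid_quality_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_gaze([], 1.5, seed=0)


class TestGenerateSpikes:
    def test_untuned_unit_is_poisson(self, small_session):
        """With no tuning the counts are Poisson at the baseline rate:
        mean matches and the Fano factor is ~1."""
        session, _, _ = small_session
        cfg = synth.SessionConfig()
        gt = synth.GroundTruth(
            units=[synth.UnitGroundTruth(unit_id=0, area="MSTd", baseline_hz=10.0)],
            gains=(1, 1), tracking_quality=1.0,
        )
        sub = type(session)(
            dt=session.dt, counts=session.counts[:1], continuous=session.continuous,
            events=session.events, lfp_phase={b: p[:1] for b, p in session.lfp_phase.items()},
            trial_index=session.trial_index, unit_meta=session.unit_meta.iloc[:1],
        )
        counts = synth.generate_spikes(sub, gt, seed=0)
        rate = counts.mean() / session.dt
        assert rate == pytest.approx(10.0, rel=0.05)
        fano = counts.var() / counts.mean()
        assert fano == pytest.approx(1.0, abs=0.05)

    def test_history_kernel_induces_refractoriness(self, small_session):
        session, _, _ = small_session
        base = synth.UnitGroundTruth(unit_id=0, area="MSTd", baseline_hz=40.0)
        refr = synth.UnitGroundTruth(
            unit_id=0, area="MSTd", baseline_hz=40.0,
            history_kernel=np.array([-4.0, -2.0, -1.0]),
        )
        sub = type(session)(
            dt=session.dt, counts=session.counts[:1], continuous=session.continuous,
            events=session.events, lfp_phase={b: p[:1] for b, p in session.lfp_phase.items()},
            trial_index=session.trial_index, unit_meta=session.unit_meta.iloc[:1],
        )
        gt0 = synth.GroundTruth([base], (1, 1), 1.0)
        gt1 = synth.GroundTruth([refr], (1, 1), 1.0)
        c0 = synth.generate_spikes(sub, gt0, seed=1)[0]
        c1 = synth.generate_spikes(sub, gt1, seed=1)[0]
        # P(spike at t | spike at t-1), vs the memoryless baseline P(spike)
        def cond_rate(c):
            prev = c[:-1] > 0
            return (c[1:][prev] > 0).mean() / (c > 0).mean()

        assert cond_rate(c0) == pytest.approx(1.0, abs=0.1)
        assert cond_rate(c1) < 0.35

    def test_planted_phase_locking(self, small_session):
        session, _, _ = small_session
        pref = 1.2
        gt = synth.GroundTruth(
            units=[synth.UnitGroundTruth(
                unit_id=0, area="MSTd", baseline_hz=20.0,
                phase_tuning={"beta": (pref, 0.8)},
            )],
            gains=(1, 1), tracking_quality=1.0,
        )
        sub = type(session)(
            dt=session.dt, counts=session.counts[:1], continuous=session.continuous,
            events=session.events, lfp_phase={b: p[:1] for b, p in session.lfp_phase.items()},
            trial_index=session.trial_index, unit_meta=session.unit_meta.iloc[:1],
        )
        counts = synth.generate_spikes(sub, gt, seed=2)[0]
        phases = sub.lfp_phase["beta"][0]
        # circular mean of spike phases sits at the planted preference
        w = counts.astype(float)
        mean_phase = np.angle(np.sum(w * np.exp(1j * phases)))
        assert abs((mean_phase - pref + np.pi) % (2 * np.pi) - np.pi) < 0.15
        # and the resultant length is clearly above an unlocked unit's
        r = abs(np.sum(w * np.exp(1j * phases))) / w.sum()
        assert r > 0.2

    def test_rate_reproducible_from_ground_truth(self, small_session):
        """Stimulus-driven log-rate recomputed from the stored ground truth
        matches what the generator used (no history/coupling case)."""
        session, _, _ = small_session
        rng = np.random.default_rng(3)
        u = synth.UnitGroundTruth(unit_id=0, area="MSTd", baseline_hz=12.0)
        x = session.continuous["lin_vel"].to_numpy()
        lo, hi = np.quantile(x, [0.02, 0.98])
        u.tunings["lin_vel"] = synth._random_tuning(rng, lo, hi)
        sub = type(session)(
            dt=session.dt, counts=session.counts[:1], continuous=session.continuous,
            events=session.events, lfp_phase={b: p[:1] for b, p in session.lfp_phase.items()},
            trial_index=session.trial_index, unit_meta=session.unit_meta.iloc[:1],
        )
        gt = synth.GroundTruth([u], (1, 1), 1.0)
        counts = synth.generate_spikes(sub, gt, seed=4)[0]
        eta = np.log(12.0 * session.dt) + u.tuning_value("lin_vel", x)
        # per-bin expectation reproduces the observed mean in rate bins
        mu = np.exp(eta)
        hi_mask = mu >= np.quantile(mu, 0.8)
        assert counts[hi_mask].mean() == pytest.approx(mu[hi_mask].mean(), rel=0.1)
        assert counts.mean() == pytest.approx(mu.mean(), rel=0.1)


class TestDeterminism:
    def test_identical_seed_identical_session(self):
        cfg = synth.SessionConfig(n_trials=8, area_counts={"MSTd": 2, "7a": 2, "dlPFC": 2})
        s1, t1, g1 = synth.make_session(cfg, seed=42)
        s2, t2, g2 = synth.make_session(cfg, seed=42)
        assert np.array_equal(s1.counts, s2.counts)
        assert np.allclose(s1.continuous.to_numpy(), s2.continuous.to_numpy())
        assert t1[3].trajectory.equals(t2[3].trajectory)
        assert g1.units[1].tuned_variables == g2.units[1].tuned_variables

    def test_different_seed_differs(self):
        cfg = synth.SessionConfig(n_trials=5, area_counts={"MSTd": 2, "7a": 2, "dlPFC": 2})
        s1, _, _ = synth.make_session(cfg, seed=1)
        s2, _, _ = synth.make_session(cfg, seed=2)
        assert not np.array_equal(s1.counts, s2.counts)
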