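"""Session data model: binning, latent covariates, QC, serialization."""

import numpy as np
import pandas as pd
import pytest

from navgam import core_data
from navgam.core_data import TrialRecord, bin_session, compute_latent_covariates, unit_qc


def _straight_trial(v=100.0, duration=1.2, dt=0.002, target=(300.0, 0.0), trial_id=0):
    n = int(duration / dt) + 1
    t = np.arange(n) * dt
    traj = pd.DataFrame(
        {
            "t": t,
            "x": np.zeros(n),
            "y": v * t,
            "heading": np.zeros(n),
            "lin_vel": np.full(n, v),
            "ang_vel": np.zeros(n),
        }
    )
    return TrialRecord(
        trial_id=trial_id, t_start=0.0, target_r=target[0], target_theta=target[1],
        t_target_on=0.0, t_target_off=0.3, trajectory=traj,
    )


class TestBinning:
    def test_spike_counting(self):
        tr = _straight_trial()
        sess = bin_session([tr], [np.array([0.001, 0.004, 0.011])], None, dt=0.006)
        assert sess.counts[0, 0] == 2 and sess.counts[0, 1] == 1

    def test_distance_from_origin_rises_linearly(self):
        tr = _straight_trial(v=100.0, duration=1.2)
        sess = bin_session([tr], [np.array([])], None, dt=0.006)
        d = sess.continuous["dist_origin"].to_numpy()[:200]
        expect = 100.0 * (np.arange(200) * 0.006 + 0.003)  # bin-center average
        assert np.allclose(d, expect, atol=0.5)
        assert d[-1] == pytest.approx(120.0, abs=1.0)

    def test_total_counts_match_histogram_oracle(self, behavior_session):
        cfg, trials = behavior_session
        trials = trials[:100]
        rng = np.random.default_rng(0)
        t_end = max(tr.t_start + tr.duration for tr in trials)
        spikes = [np.sort(rng.uniform(0, t_end, rng.poisson(t_end * 8.0))) for _ in range(3)]
        sess = bin_session(trials, spikes, None, dt=0.006)
        for u, st in enumerate(spikes):
            assert sess.counts[u].sum() == len(st)
            edges = np.arange(sess.n_bins + 1) * sess.dt
            assert np.array_equal(sess.counts[u], np.histogram(st, edges)[0])

    def test_rebinning_consistency(self):
        """Summing pairs of dt/2 bins reproduces the dt counts exactly."""
        tr = _straight_trial(duration=1.2)
        rng = np.random.default_rng(1)
        st = np.sort(rng.uniform(0, 1.2, 400))
        coarse = bin_session([tr], [st], None, dt=0.006)
        fine = bin_session([tr], [st], None, dt=0.003)
        nf = 2 * coarse.n_bins
        cf = np.zeros(nf, dtype=int)
        cf[: fine.n_bins] = fine.counts[0]
        assert np.array_equal(coarse.counts[0], cf.reshape(-1, 2).sum(axis=1))

    def test_trial_concatenation_invertible(self, behavior_session):
        cfg, trials = behavior_session
        trials = trials[:40]
        sess = bin_session(trials, [np.array([])], None, dt=0.006)
        for tr in trials[:10]:
            bins = sess.bins_of_trial(tr.trial_id)
            assert len(bins) > 0
            assert np.array_equal(bins, np.arange(bins[0], bins[-1] + 1))
            # bin times fall inside the trial window
            t0 = bins[0] * sess.dt
            assert t0 >= tr.t_start - sess.dt and t0 <= tr.t_start + sess.dt

    def test_events_marked_once(self, behavior_session):
        cfg, trials = behavior_session
        sess = bin_session(trials[:50], [np.array([])], None, dt=0.006)
        assert set(np.unique(sess.events.to_numpy())) <= {0, 1}
        assert sess.events["target_on"].sum() == 50

    def test_non_monotonic_spikes_rejected(self):
        tr = _straight_trial()
        with pytest.raises(ValueError, match="non-monotonic"):
            bin_session([tr], [np.array([0.5, 0.2])], None)

    def test_covariate_gap_rejected(self):
        tr = _straight_trial()
        traj = tr.trajectory[(tr.trajectory["t"] < 0.3) | (tr.trajectory["t"] > 0.5)]
        tr2 = TrialRecord(
            trial_id=0, t_start=0.0, target_r=300, target_theta=0,
            t_target_on=0.0, t_target_off=0.3, trajectory=traj.reset_index(drop=True),
        )
        with pytest.raises(ValueError, match="gap"):
            bin_session([tr2], [np.array([])], None, dt=0.006)


class TestLatentCovariates:
    def test_straight_run_geometry(self):
        tr = _straight_trial(v=100.0, duration=2.0, target=(300.0, 0.0))
        lat = compute_latent_covariates(tr)
        assert lat["dist_origin"].iloc[-1] == pytest.approx(200.0, abs=1e-6)
        assert lat["dist_target"].iloc[-1] == pytest.approx(100.0, abs=1e-6)
        assert np.allclose(lat["angle_origin"], 0.0)

    def test_pure_rotation(self):
        n, dt = 601, 0.002
        t = np.arange(n) * dt
        w = 25.0
        traj = pd.DataFrame(
            {"t": t, "x": np.zeros(n), "y": np.zeros(n), "heading": w * t,
             "lin_vel": np.zeros(n), "ang_vel": np.full(n, w)}
        )
        tr = TrialRecord(0, 200.0, 0.0, 0.0, 0.3, traj)
        lat = compute_latent_covariates(tr)
        assert lat["angle_origin"].iloc[-1] == pytest.approx(w * t[-1], abs=1e-6)
        assert np.allclose(lat["dist_origin"], 0.0)

    def test_curvilinear_matches_numerical_oracle(self):
        """Distance/angle on a curved path agree with dense integration."""
        dt = 0.001
        t = np.arange(0, 3.0, dt)
        v = 80.0 + 40.0 * np.sin(t)
        w = 20.0 * np.cos(0.7 * t)
        heading = np.concatenate(([0.0], np.cumsum(w[:-1] + w[1:]) * dt / 2))
        rad = np.deg2rad(heading)
        x = np.concatenate(([0.0], np.cumsum((v * np.sin(rad))[:-1] + (v * np.sin(rad))[1:]) * dt / 2))
        y = np.concatenate(([0.0], np.cumsum((v * np.cos(rad))[:-1] + (v * np.cos(rad))[1:]) * dt / 2))
        traj = pd.DataFrame({"t": t, "x": x, "y": y, "heading": heading,
                             "lin_vel": v, "ang_vel": w})
        tr = TrialRecord(0, 300.0, 10.0, 0.0, 0.3, traj)
        lat = compute_latent_covariates(tr)
        # oracle: dense cumulative integrals
        dist_oracle = np.concatenate(([0.0], np.cumsum(v[:-1] + v[1:]) * dt / 2))
        assert np.max(np.abs(lat["dist_origin"].to_numpy() - dist_oracle)) < 0.5
        tx, ty = tr.target_xy
        dt_oracle = np.hypot(tx - x, ty - y)
        assert np.max(np.abs(lat["dist_target"].to_numpy() - dt_oracle)) < 0.5

    def test_missing_target_rejected(self):
        tr = _straight_trial()
        tr.target_r = np.nan
        with pytest.raises(ValueError, match="target"):
            compute_latent_covariates(tr)

    def test_four_latent_series_distinct(self, behavior_session):
        _, trials = behavior_session
        tr = next(t for t in trials if abs(t.target_theta) > 10)
        lat = compute_latent_covariates(tr)
        cols = ["dist_origin", "angle_origin", "dist_target", "angle_target"]
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                assert not np.allclose(lat[cols[i]], lat[cols[j]])


class TestUnitQC:
    def test_regular_train_passes(self):
        st = np.arange(0, 3600.0, 0.1)
        qc = unit_qc(st, 3600.0)
        assert qc["isi_violation_fraction"] == 0.0
        assert qc["presence_rate"] == 1.0
        assert qc["pass"]

    def test_doubled_spikes_fail(self):
        base = np.arange(0, 3600.0, 0.1)
        st = np.sort(np.concatenate([base, base + 0.0005]))
        qc = unit_qc(st, 3600.0)
        assert qc["isi_violation_fraction"] == pytest.approx(0.5, abs=1e-3)
        assert not qc["pass"]

    def test_empty_train(self):
        qc = unit_qc(np.array([]), 3600.0)
        assert qc["presence_rate"] == 0.0 and not qc["pass"]

    def test_poisson_train_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        dur = 3600.0
        st = np.sort(rng.uniform(0, dur, rng.poisson(5.0 * dur)))
        qc = unit_qc(st, dur)
        # brute-force loops
        viol = sum(1 for a, b in zip(st[:-1], st[1:]) if b - a < 0.001)
        isiv_oracle = viol / len(st)
        occupied = {int(s // 60) for s in st}
        pr_oracle = len(occupied) / 60
        assert qc["isi_violation_fraction"] == pytest.approx(isiv_oracle, abs=1e-12)
        assert qc["presence_rate"] == pytest.approx(pr_oracle, abs=1e-12)
        assert qc["pass"]


class TestSerialization:
    def test_roundtrip(self, small_session, tmp_path):
        session, trials, _ = small_session
        core_data.save_session(session, tmp_path / "s", trials)
        loaded, ltrials = core_data.load_session(tmp_path / "s")
        assert loaded.dt == session.dt
        assert np.array_equal(loaded.counts, session.counts)
        assert np.allclose(loaded.continuous.to_numpy(), session.continuous.to_numpy())
        for band in session.lfp_phase:
            assert np.allclose(loaded.lfp_phase[band], session.lfp_phase[band])
        assert len(ltrials) == len(trials)
        assert ltrials[0].target_r == pytest.approx(trials[0].target_r)
        assert np.allclose(ltrials[3].trajectory.to_numpy(), trials[3].trajectory.to_numpy())

    def test_missing_stream_reported(self, small_session, tmp_path):
        session, trials, _ = small_session
        core_data.save_session(session, tmp_path / "s", trials)
        (tmp_path / "s" / "counts.npy").unlink()
        with pytest.raises(FileNotFoundError, match="counts"):
            core_data.load_session(tmp_path / "s")


def test_session_census(small_session):
    """All covariate families present: the 17 task inputs of the model."""
    session, _, _ = small_session
    n = len(session.continuous.columns) + len(session.events.columns) + len(session.lfp_phase)
    assert n == 17
    assert set(np.unique(session.lfp_phase["beta"])) != {0}
    ph = session.lfp_phase["theta"]
    assert ph.min() > -np.pi - 1e-9 and ph.max() <= np.pi + 1e-9
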