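"""Penalized Poisson GAM: design assembly, fitting, inclusion, reduction."""

import numpy as np
import pytest

from navgam import pgam
from navgam.encoding_metrics import extract_tuning

from conftest import make_covariate_session


def _bump(x):
    return 0.8 * np.exp(-((x - 0.5) ** 2) / 0.3)


class TestAssembleDesign:
    def test_seventeen_task_inputs(self, small_session):
        session, _, _ = small_session
        spec = pgam.ModelConfig(n_knots=6, phase_knots=6, coupling=False)
        design = pgam.assemble_design(session, 0, spec)
        assert design.n_task_variables == 17

    def test_no_partner_design(self, small_session):
        session, _, _ = small_session
        spec = pgam.ModelConfig(n_knots=6, phase_knots=6, coupling=False, spike_history=True)
        design = pgam.assemble_design(session, 0, spec)
        kinds = set(design.term_kind.values())
        assert kinds == {"task", "lfp", "event", "history"}

    def test_columns_match_per_term_oracle(self, small_session):
        """Each design block equals its brute-force per-term construction."""
        session, _, _ = small_session
        spec = pgam.ModelConfig(n_knots=6, phase_knots=6, coupling=True)
        design = pgam.assemble_design(session, 1, spec)
        # continuous block
        term = design.terms["lin_vel"]
        x = session.continuous["lin_vel"].to_numpy()
        expect = term.design_c(x)
        got = design.X[:, design.slices["lin_vel"]] + design.col_means[design.slices["lin_vel"]]
        assert np.allclose(got, expect)
        # event block: causal convolution with the lag kernels
        ev = design.terms["target_on"]
        z = session.events["target_on"].to_numpy().astype(float)
        K = ev.kernel_matrix()
        T = session.n_bins
        oracle = np.zeros((T, K.shape[1]))
        for t in np.flatnonzero(z):
            lo = t + 1
            hi = min(T, t + 1 + K.shape[0])
            oracle[lo:hi] += K[: hi - lo]
        got = design.X[:, design.slices["target_on"]] + design.col_means[design.slices["target_on"]]
        assert np.allclose(got, oracle)
        # a coupling block is the partner's convolved spike train
        name = next(n for n in design.terms if n.startswith("coupling_"))
        partner = int(name.split("_")[1])
        cterm = design.terms[name]
        got = design.X[:, design.slices[name]] + design.col_means[design.slices[name]]
        assert np.allclose(got, cterm.convolve(session.counts[partner].astype(float)))

    def test_constant_covariate_dropped(self, small_session):
        session, _, _ = small_session
        sess2 = session
        import pandas as pd

        cont = session.continuous.copy()
        cont["lin_vel"] = 0.0
        sess2 = pgam.BinnedSession(
            dt=session.dt, counts=session.counts, continuous=cont,
            events=session.events, lfp_phase=session.lfp_phase,
            trial_index=session.trial_index, unit_meta=session.unit_meta,
        )
        spec = pgam.ModelConfig(n_knots=6, phase_knots=6, coupling=False)
        with pytest.warns(UserWarning, match="constant"):
            design = pgam.assemble_design(sess2, 0, spec)
        assert "lin_vel" not in design.terms


class TestFit:
    def test_recovers_known_tuning(self):
        session, y, _ = make_covariate_session(
            seed=0, n_bins=60_000, tuned={"lin_vel": _bump}
        )
        spec = pgam.ModelConfig(
            continuous=tuple(session.continuous.columns), lfp_bands=(), events=(),
            n_knots=8, spike_history=False,
        )
        design = pgam.assemble_design(session, 0, spec)
        fit = pgam.fit_pgam(design, y, seed=0)
        term = design.terms["lin_vel"]
        g = np.linspace(term.knots[0], term.knots[-1], 80)
        fhat = term.evaluate(g, fit.term_beta("lin_vel"))
        assert np.corrcoef(fhat, _bump(g))[0, 1] > 0.95
        assert fit.term_pvalues["lin_vel"] < 1e-6
        assert fit.converged

    def test_null_term_flat_within_ci(self):
        session, y, _ = make_covariate_session(
            seed=1, n_bins=60_000, tuned={"lin_vel": _bump}
        )
        spec = pgam.ModelConfig(
            continuous=tuple(session.continuous.columns), lfp_bands=(), events=(),
            n_knots=8, spike_history=False,
        )
        design = pgam.assemble_design(session, 0, spec)
        fit = pgam.fit_pgam(design, y, seed=1)
        tf = extract_tuning(fit, "ang_vel")
        spread = tf.response.max() - tf.response.min()
        ci_width = np.median(tf.ci_high - tf.ci_low)
        assert spread < 2.0 * ci_width

    def test_lambda_infinity_collapse(self):
        session, y, _ = make_covariate_session(
            seed=2, n_bins=30_000, tuned={"lin_vel": _bump}
        )
        spec = pgam.ModelConfig(
            continuous=("lin_vel",), lfp_bands=(), events=(), n_knots=8,
            spike_history=False,
        )
        design = pgam.assemble_design(session, 0, spec)
        fit = pgam.fit_pgam(design, y, seed=2, fixed_lambda=1e9)
        term = design.terms["lin_vel"]
        g = np.linspace(term.knots[0], term.knots[-1], 60)
        f = term.evaluate(g, fit.term_beta("lin_vel"))
        scale = max(np.abs(np.diff(f)).max(), 1e-9)
        assert np.abs(np.diff(f, 2)).max() / scale < 1e-2  # affine limit

    def test_intercept_score_equation(self):
        """Fitted mean matches observed mean on the training bins."""
        session, y, _ = make_covariate_session(
            seed=3, n_bins=30_000, tuned={"lin_vel": _bump}
        )
        spec = pgam.ModelConfig(
            continuous=("lin_vel", "ang_vel"), lfp_bands=(), events=(),
            n_knots=8, spike_history=False,
        )
        design = pgam.assemble_design(session, 0, spec)
        fit = pgam.fit_pgam(design, y, seed=3, fixed_lambda=0.1)
        rng = np.random.default_rng(3)
        _, _, train_mask, _ = pgam._split_train_test(design.trial_index, 0.2, rng)
        mu = np.exp(np.clip(design.X[train_mask] @ fit.beta, -25, 25))
        assert mu.sum() == pytest.approx(y[train_mask].sum(), rel=1e-6)

    def test_penalized_loglik_nondecreasing(self):
        session, y, _ = make_covariate_session(seed=4, n_bins=20_000,
                                               tuned={"lin_vel": _bump})
        spec = pgam.ModelConfig(continuous=("lin_vel",), lfp_bands=(), events=(),
                                n_knots=8, spike_history=False)
        design = pgam.assemble_design(session, 0, spec)
        P = design.penalty({"lin_vel": 1.0})
        X = design.X
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(max(y.mean(), 1e-10))
        # track the objective across explicit Newton/step-halving iterations
        lls = [pgam._penalized_loglik(X, y, beta, P)]
        for _ in range(8):
            beta, _, _ = pgam._pirls(X, y, P, beta0=beta, max_iter=1)
            lls.append(pgam._penalized_loglik(X, y, beta, P))
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_zero_spike_unit_degenerate(self):
        session, y, _ = make_covariate_session(seed=5, n_bins=5_000)
        spec = pgam.ModelConfig(continuous=("lin_vel",), lfp_bands=(), events=(),
                                n_knots=6, spike_history=False)
        design = pgam.assemble_design(session, 0, spec)
        fit = pgam.fit_pgam(design, np.zeros_like(y), seed=0)
        assert fit.degenerate and not fit.converged

    def test_seed_determinism(self):
        session, y, _ = make_covariate_session(seed=6, n_bins=20_000,
                                               tuned={"lin_vel": _bump})
        spec = pgam.ModelConfig(continuous=("lin_vel", "ang_vel"), lfp_bands=(),
                                events=(), n_knots=6, spike_history=False)
        design = pgam.assemble_design(session, 0, spec)
        f1 = pgam.fit_pgam(design, y, seed=42, fixed_lambda=0.1)
        f2 = pgam.fit_pgam(design, y, seed=42, fixed_lambda=0.1)
        assert np.array_equal(f1.beta, f2.beta)
        assert f1.pseudo_r2_test == f2.pseudo_r2_test


class TestInclusionAndReduction:
    def test_zero_block_p_near_one(self):
        session, y, _ = make_covariate_session(seed=7, n_bins=20_000,
                                               tuned={"lin_vel": _bump})
        spec = pgam.ModelConfig(continuous=("lin_vel", "ang_vel"), lfp_bands=(),
                                events=(), n_knots=6, spike_history=False)
        design = pgam.assemble_design(session, 0, spec)
        fit = pgam.fit_pgam(design, y, seed=7, fixed_lambda=0.1)
        fit.beta = fit.beta.copy()
        fit.beta[fit.slices["ang_vel"]] = 0.0
        assert pgam.inclusion_test(fit, "ang_vel") > 0.99

    def test_strong_term_tiny_p(self):
        session, y, _ = make_covariate_session(seed=8, n_bins=80_000,
                                               tuned={"lin_vel": _bump})
        spec = pgam.ModelConfig(continuous=("lin_vel", "ang_vel"), lfp_bands=(),
                                events=(), n_knots=8, spike_history=False)
        design = pgam.assemble_design(session, 0, spec)
        fit = pgam.fit_pgam(design, y, seed=8)
        assert fit.term_pvalues["lin_vel"] < 1e-6

    def test_reduced_model_keeps_true_terms(self):
        session, y, _ = make_covariate_session(
            seed=9, n_bins=40_000,
            tuned={"lin_vel": _bump, "eye_hor": lambda x: 0.5 * x},
        )
        spec = pgam.ModelConfig(continuous=tuple(session.continuous.columns),
                                lfp_bands=(), events=(), n_knots=8, spike_history=False)
        design = pgam.assemble_design(session, 0, spec)
        fit = pgam.fit_pgam(design, y, seed=9)
        red = pgam.reduce_and_refit(design, fit, y, seed=9)
        assert {"lin_vel", "eye_hor"} <= set(red.term_names)
        assert set(red.term_names) == set(fit.selected_terms)
        # reduced test score within noise of the full model
        assert abs(red.pseudo_r2_test - fit.pseudo_r2_test) < 0.02

    def test_all_null_reduces_to_intercept(self):
        session, y, _ = make_covariate_session(seed=10, n_bins=30_000)
        spec = pgam.ModelConfig(continuous=("lin_vel", "ang_vel", "lin_acc"),
                                lfp_bands=(), events=(), n_knots=6, spike_history=False)
        design = pgam.assemble_design(session, 0, spec)
        fit = pgam.fit_pgam(design, y, seed=10)
        red = pgam.reduce_and_refit(design, fit, y, seed=10)
        assert len(red.term_names) <= 1  # at most one false positive at alpha
        mu = np.exp(red.intercept)
        assert mu == pytest.approx(y.mean(), rel=0.1)


class TestCouplingRecovery:
    def test_planted_coupling_kernel_recovered(self):
        """A planted sender->receiver kernel is detected with the right sign
        and peak lag; an uncoupled partner is not flagged."""
        import pandas as pd
        from navgam.core_data import BinnedSession, default_unit_meta

        rng = np.random.default_rng(12)
        T, dt = 50_000, 0.006
        kern = 0.8 * np.exp(-np.arange(6) / 2.0)  # positive, peak at lag 1
        sender = rng.poisson(15.0 * dt, T)
        bystander = rng.poisson(12.0 * dt, T)
        drive = np.convolve(sender.astype(float), np.concatenate(([0.0], kern)))[:T]
        y = rng.poisson(np.exp(np.log(10.0 * dt) + drive))
        from scipy.ndimage import gaussian_filter1d

        x = gaussian_filter1d(rng.standard_normal(T), 20)
        session = BinnedSession(
            dt=dt,
            counts=np.vstack([y, sender, bystander]),
            continuous=pd.DataFrame({"lin_vel": x / x.std()}),
            events=pd.DataFrame(index=range(T)),
            lfp_phase={},
            trial_index=np.repeat(np.arange(T // 500), 500),
            unit_meta=default_unit_meta(3),
        )
        spec = pgam.ModelConfig(continuous=("lin_vel",), lfp_bands=(), events=(),
                                n_knots=6, spike_history=True, coupling=True)
        design = pgam.assemble_design(session, 0, spec)
        fit = pgam.fit_pgam(design, y, seed=0, fixed_lambda=0.1)
        assert fit.term_pvalues["coupling_1"] < 1e-6
        term = fit.terms["coupling_1"]
        khat = term.kernel_matrix() @ fit.term_beta("coupling_1")
        assert np.sign(khat[np.argmax(np.abs(khat))]) > 0
        assert np.argmax(np.abs(khat)) == np.argmax(np.abs(kern))
        assert fit.term_pvalues["coupling_2"] > 0.01  # bystander stays out
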