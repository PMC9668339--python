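"""Penalized Poisson GAM for spike-train encoding.

The model for one unit's binned spike counts y_t is

    log mu_t = a + sum_j f_j(x_jt) + sum_k (f_k * z_k)_t

where the x_j are continuous covariates (velocities, accelerations, latent
distances/angles, eye position, LFP band phase) entering through spline tuning
functions, and the z_k are event trains (task events, the unit's own spike
history, partner-unit spike trains) entering through causal lag filters. Each
smooth f carries a curvature penalty 0.5 * lambda_f * beta' S_f beta, read as a
Gaussian prior on the spline coefficients.

Fitting alternates between maximizing the penalized Poisson log-likelihood in
the coefficients (penalized iteratively reweighted least squares) and choosing
the smoothness scale(s) lambda by minimizing the held-out deviance over
cross-validation folds built from contiguous trial blocks. The Gaussian-prior
reading of the penalty yields an approximate posterior covariance
(X'WX + P)^-1 at the optimum, from which per-term Wald-type inclusion
p-values are computed; terms with p below alpha (default 0.01) form the
reduced model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .bases import SmoothTerm, circular_term, continuous_term, temporal_basis
from .core_data import BinnedSession, CONTINUOUS_VARS, EVENT_VARS, LFP_BANDS

#: covariates modelled as periodic (phase) smooths
_CIRCULAR = tuple(f"lfp_{b}" for b in LFP_BANDS)


@dataclass
class ModelConfig:
    """Which terms enter the encoding model and at what resolution.

    Filter durations follow the within-area (36 ms) / across-area (600 ms)
    convention for coupling, with the unit's own spike history at 36 ms.
    ``n_knots`` is the per-covariate knot count of the tuning splines.
    """

    continuous: tuple = CONTINUOUS_VARS
    lfp_bands: tuple = LFP_BANDS
    events: tuple = EVENT_VARS
    n_knots: int = 15
    phase_knots: int = 9
    event_filter_s: float = 0.6
    history_filter_s: float = 0.036
    within_filter_s: float = 0.036
    across_filter_s: float = 0.6
    spike_history: bool = True
    coupling: bool = False
    alpha: float = 0.01
    test_fraction: float = 0.2

    @property
    def task_variables(self) -> tuple:
        """The task inputs of the model (continuous + LFP phases + events)."""
        return (
            tuple(self.continuous)
            + tuple(f"lfp_{b}" for b in self.lfp_bands)
            + tuple(self.events)
        )


@dataclass
class Design:
    """Assembled design matrix and penalty blocks for one unit."""

    unit_id: int
    X: np.ndarray  # (T, p); column 0 is the unpenalized intercept
    terms: dict[str, SmoothTerm]
    slices: dict[str, slice]
    col_means: np.ndarray
    trial_index: np.ndarray
    dt: float
    term_kind: dict[str, str] = field(default_factory=dict)  # task/lfp/event/history/coupling

    @property
    def n_task_variables(self) -> int:
        return sum(1 for n, k in self.term_kind.items() if k in ("task", "lfp", "event"))

    def penalty(self, lambdas: dict[str, float]) -> np.ndarray:
        p = self.X.shape[1]
        P = np.zeros((p, p))
        for name, term in self.terms.items():
            sl = self.slices[name]
            S = term.penalty_scaled if term.penalty_scaled is not None else term.penalty_c
            P[sl, sl] = lambdas[name] * S
        return P


@dataclass
class PGAMFit:
    """A fitted encoding model for one unit."""

    unit_id: int
    terms: dict[str, SmoothTerm]
    slices: dict[str, slice]
    beta: np.ndarray
    intercept: float
    posterior_cov: np.ndarray
    edf: dict[str, float]
    term_pvalues: dict[str, float]
    lambdas: dict[str, float]
    pseudo_r2_train: float
    pseudo_r2_test: float
    converged: bool
    alpha: float
    col_means: np.ndarray
    dt: float
    term_kind: dict[str, str] = field(default_factory=dict)
    degenerate: bool = False
    #: sampling covariance V (X'WX) V of the penalized estimator, used by the
    #: inclusion test (posterior_cov is the Gaussian-prior covariance, used
    #: for credible bands on tuning curves)
    freq_cov: np.ndarray | None = None

    @property
    def term_names(self) -> list[str]:
        return list(self.terms)

    @property
    def selected_terms(self) -> list[str]:
        return [n for n, p in self.term_pvalues.items() if p < self.alpha]

    def term_beta(self, name: str) -> np.ndarray:
        return self.beta[self.slices[name]]

    def term_cov(self, name: str) -> np.ndarray:
        sl = self.slices[name]
        return self.posterior_cov[sl, sl]

    def term_col_means(self, name: str) -> np.ndarray:
        return self.col_means[self.slices[name]]


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def assemble_design(
    session: BinnedSession, unit_id: int, spec: ModelConfig | None = None
) -> Design:
    """Build the design matrix and penalty blocks for one unit.

    Continuous covariates contribute spline-basis columns evaluated bin-wise,
    LFP phases periodic-spline columns of the unit's own channel phase, and
    events / spike history / partner spike trains contribute causally convolved
    lag-filter columns. Every penalized column is mean-centred so the intercept
    absorbs the overall rate and term contributions average to zero over the
    session. Knots are placed from within-trial samples only.
    """
    spec = spec or ModelConfig()
    T = session.n_bins
    in_trial = session.trial_index >= 0
    cols: list[np.ndarray] = [np.ones((T, 1))]
    terms: dict[str, SmoothTerm] = {}
    slices: dict[str, slice] = {}
    kinds: dict[str, str] = {}
    start = 1

    def _push(name: str, term: SmoothTerm, block: np.ndarray, kind: str):
        nonlocal start
        terms[name] = term
        slices[name] = slice(start, start + block.shape[1])
        kinds[name] = kind
        cols.append(block)
        start += block.shape[1]

    for name in spec.continuous:
        if name not in session.continuous.columns:
            raise KeyError(f"covariate {name!r} missing from session")
        x = session.continuous[name].to_numpy()
        if np.allclose(x, x[0]):
            warnings.warn(f"dropping constant covariate {name!r}", stacklevel=2)
            continue
        term = continuous_term(name, x[in_trial], n_knots=spec.n_knots)
        term.apply_constraint()
        _push(name, term, term.design_c(x), "task")

    for band in spec.lfp_bands:
        if band not in session.lfp_phase:
            warnings.warn(f"no LFP phase for band {band!r}; skipping", stacklevel=2)
            continue
        name = f"lfp_{band}"
        term = circular_term(name, n_knots=spec.phase_knots)
        term.apply_constraint()
        _push(name, term, term.design_c(session.lfp_phase[band][unit_id]), "lfp")

    for name in spec.events:
        if name not in session.events.columns:
            raise KeyError(f"event {name!r} missing from session")
        z = session.events[name].to_numpy().astype(float)
        if z.sum() == 0:
            warnings.warn(f"dropping empty event train {name!r}", stacklevel=2)
            continue
        term = temporal_basis(spec.event_filter_s, session.dt, name=name)
        _push(name, term, term.convolve(z), "event")

    if spec.spike_history:
        term = temporal_basis(spec.history_filter_s, session.dt, name="spike_history")
        _push(
            "spike_history",
            term,
            term.convolve(session.counts[unit_id].astype(float)),
            "history",
        )

    if spec.coupling:
        meta = session.unit_meta.set_index("unit_id")
        own_area = meta.loc[unit_id, "area"]
        for partner in session.unit_meta["unit_id"]:
            if partner == unit_id:
                continue
            dur = (
                spec.within_filter_s
                if meta.loc[partner, "area"] == own_area
                else spec.across_filter_s
            )
            name = f"coupling_{partner}"
            term = temporal_basis(dur, session.dt, name=name)
            _push(name, term, term.convolve(session.counts[partner].astype(float)), "coupling")

    X = np.concatenate(cols, axis=1)
    col_means = X.mean(axis=0)
    col_means[0] = 0.0
    X = X - col_means

    # penalties rescaled to the magnitude of the corresponding design block so
    # one dimensionless lambda is comparable across terms
    for name, term in terms.items():
        sl = slices[name]
        Xb = X[:, sl]
        S = term.penalty_c
        sx = np.linalg.norm(Xb.T @ Xb, "fro")
        ss = np.linalg.norm(S, "fro")
        term.penalty_scaled = S * (sx / ss if ss > 0 else 1.0)

    return Design(
        unit_id=unit_id,
        X=X,
        terms=terms,
        slices=slices,
        col_means=col_means,
        trial_index=session.trial_index,
        dt=session.dt,
        term_kind=kinds,
    )


# ---------------------------------------------------------------------------
# penalized IRLS
# ---------------------------------------------------------------------------

_ETA_CLIP = 25.0


def _penalized_loglik(X, y, beta, P):
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    return float(y @ eta - mu.sum() - 0.5 * beta @ P @ beta)


def _pirls(X, y, P, beta0=None, max_iter=60, tol=1e-9):
    """Maximize the penalized Poisson log-likelihood; Newton with step-halving.

    Returns (beta, XtWX + P at the optimum, converged).
    """
    p = X.shape[1]
    ridge = 1e-8 * np.eye(p)
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(y.mean(), 1e-10))
    else:
        beta = beta0.copy()
    pll = _penalized_loglik(X, y, beta, P)
    A = None
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        Xw = X * mu[:, None]
        A = X.T @ Xw + P + ridge
        g = X.T @ (y - mu) - P @ beta
        try:
            c = linalg.cho_factor(A, check_finite=False)
            step = linalg.cho_solve(c, g, check_finite=False)
        except linalg.LinAlgError:
            step = np.linalg.lstsq(A, g, rcond=None)[0]
        new = beta + step
        pll_new = _penalized_loglik(X, y, new, P)
        h = 0
        while pll_new < pll and h < 30:
            step *= 0.5
            new = beta + step
            pll_new = _penalized_loglik(X, y, new, P)
            h += 1
        beta = new
        if abs(pll_new - pll) < tol * (abs(pll) + 1.0):
            pll = pll_new
            converged = True
            break
        pll = pll_new
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    A = X.T @ (X * mu[:, None]) + P + 1e-8 * np.eye(p)
    return beta, A, converged


def _poisson_deviance(y, mu):
    mu = np.clip(mu, 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _trial_blocks(trial_index: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Attach inter-trial bins to the following trial; return (block id per
    bin, ordered unique block ids)."""
    blocks = trial_index.copy()
    # backward-fill -1 runs with the next trial id
    nxt = -1
    for i in range(len(blocks) - 1, -1, -1):
        if blocks[i] >= 0:
            nxt = blocks[i]
        else:
            blocks[i] = nxt
    if (blocks < 0).any():  # trailing inter-trial bins join the last trial
        last = blocks[blocks >= 0]
        blocks[blocks < 0] = last[-1] if len(last) else 0
    _, first = np.unique(blocks, return_index=True)
    ordered = blocks[np.sort(first)]
    return blocks, ordered


def _split_train_test(trial_index, test_fraction, rng):
    blocks, ordered = _trial_blocks(trial_index)
    n_test = max(1, int(round(test_fraction * len(ordered)))) if test_fraction > 0 else 0
    test_ids = set(rng.choice(ordered, size=n_test, replace=False)) if n_test else set()
    test_mask = np.isin(blocks, list(test_ids)) if test_ids else np.zeros(len(blocks), bool)
    return blocks, ordered, ~test_mask, test_mask


def _cv_deviance(X, y, design, lambdas, blocks, fold_of, k, beta_warm):
    dev = 0.0
    P = design.penalty(lambdas)
    for f in range(k):
        m = fold_of != f
        beta, _, _ = _pirls(X[m], y[m], P, beta0=beta_warm)
        mu = np.exp(np.clip(X[~m] @ beta, -_ETA_CLIP, _ETA_CLIP))
        dev += _poisson_deviance(y[~m], mu)
    return dev


def fit_pgam(
    design: Design,
    counts: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
    lambda_mode: str = "shared",
    fixed_lambda: float | dict | None = None,
    alpha: float = 0.01,
    test_fraction: float = 0.2,
) -> PGAMFit:
    """Fit the penalized Poisson GAM for one unit.

    20% of trials (contiguous blocks including their preceding inter-trial
    bins) are held out for the test pseudo-R^2; the remaining trials are split
    into ``folds`` contiguous blocks for the cross-validated smoothness
    search. ``lambda_mode`` "shared" searches one dimensionless scale for all
    terms on ``lambda_grid``; "per_term" follows with a coordinate pass
    refining each term's scale. ``fixed_lambda`` skips the search entirely.
    The seed governs the train/test/fold assignment only; given the folds the
    fit is deterministic.
    """
    y = np.asarray(counts, dtype=float)
    X = design.X
    rng = np.random.default_rng(seed)
    if y.sum() == 0:
        p = X.shape[1]
        beta = np.zeros(p)
        beta[0] = -_ETA_CLIP
        return PGAMFit(
            unit_id=design.unit_id, terms=design.terms, slices=design.slices,
            beta=beta, intercept=beta[0], posterior_cov=np.eye(p),
            edf={n: 0.0 for n in design.terms},
            term_pvalues={n: 1.0 for n in design.terms},
            lambdas={n: 1.0 for n in design.terms},
            pseudo_r2_train=np.nan, pseudo_r2_test=np.nan, converged=False,
            alpha=alpha, col_means=design.col_means, dt=design.dt,
            term_kind=design.term_kind, degenerate=True,
        )

    blocks, ordered, train_mask, test_mask = _split_train_test(
        design.trial_index, test_fraction, rng
    )
    Xtr, ytr = X[train_mask], y[train_mask]

    term_names = list(design.terms)
    if fixed_lambda is not None:
        if isinstance(fixed_lambda, dict):
            lambdas = dict(fixed_lambda)
        else:
            lambdas = {n: float(fixed_lambda) for n in term_names}
    else:
        if lambda_grid is None:
            lambda_grid = np.logspace(-4, 3, 8)
        # contiguous trial-block folds within the training set
        train_blocks = [b for b in ordered if b in set(np.unique(blocks[train_mask]))]
        fold_of_block = {
            b: min(folds - 1, i * folds // len(train_blocks))
            for i, b in enumerate(train_blocks)
        }
        fold_of = np.array([fold_of_block.get(b, 0) for b in blocks[train_mask]])
        beta_warm, _, _ = _pirls(Xtr, ytr, design.penalty({n: 1.0 for n in term_names}))
        best = None
        for lam in lambda_grid:
            lams = {n: float(lam) for n in term_names}
            dev = _cv_deviance(Xtr, ytr, design, lams, blocks, fold_of, folds, beta_warm)
            if best is None or dev < best[0]:
                best = (dev, lams)
        lambdas = best[1]
        if lambda_mode == "per_term" and len(term_names) > 1:
            for name in term_names:
                cur = lambdas[name]
                for lam in cur * np.array([0.01, 0.1, 10.0, 100.0]):
                    cand = dict(lambdas)
                    cand[name] = float(lam)
                    dev = _cv_deviance(
                        Xtr, ytr, design, cand, blocks, fold_of, folds, beta_warm
                    )
                    if dev < best[0]:
                        best = (dev, cand)
                lambdas = best[1]
        elif lambda_mode not in ("shared", "per_term"):
            raise ValueError("lambda_mode must be 'shared' or 'per_term'")

    P = design.penalty(lambdas)
    beta, A, converged = _pirls(Xtr, ytr, P)
    V = _safe_inv(A)
    mu_tr = np.exp(np.clip(Xtr @ beta, -_ETA_CLIP, _ETA_CLIP))
    XtWX = Xtr.T @ (Xtr * mu_tr[:, None])
    F = V @ XtWX
    edf = {n: float(np.trace(F[design.slices[n], design.slices[n]])) for n in term_names}
    freq_cov = F @ V  # V (X'WX) V

    fit = PGAMFit(
        unit_id=design.unit_id,
        terms=design.terms,
        slices=design.slices,
        beta=beta,
        intercept=float(beta[0]),
        posterior_cov=V,
        edf=edf,
        term_pvalues={},
        lambdas=lambdas,
        pseudo_r2_train=np.nan,
        pseudo_r2_test=np.nan,
        converged=converged,
        alpha=alpha,
        col_means=design.col_means,
        dt=design.dt,
        term_kind=design.term_kind,
        freq_cov=freq_cov,
    )
    for name, term in design.terms.items():
        term.beta = beta[design.slices[name]]
        term.lam = lambdas[name]
    fit.term_pvalues = {n: inclusion_test(fit, n) for n in term_names}

    fit.pseudo_r2_train = _pseudo_r2_from_mu(ytr, mu_tr)
    if test_mask.any():
        mu_te = np.exp(np.clip(X[test_mask] @ beta, -_ETA_CLIP, _ETA_CLIP))
        fit.pseudo_r2_test = _pseudo_r2_from_mu(y[test_mask], mu_te)
    return fit


def _safe_inv(A):
    try:
        c = linalg.cho_factor(A, check_finite=False)
        return linalg.cho_solve(c, np.eye(A.shape[0]), check_finite=False)
    except linalg.LinAlgError:
        return np.linalg.pinv(A)


def _pseudo_r2_from_mu(y, mu):
    null = np.full_like(y, y.mean(), dtype=float)
    dev_null = _poisson_deviance(y, null)
    if dev_null <= 0:
        return np.nan
    return 1.0 - _poisson_deviance(y, mu) / dev_null


# ---------------------------------------------------------------------------
# inclusion test and reduced model
# ---------------------------------------------------------------------------

def inclusion_test(fit: PGAMFit, term: str) -> float:
    """Wald-type p-value for the null that a term contributes nothing.

    The term's coefficient block is tested with the quadratic form
    beta' C^- beta against a chi-square whose degrees of freedom are the
    rounded effective degrees of freedom of the block. C is the block of the
    sampling covariance V (X'WX) V of the penalized estimator — under the
    null the shrinkage scales each coefficient and its standard error by the
    same factor, so the standardized statistic stays calibrated — and C^- is
    its rank-df pseudo-inverse (largest-eigenvalue directions, the
    effectively unpenalized ones).
    """
    sl = fit.slices[term]
    b = fit.term_beta(term)
    C = (fit.freq_cov if fit.freq_cov is not None else fit.posterior_cov)[sl, sl]
    C = 0.5 * (C + C.T)
    r = int(np.clip(round(fit.edf.get(term, len(b))), 1, len(b)))
    w, U = np.linalg.eigh(C)
    w = np.maximum(w, 0.0)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    if w[0] <= 0:
        return 1.0
    keep = w[:r]
    floor = 1e-12 * w[0]
    if np.any(keep < floor):  # singular block: jitter to the floor
        keep = np.maximum(keep, floor)
    T = float(np.sum((U[:, :r].T @ b) ** 2 / keep))
    return float(stats.chi2.sf(T, df=r))


def reduce_and_refit(
    design: Design,
    fit: PGAMFit,
    counts: np.ndarray,
    alpha: float = 0.01,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> PGAMFit:
    """Refit keeping only the terms passing inclusion at ``alpha``.

    Smoothness scales are carried over from the full fit. With no surviving
    terms an intercept-only model is returned.
    """
    selected = [n for n, p in fit.term_pvalues.items() if p < alpha]
    keep = [0] + [
        j for n in selected for j in range(*design.slices[n].indices(design.X.shape[1]))
    ]
    keep = np.array(keep)
    slices = {}
    start = 1
    for n in selected:
        nb = design.slices[n].stop - design.slices[n].start
        slices[n] = slice(start, start + nb)
        start += nb
    sub = Design(
        unit_id=design.unit_id,
        X=design.X[:, keep],
        terms={n: design.terms[n] for n in selected},
        slices=slices,
        col_means=design.col_means[keep],
        trial_index=design.trial_index,
        dt=design.dt,
        term_kind={n: design.term_kind[n] for n in selected},
    )
    return fit_pgam(
        sub,
        counts,
        seed=seed,
        fixed_lambda={n: fit.lambdas[n] for n in selected} if selected else 1.0,
        alpha=alpha,
        test_fraction=test_fraction,
    )


# ---------------------------------------------------------------------------
# session-level convenience
# ---------------------------------------------------------------------------

def fit_unit(
    session: BinnedSession,
    unit_id: int,
    spec: ModelConfig | None = None,
    seed: int = 0,
    **kwargs,
) -> tuple[PGAMFit, PGAMFit]:
    """Assemble, fit, and refit the reduced model for one unit.

    Returns (full fit, reduced fit).
    """
    spec = spec or ModelConfig()
    design = assemble_design(session, unit_id, spec)
    full = fit_pgam(
        design, session.counts[unit_id], seed=seed, alpha=spec.alpha,
        test_fraction=spec.test_fraction, **kwargs
    )
    red = reduce_and_refit(
        design, full, session.counts[unit_id], alpha=spec.alpha, seed=seed,
        test_fraction=spec.test_fraction,
    )
    return full, red
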