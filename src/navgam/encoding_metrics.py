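"""Model-quality and tuning-summary statistics.

* pseudo-R^2 — likelihood-ratio goodness of fit for Poisson observations:
  0 at the constant-rate null model, 1 at a saturated (perfect) prediction,
  occasionally negative on held-out data when a model overfits.
* mutual information I(Y;S) between spike counts and a discretized stimulus,
  under the Poisson assumption for the count distributions.
* discrimination index DDI = (Rmax - Rmin) / (Rmax - Rmin + 2 sqrt(SSE/(N-M))),
  a contrast-to-noise summary of a tuning function.
* tuning-curve extraction from a fitted encoding model, with credible bands
  and the preferred (peak) covariate value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "pseudo_r2",
    "mutual_information",
    "ddi",
    "ddi_from_series",
    "extract_tuning",
    "empirical_tuning",
    "TuningFunction",
    "DDIResult",
    "MIResult",
]


# ---------------------------------------------------------------------------
# pseudo-R^2
# ---------------------------------------------------------------------------

def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-300, None)
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def pseudo_r2(counts: np.ndarray, predicted: np.ndarray, null_rate: float) -> float:
    """Fraction of the maximum attainable likelihood gain over the null model.

        1 - [L(y) - L(yhat)] / [L(y) - L(ybar)]

    with Poisson log-likelihoods: L(y) at the saturated prediction (mu = y),
    L(yhat) at the model prediction, L(ybar) at the constant ``null_rate``
    (expected counts per bin). Returns NaN (flagged) for constant counts,
    where the saturated and null likelihoods coincide.
    """
    y = np.asarray(counts, dtype=float)
    mu = np.broadcast_to(np.asarray(predicted, dtype=float), y.shape)
    if null_rate <= 0:
        raise ValueError("null_rate must be positive")
    l_sat = _poisson_loglik(y, np.where(y > 0, y, 1e-300))
    l_hat = _poisson_loglik(y, mu)
    l_null = _poisson_loglik(y, np.full_like(y, null_rate))
    denom = l_sat - l_null
    if denom <= 1e-12:
        return float("nan")
    return 1.0 - (l_sat - l_hat) / denom


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

@dataclass
class MIResult:
    mi_bits: float
    h_y: float
    h_y_given_s: float
    stimulus_pmf: np.ndarray
    conditional_rates: np.ndarray


def _poisson_entropy_bits(lam: float, y_max: int) -> float:
    ks = np.arange(y_max + 1)
    p = stats.poisson.pmf(ks, lam)
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def mutual_information(
    tuning,
    stimulus_samples: np.ndarray,
    dt: float,
    n_bins: int | None = None,
    stimulus_dist: str = "empirical",
) -> MIResult:
    """I(Y;S) = H(Y) - H(Y|S) in bits for one unit/stimulus pair.

    The stimulus is discretized over the tuning grid; p(s) is the empirical
    pmf of the samples (or a moment-matched binomial over the stimulus bins
    with ``stimulus_dist="binomial"``). Counts are taken Poisson: H(Y) uses
    the unit's mean rate, H(Y|S) uses the per-bin model rate lambda(s) * dt.
    Sums over counts are truncated at the 1 - 1e-10 Poisson quantile. Empty
    stimulus bins are dropped with renormalization.
    """
    grid = np.asarray(tuning.grid, dtype=float)
    resp = np.asarray(tuning.response, dtype=float)  # rate in Hz over grid
    s = np.asarray(stimulus_samples, dtype=float)
    if n_bins is None:
        n_bins = min(len(grid), 15)
    edges = np.linspace(grid.min(), grid.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    countspmf = np.bincount(idx, minlength=n_bins).astype(float)
    keep = countspmf > 0
    if stimulus_dist == "empirical":
        pmf = countspmf[keep] / countspmf[keep].sum()
    elif stimulus_dist == "binomial":
        mean_bin = float(np.mean(idx))
        n = n_bins - 1
        pb = np.clip(mean_bin / n, 1e-9, 1 - 1e-9) if n else 0.5
        pmf = stats.binom.pmf(np.arange(n_bins), n, pb)[keep]
        pmf = pmf / pmf.sum()
    else:
        raise ValueError("stimulus_dist must be 'empirical' or 'binomial'")
    # lambda(s): model rate averaged over the samples falling in each bin
    rate_per_sample = np.interp(np.clip(s, grid.min(), grid.max()), grid, resp)
    sums = np.bincount(idx, weights=rate_per_sample, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        lam_s = (sums / countspmf)[keep] * dt  # expected counts per stimulus bin
    lam_s = np.clip(lam_s, 1e-12, None)
    lam_bar = float(np.sum(pmf * lam_s))
    y_max = int(stats.poisson.ppf(1.0 - 1e-10, max(lam_s.max(), lam_bar))) + 2
    h_y = _poisson_entropy_bits(lam_bar, y_max)
    h_cond = float(np.sum([p * _poisson_entropy_bits(l, y_max) for p, l in zip(pmf, lam_s)]))
    return MIResult(
        mi_bits=h_y - h_cond,
        h_y=h_y,
        h_y_given_s=h_cond,
        stimulus_pmf=pmf,
        conditional_rates=lam_s / dt,
    )


# ---------------------------------------------------------------------------
# discrimination index
# ---------------------------------------------------------------------------

@dataclass
class DDIResult:
    ddi: float
    r_max: float
    r_min: float
    sse: float
    n: int
    m: int


def ddi(responses: np.ndarray) -> DDIResult:
    """DDI from a (segments x stimulus-bins) matrix of mean responses.

    The tuning function is the across-segment mean per stimulus bin; SSE pools
    squared deviations of segment responses around their bin means; N is the
    number of finite observations and M the number of stimulus bins.
    """
    R = np.asarray(responses, dtype=float)
    if R.ndim != 2:
        raise ValueError("responses must be (segments, stimulus bins)")
    M = R.shape[1]
    finite = np.isfinite(R)
    N = int(finite.sum())
    if N <= M:
        raise ValueError(f"need more observations ({N}) than stimulus bins ({M})")
    with np.errstate(invalid="ignore"):
        bin_means = np.nanmean(R, axis=0)
    sse = float(np.nansum((R - bin_means) ** 2))
    r_max = float(np.nanmax(bin_means))
    r_min = float(np.nanmin(bin_means))
    noise = 2.0 * np.sqrt(sse / (N - M))
    denom = (r_max - r_min) + noise
    val = 0.0 if denom == 0 else (r_max - r_min) / denom
    return DDIResult(ddi=val, r_max=r_max, r_min=r_min, sse=sse, n=N, m=M)


def ddi_from_series(
    response: np.ndarray,
    stimulus: np.ndarray,
    m: int = 15,
    segments: int = 80,
) -> DDIResult:
    """DDI of a continuous recording: the session is cut into ``segments``
    contiguous equal-duration segments, the stimulus into ``m`` equi-spaced
    bins, and each cell holds that segment's mean response in that bin."""
    r = np.asarray(response, dtype=float)
    s = np.asarray(stimulus, dtype=float)
    edges = np.linspace(s.min(), s.max() + 1e-12, m + 1)
    sbin = np.clip(np.digitize(s, edges) - 1, 0, m - 1)
    seg = np.minimum((np.arange(len(r)) * segments) // len(r), segments - 1)
    table = np.full((segments, m), np.nan)
    for g in range(segments):
        msk = seg == g
        for b in np.unique(sbin[msk]):
            table[g, b] = r[msk][sbin[msk] == b].mean()
    return ddi(table)


# ---------------------------------------------------------------------------
# tuning curves
# ---------------------------------------------------------------------------

@dataclass
class TuningFunction:
    unit_id: int
    variable: str
    grid: np.ndarray
    response: np.ndarray  # rate (Hz) with other covariates at session means
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: float
    significant: bool

    @property
    def preferred(self) -> float:
        return float(self.grid[int(np.argmax(self.response))])


def extract_tuning(fit, variable: str, n_grid: int = 100, ci: float = 0.95) -> TuningFunction:
    """Tuning curve of one model term on the rate scale.

    The response is the model rate (Hz) along the term's knot span with every
    other covariate at its session mean; because penalized columns are
    mean-centred at assembly, that reference collapses to exp(intercept).
    Credible bands come from the Gaussian posterior of the term's
    coefficients. For temporal-filter terms the grid is the lag axis (s).
    """
    if variable not in fit.terms:
        raise KeyError(f"term {variable!r} not in fit")
    term = fit.terms[variable]
    if term.kind == "temporal_filter":
        grid = (np.arange(term.n_lags) + 1) * term.dt
        B = term.kernel_matrix()
    else:
        grid = np.linspace(term.knots[0], term.knots[-1], n_grid)
        B = term.design_c(grid) if term.constraint is not None else term.design(grid)
    beta = fit.term_beta(variable)
    cm = fit.term_col_means(variable)
    eta = B @ beta - float(cm @ beta)
    V = fit.term_cov(variable)
    sd = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", B, V, B), 0.0, None))
    z = stats.norm.ppf(0.5 + ci / 2.0)
    base = fit.intercept
    rate = np.exp(base + eta) / fit.dt
    p = fit.term_pvalues.get(variable, np.nan)
    return TuningFunction(
        unit_id=fit.unit_id,
        variable=variable,
        grid=grid,
        response=rate,
        ci_low=np.exp(base + eta - z * sd) / fit.dt,
        ci_high=np.exp(base + eta + z * sd) / fit.dt,
        p_value=float(p),
        significant=bool(p < fit.alpha),
    )


def empirical_tuning(
    counts: np.ndarray,
    values: np.ndarray,
    dt: float,
    n_bins: int = 15,
    trial_index: np.ndarray | None = None,
    trials: str = "all",
) -> tuple[np.ndarray, np.ndarray]:
    """Binned raw firing rate vs covariate value; (bin centers, rate in Hz).

    ``trials`` may be "odd"/"even" to restrict to alternating trials for
    split-half (cross-validated) preferred-value checks.
    """
    y = np.asarray(counts, dtype=float)
    x = np.asarray(values, dtype=float)
    mask = np.ones(len(y), dtype=bool)
    if trials != "all":
        if trial_index is None:
            raise ValueError("trial_index required for odd/even splits")
        parity = 1 if trials == "odd" else 0
        mask = (trial_index >= 0) & (trial_index % 2 == parity)
    edges = np.quantile(x[mask], np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    idx = np.clip(np.digitize(x[mask], edges) - 1, 0, n_bins - 1)
    num = np.bincount(idx, weights=y[mask], minlength=n_bins)
    den = np.bincount(idx, minlength=n_bins).astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        rate = num / den / dt
    return centers, rate
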