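# Methods

`navgam` implements an encoding-model pipeline for closed-loop virtual
navigation ("firefly") sessions: a penalized Poisson generalized additive
model (P-GAM) of single-unit spike trains, plus the behavioral, population-
clustering and coupling-network analyses built on top of it, all exercised on
a synthetic session generator with known ground truth. This note documents
the model, the defaults and the numerical choices, and what the synthetic
benchmark does and does not establish.

## The encoding model

Spike counts y_t of one unit in 6 ms bins are modelled as Poisson with

    log mu_t = a + sum_j f_j(x_jt) + sum_k (f_k * z_k)_t

where the x_j are continuous covariates — linear/angular velocity and
acceleration, the path-integration variables (distance and angle from the
trial origin), the target-vector variables (distance and angle to the hidden
target), horizontal/vertical eye position, and the instantaneous LFP phase in
theta (4–8 Hz), alpha (8–12 Hz) and beta (12–30 Hz) bands — and the z_k are
event trains (target onset, movement onset/offset, reward), the unit's own
spike history, and partner-unit spike trains, entering through causal lag
filters (`*` is convolution). With all families present the model has 17 task
inputs (10 continuous + 3 LFP phases + 4 events), plus history and coupling.

**Bases.** Every f is a cubic B-spline expansion. Continuous covariates get
15 knots by default, placed at equi-probable quantiles from the 2nd to the
98th percentile of the sampled values; values outside the span are clamped to
the boundary rather than extrapolated. LFP phases use periodic splines on
(−pi, pi] (b(−pi) = b(pi) to machine precision). Lag filters are spline bases
over the discrete lags (0, duration]: 36 ms (6 lags) with linearly spaced
knots for spike history and within-area coupling, 600 ms (100 lags) with
log-spaced knots for across-area coupling and event kernels, so long filters
resolve early lags more finely. All filters act from lag 1 bin, so spike
history excludes lag 0 by construction.

**Penalty.** Each term carries the curvature penalty
0.5 λ_f βᵀ S_f β with S_f = ∫ b'' b''ᵀ dx, computed per inter-knot interval
by 3-point Gauss–Legendre quadrature (exact for the piecewise-quadratic
integrand of cubic splines). The null space of S_f is the affine functions,
so λ → ∞ collapses a term to its best straight line. Penalties are rescaled
by the Frobenius norm of the corresponding design block so a single
dimensionless λ is comparable across terms.

**Identifiability.** Because B-splines form a partition of unity, the
constant function lies in every bin-wise term's span and in the penalty null
space, confounding the intercept and making the posterior covariance
degenerate. Each continuous/circular term is therefore reparametrized with a
sum-to-zero constraint (the all-ones coefficient direction removed) and every
penalized column is mean-centred, so the intercept carries the mean rate and
each term's session-average contribution is zero. A consequence used by the
tuning extractor: "other covariates at their session means" reduces to
exp(intercept).

**Fitting.** For fixed λ the penalized log-likelihood is maximized by Newton
iterations (penalized IRLS) with step halving; the objective is monotone
non-decreasing and the intercept score equation (Σ mu = Σ y on training bins)
holds at convergence to 1e−6 relative. λ is chosen by minimizing held-out
Poisson deviance over k = 5 cross-validation folds built from contiguous
trial blocks (inter-trial bins are retained and attached to the following
trial), searching a log-spaced grid; a shared λ across terms is the default,
with an optional per-term coordinate pass (`lambda_mode="per_term"`). 20% of
trials are held out entirely for the test pseudo-R². The seed governs only
the trial split; given the split the fit is deterministic. Linear predictors
are clipped at ±25 for overflow safety; a 1e−8 ridge stabilizes the Newton
system.

**Inclusion test.** Under the Gaussian-prior reading of the penalty, the fit
yields a posterior covariance V = (XᵀWX + P)⁻¹, used for credible bands on
tuning curves. For the variable-inclusion decision we instead use the
sampling covariance of the penalized estimator, V (XᵀWX) V: under the null
the shrinkage scales a coefficient and its standard error by the same
factor, so the standardized quadratic form stays calibrated, whereas the
posterior covariance overstates the variance of shrunk directions and makes
the test severely conservative (we measured 0/300 null flags at α = 0.01
versus 0.010 with the sandwich form). The statistic is βᵀ C⁻ β on the term's
block, with C⁻ the rank-r pseudo-inverse keeping the r largest-eigenvalue
(effectively unpenalized) directions, r the rounded effective degrees of
freedom of the block, referred to chi-square(r). Terms with p < 0.01 form the
reduced model, refit at the same λ; units with negative test pseudo-R²
should be excluded from population summaries (overfitting).

## Scoring and summaries

* **Pseudo-R²** = 1 − [L(y) − L(ŷ)]/[L(y) − L(ȳ)] with Poisson likelihoods,
  L(y) saturated: 0 at the constant-rate null, 1 at a perfect prediction,
  occasionally negative out of sample. Constant counts make it undefined
  (flagged NaN).
* **Mutual information** I(Y;S) = H(Y) − H(Y|S) in bits, counts taken Poisson
  with rate λ̄ (marginal) and λ(s)·dt (conditional), stimulus discretized with
  its empirical pmf (a moment-matched binomial is available behind
  `stimulus_dist="binomial"`); count sums truncated at the 1 − 1e−10 Poisson
  quantile; empty stimulus bins dropped with renormalization.
* **DDI** = (Rmax − Rmin)/(Rmax − Rmin + 2√(SSE/(N − M))) from a segments ×
  stimulus-bins response table; the series helper cuts a recording into 80
  contiguous equal-duration segments and 15 stimulus bins.
* **Tuning curves** are the model rate along a term's knot span with all
  other covariates at their session means, with Gaussian-posterior credible
  bands; the preferred value is the grid argmax. Split-half (odd/even trial)
  checks use binned raw rates.

## Behavior

Endpoints and targets are polar (r cm, θ deg, rightward positive). Trials
are excluded when the endpoint lies within 50 cm of the origin or no stop
occurs within 7 s (stop = both speeds below 1 cm/s and 1 deg/s for ≥ 200 ms;
configurable). Bias is the no-intercept regression slope of response on
target, radial and angular separately (1 = unbiased, < 1 = undershoot). The
gaze prediction projects the target center into binocular eye-centered
angles for a camera 0.1 m above the ground plane (interocular distance
3.5 cm, which only affects vergence and is near-negligible at task
distances); targets behind the observer or inside the 5 cm near plane are
flagged invalid. The target-tracking index is sqrt(max(0, 1 − SS_res/SS_tot))
pooled over horizontal/vertical components with eyes averaged, computed
against the prediction directly (no free gain; a gain-fit variant exists
behind a flag), per trial with whole-trial and first-second variants. The
bimodality coefficient is Sarle's (g1² + 1)/(g2 + 3(n−1)²/((n−2)(n−3))) with
bias-corrected skewness/kurtosis; its uniform null is 5/9 ≈ 0.556 (≈ 0.547 in
the mean at n = 200 due to finite-sample skewness variance), Gaussian ≈ 1/3.

## Population structure and coupling

Binary tuning profiles (17 booleans from the reduced-model selection) are
clustered by spectral partitioning of the Jaccard-similarity graph (default
k = 7, robustness expected for k ≥ 3); stacked tuning shapes (z-scored per
variable) are reduced by PCA to the smallest dimension exceeding 90%
explained variance, embedded in 2D by UMAP and clustered by DBSCAN with the
neighborhood radius at the knee of the 4-distance curve (capped at the 99th
percentile and given 1.5× headroom, since the chord-knee undershoots when no
genuine outliers exist). Subsample-to-match controls re-run either analysis
with larger areas drawn down (without replacement) to the smallest area's
unit count. Tuned fractions carry exact Clopper–Pearson 99% CIs; area
contrasts report a two-proportion z-test and Cohen's d on a modulation
metric.

Coupling edges are the `coupling_<sender>` terms passing inclusion at
α = 0.01 in each receiver's fit; fractions are directional (fraction of
sender-area units with ≥ 1 significant edge into the receiver area, among
those with a candidate partner there; edge-density mode behind a flag).
Within-area coupling probability is corrected for electrode distance by a
penalized spline-logistic model p(c=1|d) = logit⁻¹ f(d), reported at the
500 µm reference; electrode distance is undefined (and unused) across areas.
Session-level association between coupling fractions and the tracking index
(whole-trial, averaged across trials) uses OLS per sender→receiver cell,
restricted to sessions with mean pseudo-R² > 0.05 and ≥ 2 units in each of
two areas, with raw and Bonferroni-corrected p-values (9 cells). Like-to-like
connectivity is tested by the Spearman correlation between pairwise
tuning-shape similarity and coupling, with a permutation p-value.

## Synthetic sessions

The generator emulates the task's study conditions: targets uniform on
1–4 m × ±40°; a proportional steering controller with speed caps 2 m/s and
90 deg/s and smooth acceleration ramps produces curvilinear trajectories to a
goal at gain × target + noise (default gains 0.89 radial / 0.79 angular,
endpoint noise 30 cm / 4°); 300 ms target visibility; reward within 0.6 m of
the true target; inter-trial intervals truncated-exponential on 0.2–2.0 s
with mean 0.5 s; 5% near-origin-stop and 13% no-stop trials; 7 s maximum
duration. Gaze mixes the perfect-fixation prediction with AR(1) drift scaled
so the expected whole-trial tracking index equals `tracking_quality`
(default 0.73). LFP phases are band-center oscillators with phase diffusion.
Spikes are Poisson draws from the same log-additive model the analysis fits,
with spike-history and coupling kernels applied sequentially in time so the
causal filters have a well-defined truth; per-bin expected rates are capped
at a 1 kHz equivalent. The default 30-unit cohort assigns area-stereotyped
tuning probabilities (MSTd eye-heavy, 7a sensorimotor/LFP-heavy, dlPFC
latent-heavy) and distance-decaying within-area coupling with an
MSTd↔dlPFC-biased across-area component — configuration for exercising the
population analyses, not an empirical claim.

What passing the synthetic benchmark shows: the fitting, testing, selection,
clustering and coupling machinery recover a known generative truth at
realistic firing rates and session lengths. What it does not show: robustness
to un-modelled features of real recordings — spike-sorting contamination,
non-Poisson dispersion, nonstationary rates, electrode drift, or correlated
measurement noise in the behavioral streams.

## Problem sizes and tolerances

The repeated-fit studies (type-I calibration of the inclusion test; reduced-
model selection stability) use 100 simulated units of 8–10 minutes each at
10 Hz with 3 tuned + 5 null covariates, with the smoothness scale
cross-validated once on a pilot unit and reused across the cohort; the
single-unit recovery check uses a 30-minute unit with full cross-validation.
The clustering benchmark uses 600 units (areas 231/200/169) with 10% bit-flip
noise and 40 subsample draws; the planted coupling network uses 12 units over
6 minutes. Numerical tolerances: quadrature vs dense-integration agreement
1e−6 relative; MI vs direct summation 1e−10 bits; DDI closed form 1e−12;
intercept score equation 1e−6 relative. Degenerate inputs (zero-spike units,
constant covariates, empty event trains, constant observed gaze, single
electrode distance) return flagged results or are dropped with warnings
rather than raising mid-pipeline.
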