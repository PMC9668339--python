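"""Spline bases and smoothness penalties for the encoding model.

Three kinds of smooth term are supported:

* ``continuous`` — cubic B-splines over the sampled range of a covariate, with
  knots placed at equi-probable quantiles between the 2nd and 98th percentile
  and values outside the knot span clamped to its boundary;
* ``circular`` — periodic cubic B-splines on (-pi, pi] for angles entered as
  phase (LFP bands), with b(-pi) == b(pi);
* ``temporal_filter`` — a causal spline basis over discrete lags (0, duration]
  whose columns, convolved with an event or spike train, produce the design
  columns of the convolutional terms of the model.

Each term carries a curvature penalty S = int b'' b''^T dx, so that the null
space of the penalty is exactly the affine functions and a penalized fit with
lambda -> inf collapses to the best straight-line tuning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import BSpline

DEGREE = 3  # cubic splines throughout


# ---------------------------------------------------------------------------
# knot placement
# ---------------------------------------------------------------------------

def place_knots(samples: np.ndarray, n_knots: int = 15) -> np.ndarray:
    """Equi-probable knots from the 2nd to the 98th percentile of ``samples``.

    Knots sit at the q-quantiles for q linearly spaced on [0.02, 0.98], so each
    inter-knot interval carries the same probability mass. Duplicate quantiles
    (mass atoms) are collapsed with a warning.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < n_knots:
        raise ValueError(f"need at least {n_knots} samples, got {x.size}")
    qs = np.linspace(0.02, 0.98, n_knots)
    knots = np.quantile(x, qs)
    uniq = np.unique(knots)
    if uniq.size < 2:
        raise ValueError("degenerate knots: samples carry no spread between the "
                         "2nd and 98th percentile")
    if uniq.size < knots.size:
        warnings.warn(
            f"collapsed {knots.size - uniq.size} duplicate knots (mass atoms)",
            stacklevel=2,
        )
    return uniq


def _full_knots(knots: np.ndarray) -> np.ndarray:
    """Open (clamped) knot vector: boundary knots repeated DEGREE times."""
    return np.concatenate(
        ([knots[0]] * DEGREE, knots, [knots[-1]] * DEGREE)
    )


def _periodic_knots(knots: np.ndarray, period: float) -> np.ndarray:
    """Knot vector extended by one period on each side for wrap-around."""
    pre = knots[-(DEGREE + 1) : -1] - period
    post = knots[1 : DEGREE + 1] + period
    return np.concatenate((pre, knots, post))


# ---------------------------------------------------------------------------
# smooth terms
# ---------------------------------------------------------------------------

@dataclass
class SmoothTerm:
    """One covariate's spline basis, penalty and (after fitting) coefficients.

    ``knots`` are the placed (deduplicated) knot abscissae. For circular terms
    they must start/end one period apart (e.g. -pi and pi). For temporal
    filters the abscissa is the lag in seconds and ``n_lags`` gives the kernel
    support in bins.
    """

    name: str
    kind: str  # {"continuous", "circular", "temporal_filter"}
    knots: np.ndarray
    order: int = DEGREE + 1
    dt: float | None = None  # bin width, temporal filters only
    n_lags: int | None = None
    beta: np.ndarray | None = None
    lam: float = 1.0
    penalty: np.ndarray | None = field(default=None, repr=False)
    #: penalty rescaled to the magnitude of its design block (set at design
    #: assembly so one dimensionless lambda is comparable across terms)
    penalty_scaled: np.ndarray | None = field(default=None, repr=False)
    #: identifiability constraint for bin-wise smooths: the constant function
    #: (partition of unity) is removed from the coefficient space so the
    #: intercept stays identified; None for temporal filters
    constraint: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if self.order - 1 != DEGREE:
            raise ValueError("only cubic splines are supported")
        if self.kind not in ("continuous", "circular", "temporal_filter"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.penalty is None:
            self.penalty = penalty_matrix(self)

    @property
    def n_basis(self) -> int:
        K = len(self.knots)
        if self.kind == "circular":
            return K - 1
        return K + DEGREE - 1

    @property
    def period(self) -> float:
        return float(self.knots[-1] - self.knots[0])

    def design(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis at covariate values ``x`` -> (n, n_basis)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "circular":
            per = self.period
            xw = self.knots[0] + np.mod(x - self.knots[0], per)
            t = _periodic_knots(self.knots, per)
            B = BSpline.design_matrix(xw, t, DEGREE, extrapolate=False).toarray()
            K = len(self.knots)
            # fold wrap-around columns (j and j + K - 1 are periodic images):
            # the dimension of the periodic space is K - 1
            Bp = B[:, : K - 1].copy()
            Bp[:, : DEGREE] += B[:, K - 1 :]
            return Bp
        xc = np.clip(x, self.knots[0], self.knots[-1])  # clamp outside the span
        t = _full_knots(self.knots)
        return BSpline.design_matrix(xc, t, DEGREE).toarray()

    # -- temporal filters ---------------------------------------------------

    def kernel_matrix(self) -> np.ndarray:
        """(n_lags, n_basis) basis evaluated at the discrete lags dt..L*dt."""
        if self.kind != "temporal_filter":
            raise ValueError("kernel_matrix is defined for temporal filters only")
        lags = (np.arange(self.n_lags) + 1) * self.dt
        return self.design(lags)

    def convolve(self, train: np.ndarray) -> np.ndarray:
        """Causal convolution of an event/spike train with each basis column.

        The kernel acts at lags 1..n_lags bins, so the bin of the event itself
        receives no contribution (spike-history filters therefore exclude lag
        0 by construction).
        """
        K = self.kernel_matrix()
        T = len(train)
        out = np.empty((T, K.shape[1]))
        for j in range(K.shape[1]):
            kern = np.concatenate(([0.0], K[:, j]))
            out[:, j] = np.convolve(train, kern)[:T]
        return out

    def apply_constraint(self) -> np.ndarray:
        """Install the sum-to-zero constraint; returns the (nb, nb-1) map Z.

        The spline partition of unity makes the all-ones coefficient vector
        represent the constant function, which is confounded with the model
        intercept and unpenalized by the curvature penalty. Reparametrizing
        with Z spanning the complement of that direction removes the
        degeneracy: the constrained design is B @ Z with penalty Z' S Z.
        """
        from scipy.linalg import null_space

        if self.constraint is None:
            self.constraint = null_space(np.ones((1, self.n_basis)))
        return self.constraint

    def design_c(self, x: np.ndarray) -> np.ndarray:
        """Basis evaluated under the identifiability constraint (if any)."""
        B = self.design(x)
        return B @ self.constraint if self.constraint is not None else B

    @property
    def penalty_c(self) -> np.ndarray:
        if self.constraint is None:
            return self.penalty
        return self.constraint.T @ self.penalty @ self.constraint

    def evaluate(self, x: np.ndarray, beta: np.ndarray | None = None) -> np.ndarray:
        """Evaluate f(x) for coefficients in the (possibly constrained) space."""
        b = self.beta if beta is None else beta
        if b is None:
            raise ValueError("term has no coefficients")
        b = np.asarray(b, dtype=float)
        if self.constraint is not None and b.shape[0] == self.constraint.shape[1]:
            return self.design_c(x) @ b
        return self.design(x) @ b

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "knots": self.knots.tolist(),
            "order": self.order,
            "dt": self.dt,
            "n_lags": self.n_lags,
            "lambda": self.lam,
            "beta": None if self.beta is None else np.asarray(self.beta).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothTerm":
        t = cls(
            name=d["name"],
            kind=d["kind"],
            knots=np.asarray(d["knots"], dtype=float),
            order=d.get("order", DEGREE + 1),
            dt=d.get("dt"),
            n_lags=d.get("n_lags"),
            lam=d.get("lambda", 1.0),
        )
        if d.get("beta") is not None:
            t.beta = np.asarray(d["beta"], dtype=float)
        return t


def continuous_term(name: str, samples: np.ndarray, n_knots: int = 15) -> SmoothTerm:
    """Cubic spline term with equi-probable knots over the sampled range."""
    return SmoothTerm(name=name, kind="continuous", knots=place_knots(samples, n_knots))


def circular_term(name: str, n_knots: int = 9, period: float = 2 * np.pi) -> SmoothTerm:
    """Periodic spline term on (-period/2, period/2] (uniform knots)."""
    knots = np.linspace(-period / 2, period / 2, n_knots)
    return SmoothTerm(name=name, kind="circular", knots=knots)


def temporal_basis(
    duration: float,
    dt: float,
    name: str = "filter",
    n_knots: int | None = None,
    spacing: str | None = None,
) -> SmoothTerm:
    """Causal lag-filter spline basis covering (0, duration].

    Short filters (<= 60 ms) get linearly spaced lag knots; long filters get
    log-spaced knots so early lags are resolved more finely. The number of lag
    bins is duration/dt, which must be a positive integer multiple.
    """
    n_lags = int(round(duration / dt))
    if n_lags < 1 or abs(n_lags * dt - duration) > 1e-9:
        raise ValueError("duration must be a positive multiple of dt")
    if spacing is None:
        spacing = "linear" if duration <= 0.060 + 1e-9 else "log"
    if n_knots is None:
        n_knots = min(n_lags, 4) if spacing == "linear" else 6
    lo, hi = dt, n_lags * dt
    if spacing == "linear":
        knots = np.linspace(lo, hi, n_knots)
    elif spacing == "log":
        knots = np.exp(np.linspace(np.log(lo), np.log(hi), n_knots))
    else:
        raise ValueError("spacing must be 'linear' or 'log'")
    return SmoothTerm(
        name=name, kind="temporal_filter", knots=np.unique(knots), dt=dt, n_lags=n_lags
    )


# ---------------------------------------------------------------------------
# curvature penalty
# ---------------------------------------------------------------------------

def penalty_matrix(term: SmoothTerm) -> np.ndarray:
    """S[i, j] = int b_i''(x) b_j''(x) dx over the knot span.

    Computed per inter-knot interval with 3-point Gauss-Legendre quadrature,
    exact for the piecewise-quadratic integrand of cubic splines.
    """
    if term.order - 1 < 2:
        raise ValueError("second-derivative penalty needs spline order >= 2")
    knots = term.knots
    if term.kind == "circular":
        t = _periodic_knots(knots, knots[-1] - knots[0])
        nb_full = len(t) - DEGREE - 1
    else:
        t = _full_knots(knots)
        nb_full = len(t) - DEGREE - 1
    gx, gw = np.polynomial.legendre.leggauss(3)
    xs, ws = [], []
    for a, b in zip(knots[:-1], knots[1:]):
        half = (b - a) / 2.0
        xs.append((a + b) / 2.0 + half * gx)
        ws.append(half * gw)
    xs = np.concatenate(xs)
    ws = np.concatenate(ws)
    # second derivatives of every basis function at the quadrature points
    D2 = np.empty((len(xs), nb_full))
    eye = np.eye(nb_full)
    for j in range(nb_full):
        D2[:, j] = BSpline(t, eye[j], DEGREE, extrapolate=True).derivative(2)(xs)
    if term.kind == "circular":
        K = len(knots)
        D2p = D2[:, : K - 1].copy()
        D2p[:, : DEGREE] += D2[:, K - 1 :]
        D2 = D2p
    S = (D2 * ws[:, None]).T @ D2
    return 0.5 * (S + S.T)


def export_basis(term: SmoothTerm, path: str | Path) -> None:
    """Write the term definition (JSON) and penalty matrix (CSV) side by side."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.with_suffix(".json").write_text(json.dumps(term.to_dict(), indent=1))
    np.savetxt(path.with_suffix(".penalty.csv"), term.penalty, delimiter=",")
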