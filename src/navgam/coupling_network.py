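"""Unit-to-unit coupling networks and their relation to behavior.

Coupling filters fitted by the encoding model capture signal-independent
(noise) correlations: a directed edge sender -> receiver means the sender's
spiking shifts the receiver's firing probability at short lags (36 ms within
an area, 600 ms across areas). This module extracts the significant edges,
corrects within-area coupling probability for electrode distance with a
spline-logistic model evaluated at a 500 um reference, and correlates
session-level coupling fractions with behavioral target tracking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import linalg, stats

from .bases import SmoothTerm, place_knots
from .core_data import AREAS

__all__ = [
    "CouplingGraph",
    "DistanceModel",
    "extract_couplings",
    "coupling_fractions",
    "distance_corrected_probability",
    "coupling_behavior_correlation",
    "tuning_similarity_vs_coupling",
]


@dataclass
class CouplingGraph:
    """Directed significant couplings plus per-pair candidate bookkeeping."""

    graph: nx.DiGraph
    alpha: float

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "sender": s,
                "receiver": r,
                "sender_area": self.graph.nodes[s]["area"],
                "receiver_area": self.graph.nodes[r]["area"],
                "p_value": d["p_value"],
                "significant": d["significant"],
                "distance_um": d.get("distance_um", np.nan),
                "peak_lag_s": d.get("peak_lag_s", np.nan),
                "sign": d.get("sign", 0),
            }
            for s, r, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)


def extract_couplings(fits: dict[int, "object"], unit_meta: pd.DataFrame, alpha: float = 0.01) -> CouplingGraph:
    """Build the directed coupling graph from per-unit encoding fits.

    ``fits`` maps receiver unit id -> fitted model whose coupling terms are
    named ``coupling_<sender>``. Every candidate pair becomes a graph edge
    carrying its inclusion p-value; ``significant`` marks p < alpha. Self
    edges cannot occur (a unit's own history is a separate term).
    """
    meta = unit_meta.set_index("unit_id")
    g = nx.DiGraph()
    for uid in meta.index:
        g.add_node(
            int(uid),
            area=meta.loc[uid, "area"],
            elec=(float(meta.loc[uid, "elec_x"]), float(meta.loc[uid, "elec_y"])),
        )
    for receiver, fit in fits.items():
        for name, p in fit.term_pvalues.items():
            if not name.startswith("coupling_"):
                continue
            sender = int(name.split("_", 1)[1])
            if sender == receiver:
                continue
            d = np.nan
            if meta.loc[sender, "area"] == meta.loc[receiver, "area"]:
                d = float(
                    np.hypot(
                        meta.loc[sender, "elec_x"] - meta.loc[receiver, "elec_x"],
                        meta.loc[sender, "elec_y"] - meta.loc[receiver, "elec_y"],
                    )
                )
            peak_lag = np.nan
            sign = 0
            term = fit.terms.get(name)
            if term is not None and term.beta is not None:
                kern = term.kernel_matrix() @ term.beta
                peak_lag = float((np.argmax(np.abs(kern)) + 1) * term.dt)
                sign = int(np.sign(kern[np.argmax(np.abs(kern))]))
            g.add_edge(
                sender,
                receiver,
                p_value=float(p),
                significant=bool(p < alpha),
                distance_um=d,
                peak_lag_s=peak_lag,
                sign=sign,
            )
    return CouplingGraph(graph=g, alpha=alpha)


def coupling_fractions(coupling: CouplingGraph, mode: str = "units") -> pd.DataFrame:
    """Sender-area x receiver-area coupling summary.

    ``mode="units"`` (default): fraction of sender-area units with at least
    one significant outgoing edge to the receiver area, among sender units
    with at least one candidate partner there. ``mode="edges"``: significant
    edge density among candidate pairs.
    """
    e = coupling.edges
    areas = sorted({d["area"] for _, d in coupling.graph.nodes(data=True)})
    out = pd.DataFrame(np.nan, index=areas, columns=areas)
    if e.empty:
        return out
    for sa in areas:
        for ra in areas:
            sub = e[(e.sender_area == sa) & (e.receiver_area == ra)]
            if sub.empty:
                continue
            if mode == "units":
                per_sender = sub.groupby("sender")["significant"].any()
                out.loc[sa, ra] = float(per_sender.mean())
            elif mode == "edges":
                out.loc[sa, ra] = float(sub["significant"].mean())
            else:
                raise ValueError("mode must be 'units' or 'edges'")
    return out


# ---------------------------------------------------------------------------
# distance correction
# ---------------------------------------------------------------------------

@dataclass
class DistanceModel:
    """Within-area coupling probability as a smooth function of electrode
    distance: p(c=1 | d) = logit^-1 f(d), f spline-expanded."""

    area: str
    term: SmoothTerm | None
    beta: np.ndarray | None
    intercept: float
    fallback_p: float | None = None

    def predict(self, d: np.ndarray) -> np.ndarray:
        d = np.atleast_1d(np.asarray(d, dtype=float))
        if self.term is None:
            return np.full(d.shape, self.fallback_p)
        eta = self.intercept + self.term.design_c(d) @ self.beta
        return 1.0 / (1.0 + np.exp(-eta))

    @property
    def p500(self) -> float:
        """Model prediction at the 500 um reference distance."""
        return float(self.predict(np.array([500.0]))[0])


def _logistic_pirls(X, y, P, max_iter=100, tol=1e-10):
    p = X.shape[1]
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = np.clip(mu * (1 - mu), 1e-10, None)
        g = X.T @ (y - mu) - P @ beta
        A = X.T @ (X * W[:, None]) + P + 1e-10 * np.eye(p)
        step = linalg.solve(A, g, assume_a="pos")
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def distance_corrected_probability(
    distances: np.ndarray,
    coupled: np.ndarray,
    area: str = "",
    n_knots: int = 5,
    lam: float = 1.0,
) -> DistanceModel:
    """Fit p(coupled | electrode distance) by penalized spline logistic
    regression for one area's candidate pairs.

    Needs >= 50 candidate pairs spanning >= 3 distinct distances; with a
    single distance the raw proportion is returned with a warning.
    """
    d = np.asarray(distances, dtype=float)
    c = np.asarray(coupled, dtype=float)
    uniq = np.unique(d)
    if len(uniq) < 3:
        warnings.warn("too few distinct distances; returning raw proportion", stacklevel=2)
        return DistanceModel(area=area, term=None, beta=None, intercept=np.nan,
                             fallback_p=float(c.mean()))
    if len(d) < 50:
        raise ValueError("need at least 50 candidate pairs")
    knots = place_knots(d, n_knots=min(n_knots, len(uniq)))
    term = SmoothTerm(name="distance", kind="continuous", knots=knots)
    term.apply_constraint()
    B = term.design_c(d)
    X = np.column_stack([np.ones(len(d)), B])
    P = np.zeros((X.shape[1], X.shape[1]))
    S = term.penalty_c
    P[1:, 1:] = lam * S / max(np.linalg.norm(S, "fro"), 1e-12) * np.linalg.norm(B.T @ B, "fro")
    beta = _logistic_pirls(X, c, P)
    return DistanceModel(area=area, term=term, beta=beta[1:], intercept=float(beta[0]))


# ---------------------------------------------------------------------------
# coupling vs behavior across sessions
# ---------------------------------------------------------------------------

def coupling_behavior_correlation(
    sessions: pd.DataFrame,
    min_pseudo_r2: float = 0.05,
    min_units_per_area: int = 2,
    min_sessions: int = 5,
) -> pd.DataFrame:
    """OLS association between target tracking and coupling, per area pair.

    ``sessions`` needs columns ``tracking_index`` (whole-trial index averaged
    across trials), ``mean_pseudo_r2``, ``n_units_<area>`` and
    ``frac_<sender>_<receiver>`` for each area pair. Sessions qualify when the
    mean pseudo-R^2 exceeds ``min_pseudo_r2`` and at least two areas have
    >= ``min_units_per_area`` units. Returns one row per sender->receiver pair
    with r^2, raw p and Bonferroni-corrected p (across the 9 cells).
    """
    ok_fit = sessions["mean_pseudo_r2"] > min_pseudo_r2
    unit_cols = [c for c in sessions.columns if c.startswith("n_units_")]
    enough = (sessions[unit_cols] >= min_units_per_area).sum(axis=1) >= 2
    df = sessions[ok_fit & enough]
    rows = []
    n_cells = sum(
        1 for sa in AREAS for ra in AREAS if f"frac_{sa}_{ra}" in sessions.columns
    )
    for sa in AREAS:
        for ra in AREAS:
            col = f"frac_{sa}_{ra}"
            if col not in sessions.columns:
                continue
            sub = df[["tracking_index", col]].dropna()
            row = {"sender": sa, "receiver": ra, "n_sessions": len(sub)}
            if len(sub) < min_sessions:
                row.update({"r2": np.nan, "p_value": np.nan, "slope": np.nan,
                            "underpowered": True})
            elif sub["tracking_index"].nunique() < 2:
                row.update({"r2": np.nan, "p_value": np.nan, "slope": np.nan,
                            "underpowered": True})
            else:
                res = stats.linregress(sub["tracking_index"], sub[col])
                row.update(
                    {
                        "r2": float(res.rvalue**2),
                        "p_value": float(res.pvalue),
                        "slope": float(res.slope),
                        "underpowered": False,
                    }
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p_value"] * max(n_cells, 1), 1.0)
    return out


# ---------------------------------------------------------------------------
# like-to-like connectivity
# ---------------------------------------------------------------------------

def tuning_similarity_vs_coupling(
    similarity: np.ndarray,
    coupled: np.ndarray,
    n_bins: int = 8,
    n_permutations: int = 2000,
    seed: int = 0,
) -> dict:
    """Does coupling probability increase with tuning similarity?

    ``similarity`` holds pairwise correlations of stacked tuning shapes and
    ``coupled`` the corresponding significance booleans, one entry per
    candidate pair. Pairs are binned by similarity; the statistic is the
    Spearman rank correlation between pair similarity and coupling, with a
    permutation p-value (coupling labels shuffled across pairs).
    """
    s = np.asarray(similarity, dtype=float)
    c = np.asarray(coupled, dtype=float)
    if len(s) != len(c) or len(s) < n_bins:
        raise ValueError("similarity/coupled must match and exceed n_bins")
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    rate = np.array([c[idx == b].mean() if (idx == b).any() else np.nan for b in range(n_bins)])
    rho = stats.spearmanr(s, c).statistic
    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm[i] = stats.spearmanr(s, rng.permutation(c)).statistic
    p = float((np.sum(np.abs(perm) >= abs(rho)) + 1) / (n_permutations + 1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {
        "rho": float(rho),
        "p_value": p,
        "bin_centers": centers,
        "coupling_rate": rate,
    }
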