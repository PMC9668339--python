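"""Area-level coding summaries and population clustering.

Two complementary clusterings of the per-unit encoding profiles:

* ``jaccard_spectral_cluster`` — units described by a binary vector (tuned /
  not tuned at p < 0.01 for each of the 17 task variables), clustered by
  spectral partitioning of the Jaccard similarity graph into k groups
  (default k = 7; findings should be robust for k >= 3).
* ``shape_embed_cluster`` — units described by their stacked (per-variable
  z-scored) tuning-curve shapes, reduced by PCA to the smallest number of
  components explaining > 90% of variance, embedded on a 2D manifold (UMAP),
  and clustered by spatial density (DBSCAN with the neighborhood radius at
  the knee of the k-distance curve).

Plus binomial tuned-fraction summaries with 99% CIs, centroid-distance
ratios in the embedding, and subsample-to-match controls for unequal area
sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from sklearn.cluster import DBSCAN, SpectralClustering
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TuningProfile",
    "ClusterAssignment",
    "fraction_tuned",
    "area_contrast",
    "jaccard_spectral_cluster",
    "shape_embed_cluster",
    "centroid_distance_ratio",
    "subsampled_cluster_control",
    "subsampled_centroid_ratio",
]


@dataclass
class TuningProfile:
    unit_id: int
    area: str
    binary_vector: np.ndarray  # tuned-or-not per task variable
    stacked_shape: np.ndarray | None = None


@dataclass
class ClusterAssignment:
    method: str
    labels: np.ndarray
    k: int
    embedding_2d: np.ndarray | None = None

    def cluster_fractions(self, areas: np.ndarray) -> pd.DataFrame:
        """Fraction of each area's units in each cluster."""
        df = pd.DataFrame({"area": areas, "label": self.labels})
        return df.groupby(["area", "label"]).size().unstack(fill_value=0).apply(
            lambda r: r / r.sum(), axis=1
        )


# ---------------------------------------------------------------------------
# tuned fractions
# ---------------------------------------------------------------------------

def fraction_tuned(tuned: np.ndarray, ci: float = 0.99) -> dict:
    """Binomial proportion of tuned units with an exact (Clopper-Pearson) CI."""
    tuned = np.asarray(tuned, dtype=bool)
    n = len(tuned)
    k = int(tuned.sum())
    lo, hi = proportion_confint(k, n, alpha=1 - ci, method="beta")
    return {
        "fraction": k / n if n else np.nan,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n": n,
        "wide": n < 5,
    }


def area_contrast(
    tuned_a: np.ndarray, tuned_b: np.ndarray,
    metric_a: np.ndarray | None = None, metric_b: np.ndarray | None = None,
) -> dict:
    """Two-proportion contrast of tuned fractions between areas, with Cohen's
    d on an underlying modulation metric when one is supplied."""
    a = np.asarray(tuned_a, dtype=bool)
    b = np.asarray(tuned_b, dtype=bool)
    pa, pb = a.mean(), b.mean()
    p = (a.sum() + b.sum()) / (len(a) + len(b))
    se = np.sqrt(p * (1 - p) * (1 / len(a) + 1 / len(b)))
    z = (pa - pb) / se if se > 0 else 0.0
    out = {"p_value": float(2 * stats.norm.sf(abs(z))), "diff": float(pa - pb)}
    if metric_a is not None and metric_b is not None:
        ma, mb = np.asarray(metric_a, float), np.asarray(metric_b, float)
        nd = len(ma) + len(mb) - 2
        sp = np.sqrt(((len(ma) - 1) * ma.var(ddof=1) + (len(mb) - 1) * mb.var(ddof=1)) / nd)
        out["cohens_d"] = float(abs(ma.mean() - mb.mean()) / sp) if sp > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# Jaccard spectral clustering
# ---------------------------------------------------------------------------

def jaccard_spectral_cluster(
    profiles: np.ndarray, k: int = 7, seed: int = 0
) -> ClusterAssignment:
    """Spectral k-way partition of the Jaccard-similarity graph of binary
    tuning profiles. Deterministic given the seed."""
    B = np.asarray(profiles, dtype=bool)
    uniq = np.unique(B, axis=0)
    if len(uniq) < k:
        if len(uniq) == 1:
            warnings.warn("all profiles identical: single cluster", stacklevel=2)
            return ClusterAssignment("jaccard_spectral", np.zeros(len(B), int), 1)
        raise ValueError(f"need at least k={k} distinct profiles, got {len(uniq)}")
    D = squareform(pdist(B, metric="jaccard"))
    S = 1.0 - D
    model = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed, assign_labels="kmeans"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = model.fit_predict(S)
    return ClusterAssignment("jaccard_spectral", labels, k)


def subsampled_cluster_control(
    profiles: np.ndarray,
    areas: np.ndarray,
    match_area: str,
    k: int = 7,
    n_iter: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeat the Jaccard-spectral clustering while subsampling every larger
    area (without replacement) to the unit count of ``match_area``; returns
    per-area ratios of the modal (largest) cluster size to the area size."""
    B = np.asarray(profiles, dtype=bool)
    areas = np.asarray(areas)
    rng = np.random.default_rng(seed)
    n_match = int(np.sum(areas == match_area))
    rows = []
    for it in range(n_iter):
        keep = []
        for a in np.unique(areas):
            idx = np.flatnonzero(areas == a)
            if len(idx) > n_match:
                idx = rng.choice(idx, n_match, replace=False)
            keep.append(idx)
        keep = np.concatenate(keep)
        lab = jaccard_spectral_cluster(B[keep], k=k, seed=int(rng.integers(2**31))).labels
        for a in np.unique(areas):
            m = areas[keep] == a
            counts = np.bincount(lab[m])
            rows.append({"iter": it, "area": a, "modal_fraction": counts.max() / m.sum()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shape embedding + density clustering
# ---------------------------------------------------------------------------

def _knee_eps(X: np.ndarray, k: int = 4) -> float:
    """Neighborhood radius at the knee (max distance-to-chord) of the sorted
    k-th nearest-neighbor distance curve."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    d = np.sort(nn.kneighbors(X)[0][:, -1])
    n = len(d)
    x = np.arange(n, dtype=float)
    chord = d[0] + (d[-1] - d[0]) * x / (n - 1)
    knee = int(np.argmax(np.abs(d - chord)))
    # without genuine outliers the k-distance curve has no sharp elbow and
    # the chord knee undershoots; allow headroom but stay below the extreme
    # tail so real outliers still become noise
    eps = float(min(np.percentile(d, 99), 1.5 * d[knee]))
    return eps if eps > 0 else float(d[d > 0].min() if (d > 0).any() else 1.0)


def shape_embed_cluster(
    profiles: np.ndarray,
    seed: int = 0,
    var_threshold: float = 0.90,
    standardize: bool = False,
    min_samples: int = 5,
) -> ClusterAssignment:
    """PCA (> ``var_threshold`` variance) -> UMAP 2D -> DBSCAN density labels.

    ``profiles`` is the (units x sum n_i) matrix of stacked tuning shapes,
    normally already z-scored per variable (set ``standardize`` to z-score
    columns here instead). DBSCAN's radius comes from the knee of the
    4-distance curve; label -1 marks density outliers ("noise").
    """
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 units")
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=min(X.shape), random_state=seed).fit(X)
    m = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), var_threshold) + 1)
    Z = pca.transform(X)[:, :m]
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(Z)
    emb = np.asarray(emb, dtype=float)
    labels = DBSCAN(eps=_knee_eps(emb), min_samples=min_samples).fit_predict(emb)
    k = int(len(set(labels) - {-1}))
    return ClusterAssignment("shape_embedding_density", labels, k, embedding_2d=emb)


def pca_dimension(profiles: np.ndarray, var_threshold: float = 0.90) -> int:
    """Smallest number of principal components explaining > threshold variance."""
    X = np.asarray(profiles, dtype=float)
    pca = PCA(n_components=min(X.shape)).fit(X)
    return int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), var_threshold) + 1)


# ---------------------------------------------------------------------------
# centroid distances
# ---------------------------------------------------------------------------

def centroid_distance_ratio(
    embedding: np.ndarray,
    areas: np.ndarray,
    ref_area: str,
    near_area: str,
    far_area: str,
) -> float:
    """dist(ref, far) / dist(ref, near) of area centroids in the embedding.

    A ratio of R means the reference area's centroid sits R times closer to
    ``near_area`` than to ``far_area``.
    """
    emb = np.asarray(embedding, dtype=float)
    areas = np.asarray(areas)
    cents = {}
    for a in (ref_area, near_area, far_area):
        idx = areas == a
        if idx.sum() < 2:
            raise ValueError(f"area {a!r} has fewer than 2 units in the embedding")
        cents[a] = emb[idx].mean(axis=0)
    d_near = np.linalg.norm(cents[ref_area] - cents[near_area])
    d_far = np.linalg.norm(cents[ref_area] - cents[far_area])
    return float(d_far / d_near)


def subsampled_centroid_ratio(
    profiles: np.ndarray,
    areas: np.ndarray,
    ref_area: str,
    near_area: str,
    far_area: str,
    n_iter: int = 50,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Centroid-distance ratio under subsampling to the smallest area's size,
    re-running the PCA -> 2D embedding each iteration; returns mean and CI."""
    areas = np.asarray(areas)
    rng = np.random.default_rng(seed)
    n_min = min(np.sum(areas == a) for a in np.unique(areas))
    ratios = []
    for _ in range(n_iter):
        keep = np.concatenate(
            [
                rng.choice(np.flatnonzero(areas == a), n_min, replace=False)
                if np.sum(areas == a) > n_min
                else np.flatnonzero(areas == a)
                for a in np.unique(areas)
            ]
        )
        ca = shape_embed_cluster(np.asarray(profiles)[keep], seed=int(rng.integers(2**31)))
        ratios.append(
            centroid_distance_ratio(ca.embedding_2d, areas[keep], ref_area, near_area, far_area)
        )
    lo, hi = np.quantile(ratios, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return {"mean": float(np.mean(ratios)), "ci_low": float(lo), "ci_high": float(hi),
            "ratios": np.asarray(ratios)}
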