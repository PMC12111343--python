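"""K-means co-expression clustering of regulated miRNAs on group-mean profiles.

Features significant in at least one comparison are clustered on their
row-z-scored group-mean profiles with best-of-restarts Lloyd's algorithm
(k-means++ initialization).  The cluster count is chosen at the elbow of the
SSE-vs-k curve (maximum discrete second difference), overridable by the
caller.  Cluster *core* members are those whose profile correlates with
their centroid above a threshold (Pearson r > 0.8 over the group axis).
The SSE curve is guaranteed non-increasing: in addition to the k-means++
restarts, each k is warm-started from the previous solution's centroids
plus a split at the worst-fit point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

from .core_data import ExpressionMatrix, SampleDesign

__all__ = [
    "ClusterModel",
    "select_clustering_features",
    "group_mean_profile",
    "zscore_rows",
    "sse_curve",
    "choose_k_elbow",
    "kmeans_cluster",
    "extract_core",
    "heatmap_export",
    "pca_scores",
]


@dataclass
class ClusterModel:
    k: int
    centroids: pd.DataFrame              # k x groups
    assignments: dict[str, int]          # feature -> cluster id (0-based)
    sse: float
    seed: int
    n_init: int
    core: dict[int, list[tuple[str, float]]] | None = None
    core_r_threshold: float | None = None


def select_clustering_features(de_tables: dict[str, pd.DataFrame]) -> list[str]:
    """Union of features with status up/down in any DE table, order-stable."""
    seen: set[str] = set()
    out: list[str] = []
    for tbl in de_tables.values():
        sig = tbl.index[tbl["status"].isin(["up", "down"])]
        for f in sig:
            if f not in seen:
                seen.add(f)
                out.append(f)
    return out


def group_mean_profile(
    m: ExpressionMatrix, design: SampleDesign, features: list[str]
) -> pd.DataFrame:
    """Arithmetic per-group means (log2 scale), features x groups."""
    sub = m.subset_features(features)
    frame = sub.to_frame()
    cols = {}
    for g in design.group_order:
        cols[g] = frame[design.samples_of(g)].mean(axis=1)
    return pd.DataFrame(cols)


def zscore_rows(profiles: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0, population sd 1; constant rows become zeros."""
    if profiles.shape[1] < 2:
        raise ValueError("row z-scoring needs at least 2 columns")
    x = profiles.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population sd
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s) z-scored to zeros")
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd_safe
    z[constant] = 0.0
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)


def _fit_kmeans(x: np.ndarray, k: int, seed: int, n_init: int, init=None) -> KMeans:
    if init is None:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    else:
        km = KMeans(n_clusters=k, n_init=1, init=init, random_state=seed)
    return km.fit(x)


def sse_curve(
    profiles: pd.DataFrame, k_max: int, seed: int, n_init: int = 25
) -> list[tuple[int, float]]:
    """Best-of-restarts within-cluster SSE for k = 1..k_max (non-increasing)."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x = profiles.to_numpy(dtype=float)
    if k_max > x.shape[0]:
        raise ValueError(f"k_max {k_max} exceeds feature count {x.shape[0]}")
    curve: list[tuple[int, float]] = []
    prev_fit: KMeans | None = None
    for k in range(1, k_max + 1):
        fit = _fit_kmeans(x, k, seed, n_init)
        if prev_fit is not None:
            # warm start: previous centroids plus a split at the worst-fit point,
            # which makes best-of SSE provably non-increasing in k
            d2 = ((x - prev_fit.cluster_centers_[prev_fit.labels_]) ** 2).sum(axis=1)
            split = x[int(np.argmax(d2))]
            init = np.vstack([prev_fit.cluster_centers_, split[None, :]])
            warm = _fit_kmeans(x, k, seed, 1, init=init)
            if warm.inertia_ < fit.inertia_:
                fit = warm
        curve.append((k, float(fit.inertia_)))
        prev_fit = fit
    return curve


def choose_k_elbow(curve: list[tuple[int, float]]) -> tuple[int, pd.DataFrame]:
    """Pick k at the maximum discrete second difference of the SSE curve.

    Returns (k, diagnostics); ties resolve to the smallest k, and a flat /
    strictly linear curve warns ("no clear elbow") and returns the smallest
    interior k.  The diagnostic table lets a user override the choice.
    """
    if len(curve) < 3:
        raise ValueError("elbow selection needs an SSE curve of length >= 3")
    ks = [k for k, _ in curve]
    sse = np.array([s for _, s in curve], dtype=float)
    second = sse[:-2] - 2 * sse[1:-1] + sse[2:]
    diag = pd.DataFrame({"k": ks[1:-1], "sse": sse[1:-1], "second_difference": second})
    scale = max(sse[0], 1.0)
    if np.all(np.abs(second) <= 1e-9 * scale):
        warnings.warn("no clear elbow: SSE curve is (near-)linear in k")
        return ks[1], diag
    best = int(np.argmax(second))  # ties -> smallest k via argmax first-occurrence
    return ks[1 + best], diag


def kmeans_cluster(
    profiles: pd.DataFrame, k: int, seed: int, n_init: int = 25
) -> ClusterModel:
    """Best-of-n_init Lloyd's clustering; deterministic given the seed."""
    x = profiles.to_numpy(dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.shape[0]:
        raise ValueError(f"k {k} exceeds feature count {x.shape[0]}")
    fit = _fit_kmeans(x, k, seed, n_init)
    centroids = pd.DataFrame(fit.cluster_centers_, columns=profiles.columns)
    centroids.index.name = "cluster"
    assignments = {f: int(c) for f, c in zip(profiles.index, fit.labels_)}
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        sse=float(fit.inertia_),
        seed=seed,
        n_init=n_init,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def extract_core(
    model: ClusterModel, profiles: pd.DataFrame, r_threshold: float = 0.8
) -> ClusterModel:
    """Fill ``model.core`` with members correlating r > r_threshold (strict)
    with their own centroid over the group axis; constant rows are excluded
    with a warning."""
    core: dict[int, list[tuple[str, float]]] = {c: [] for c in range(model.k)}
    n_constant = 0
    for f in profiles.index:
        c = model.assignments[f]
        r = _pearson(profiles.loc[f].to_numpy(), model.centroids.loc[c].to_numpy())
        if np.isnan(r):
            n_constant += 1
            continue
        if r > r_threshold:
            core[c].append((f, r))
    if n_constant:
        warnings.warn(f"{n_constant} constant profile(s) excluded from core extraction")
    model.core = core
    model.core_r_threshold = r_threshold
    return model


def heatmap_export(
    m: ExpressionMatrix,
    design: SampleDesign,
    model: ClusterModel,
    de_tables: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Three aligned panels over core members: row-scaled group means,
    row-scaled per-sample expression, per-comparison log2 fold changes.

    Rows are ordered by cluster, then by average-linkage (Euclidean)
    hierarchical leaf order within the cluster.
    """
    if model.core is None:
        raise ValueError("extract_core must run before heatmap export")
    ordered: list[str] = []
    means_all = group_mean_profile(m, design, [f for c in sorted(model.core) for f, _ in model.core[c]]) if any(model.core.values()) else None
    for c in sorted(model.core):
        members = [f for f, _ in model.core[c]]
        if not members:
            continue
        if len(members) > 2:
            sub = zscore_rows(means_all.loc[members])
            order = leaves_list(linkage(sub.to_numpy(), method="average", metric="euclidean"))
            members = [members[i] for i in order]
        ordered.extend(members)
    if not ordered:
        empty = pd.DataFrame()
        return empty, empty.copy(), empty.copy()
    mean_panel = zscore_rows(group_mean_profile(m, design, ordered))
    sample_panel = zscore_rows(m.subset_features(ordered).to_frame())
    fc = {name: tbl["log2fc"].reindex(ordered) for name, tbl in de_tables.items()}
    fc_panel = pd.DataFrame(fc, index=pd.Index(ordered, name="feature"))
    return mean_panel, sample_panel, fc_panel


def pca_scores(m: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the first two principal components.

    Feature-wise centered covariance PCA via SVD; per component, the
    largest-magnitude feature loading is made positive.  Returns
    (scores DataFrame indexed by sample with PC1/PC2, explained-variance
    fractions for the two components).
    """
    if m.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = m.values - m.values.mean(axis=1, keepdims=True)  # center features
    # samples are observations: SVD of x.T = U S Vt, loadings in Vt rows
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    n_comp = min(2, len(s))
    for i in range(n_comp):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u[:, :n_comp] * s[:n_comp]
    total = float((s**2).sum())
    explained = (s[:n_comp] ** 2) / total if total > 0 else np.zeros(n_comp)
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return pd.DataFrame(scores, index=pd.Index(m.sample_ids, name="sample"), columns=cols), explained
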