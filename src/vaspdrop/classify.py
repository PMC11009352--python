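"""Unsupervised shape taxonomy of actin networks.

Pipeline: per-snapshot order parameters → z-scored ensemble matrix →
correlation-matrix PCA → varimax rotation of the retained loadings →
K-means on the leading component scores → representative snapshots and
rule-based cluster naming (ring / shell / shells with weak or strong
bundling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .analysis import COLUMNS, order_params
from .geometry import TriangulatedSurface

__all__ = [
    "EnsembleMatrix",
    "ClusterResult",
    "assemble_ensemble",
    "ensemble_from_params",
    "pca_varimax",
    "kmeans_partition",
    "name_clusters",
    "varimax",
]


@dataclass
class EnsembleMatrix:
    """Snapshot ensemble in order-parameter space.

    ``raw`` holds the unstandardized order parameters (one row per
    snapshot, plus any tag columns); ``X`` the z-scored matrix over the
    retained columns."""

    raw: pd.DataFrame
    X: np.ndarray
    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.X)


def ensemble_from_params(df: pd.DataFrame) -> EnsembleMatrix:
    """Standardize an order-parameter table (columns area_fraction, f1..f4;
    extra columns are carried as tags).  Constant columns are dropped with
    a warning."""
    cols = [c for c in COLUMNS if c in df.columns]
    mat = df[cols].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("missing values in the ensemble matrix")
    sd = mat.std(axis=0, ddof=1) if len(mat) > 1 else np.zeros(mat.shape[1])
    keep = sd > 0
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant order-parameter columns: {dropped}")
    cols = [c for c, k in zip(cols, keep) if k]
    mat = mat[:, keep]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    X = (mat - mean) / sd if mat.shape[1] else mat
    return EnsembleMatrix(raw=df.reset_index(drop=True), X=X, columns=cols,
                          mean=mean, sd=sd, dropped=dropped)


def assemble_ensemble(
    trajectories,
    window_fraction: float = 0.05,
    tags: list[dict] | None = None,
    surf: TriangulatedSurface | None = None,
) -> EnsembleMatrix:
    """Order parameters over the final ``window_fraction`` of each
    trajectory (a list of Snapshot sequences), z-scored per column.

    With the study's 600-snapshot trajectories and the default 5% window,
    each trajectory contributes 30 rows."""
    rows = []
    for j, traj in enumerate(trajectories):
        if len(traj) < 1.0 / window_fraction:
            raise ValueError(
                f"trajectory {j} has {len(traj)} snapshots; need >= {1/window_fraction:.0f}"
            )
        n_take = max(1, int(round(window_fraction * len(traj))))
        for k, snap in enumerate(traj[-n_take:]):
            op = order_params(snap, surf)
            row = {
                "trajectory": j,
                "snapshot": len(traj) - n_take + k,
                "time": snap.time,
                **dict(zip(COLUMNS, op.as_array())),
            }
            if tags is not None:
                row.update(tags[j])
            rows.append(row)
    return ensemble_from_params(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# PCA + varimax


def varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Orthogonal rotation matrix maximizing the (raw) varimax criterion —
    the summed variance of squared loadings per rotated column."""
    p, k = loadings.shape
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return R


@dataclass
class ClusterResult:
    """PCA / varimax / K-means outputs for one ensemble."""

    scores: np.ndarray  # (n, n_components)
    variance_explained: np.ndarray  # percent, all PCs, non-increasing
    loadings: np.ndarray  # unrotated, (p, n_components)
    rotated_loadings: np.ndarray  # varimax-rotated
    rotation: np.ndarray  # orthogonal (n_components, n_components)
    columns: list[str]
    labels: np.ndarray | None = None
    centroids: np.ndarray | None = None
    representatives: np.ndarray | None = None
    names: dict | None = None
    inertia: float | None = None


def pca_varimax(m: EnsembleMatrix, n_components: int = 3) -> ClusterResult:
    """Correlation-matrix PCA with varimax-rotated loadings.

    Eigen-decomposes the column correlation matrix of the z-scored data;
    scores are projections on the top ``n_components`` eigenvectors;
    loadings (eigvec·sqrt(eigval)) are varimax-rotated; signs are fixed so
    each loading column's largest-magnitude entry is positive."""
    n, p = m.X.shape
    if n <= p:
        raise ValueError("need more snapshots than order parameters")
    n_components = min(n_components, p)
    corr = m.X.T @ m.X / (n - 1)
    lam, vec = np.linalg.eigh(corr)
    order = np.argsort(lam)[::-1]
    lam, vec = np.clip(lam[order], 0, None), vec[:, order]
    var_pct = lam / lam.sum() * 100.0
    V = vec[:, :n_components]
    loadings = V * np.sqrt(lam[:n_components])
    R = varimax(loadings)
    rotated = loadings @ R
    # sign convention
    signs = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(rotated.shape[1])])
    signs[signs == 0] = 1.0
    rotated = rotated * signs
    score_signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(n_components)])
    score_signs[score_signs == 0] = 1.0
    V = V * score_signs
    scores = m.X @ V
    return ClusterResult(
        scores=scores,
        variance_explained=var_pct,
        loadings=V * np.sqrt(lam[:n_components]),
        rotated_loadings=rotated,
        rotation=R,
        columns=list(m.columns),
    )


def kmeans_partition(
    scores: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Best-of-n_init K-means (k-means++ starts) on the PC scores.

    Returns (labels, centroids, representative row indices, inertia); the
    representative of a cluster is the row closest to its centroid, ties
    broken by lowest row index."""
    if k < 1 or len(scores) < k:
        raise ValueError("need k >= 1 and at least k rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, tol=1e-6, max_iter=500)
    labels = km.fit_predict(scores)
    centroids = km.cluster_centers_
    reps = np.empty(k, dtype=int)
    for c in range(k):
        idx = np.nonzero(labels == c)[0]
        d = np.linalg.norm(scores[idx] - centroids[c], axis=1)
        reps[c] = idx[np.argmin(d)]  # argmin returns first minimum: lowest index
    return labels, centroids, reps, float(km.inertia_)


def silhouette_scan(scores: np.ndarray, k_range=range(2, 8), seed: int = 0,
                    n_init: int = 50) -> pd.DataFrame:
    """Mean silhouette coefficient for each candidate k.

    Diagnostic only — the pipeline never selects k automatically; k is
    fixed per experiment (4 for the kinetic sweep, 3 for the
    filament-number study)."""
    from sklearn.metrics import silhouette_score

    rows = []
    for k in k_range:
        if k >= len(scores):
            break
        labels, _, _, _ = kmeans_partition(scores, k, seed=seed, n_init=n_init)
        rows.append({"k": k, "silhouette": silhouette_score(scores, labels)})
    return pd.DataFrame(rows)


def classify_ensemble(m: EnsembleMatrix, k: int = 4, n_components: int = 3,
                      seed: int = 0, n_init: int = 50) -> ClusterResult:
    """Full pipeline: PCA + varimax + K-means + naming."""
    res = pca_varimax(m, n_components=n_components)
    labels, centroids, reps, inertia = kmeans_partition(res.scores, k, seed, n_init)
    res.labels, res.centroids, res.representatives, res.inertia = (
        labels, centroids, reps, inertia)
    res.names = name_clusters(res, m)
    return res


def name_clusters(result: ClusterResult, ensemble: EnsembleMatrix) -> dict:
    """Heuristic names from cluster-mean RAW order parameters.

    ring — lowest area fraction with high bundling (f3+f4); shell —
    highest unbound fraction f0 among the rest; remaining clusters split
    into strongly vs weakly bundled shells by f3+f4.  On a rule collision
    clusters are named by bundling rank with a warning."""
    if result.labels is None:
        raise ValueError("clusters not computed")
    k = int(result.labels.max()) + 1
    df = ensemble.raw
    stats = []
    for c in range(k):
        sub = df[result.labels == c]
        stats.append(
            {
                "area": float(sub["area_fraction"].mean()),
                "f0": float(1.0 - sub[["f1", "f2", "f3", "f4"]].sum(axis=1).mean()),
                "f34": float((sub["f3"] + sub["f4"]).mean()),
            }
        )
    names = {}
    if k == 1:
        s = stats[0]
        names[0] = "ring" if s["area"] < 0.5 and s["f34"] > 0.3 else "shell"
        return names
    order_area = np.argsort([s["area"] for s in stats])
    ring = int(order_area[0])
    f34_all = [s["f34"] for s in stats]
    if stats[ring]["f34"] < np.median(f34_all):
        warnings.warn("rule collision: lowest-area cluster is not strongly "
                      "bundled; naming clusters by bundling rank")
        rank = np.argsort(f34_all)[::-1]
        return {int(c): f"cluster-{i+1} (bundling rank)" for i, c in enumerate(rank)}
    names[ring] = "ring"
    rest = [c for c in range(k) if c != ring]
    shell = max(rest, key=lambda c: stats[c]["f0"])
    names[shell] = "shell"
    rest = [c for c in rest if c != shell]
    rest_sorted = sorted(rest, key=lambda c: stats[c]["f34"], reverse=True)
    tiers = ["shell (strong bundling)", "shell (weak bundling)"]
    for i, c in enumerate(rest_sorted):
        names[c] = tiers[i] if i < 2 else f"shell (bundling rank {i+1})"
    return names
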