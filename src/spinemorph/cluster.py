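"""K-Means clustering of spines in PC space.

Cluster count is selected by agreement of three scores over a candidate
range (default 3..11): the silhouette score (argmax), the Calinski-Harabasz
score (argmax), and the elbow of the inertia curve (knee = point of maximum
perpendicular distance to the chord joining the first and last inertia
values). Fitted clusters are relabeled by ascending centroid PC1 so that
cluster identities are stable across runs and row permutations.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

__all__ = [
    "ClusterModel",
    "KSelectionReport",
    "ClusterProfile",
    "ShiftMap",
    "fit_kmeans",
    "select_k",
    "profile_clusters",
    "kde_shift",
    "plot_shift_map",
]


def _as_array(scores) -> np.ndarray:
    if isinstance(scores, pd.DataFrame):
        return scores.to_numpy(dtype=float)
    return np.asarray(scores, dtype=float)


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray            # (k, d), ordered by ascending PC1
    labels: np.ndarray               # per-spine cluster id in 1..k
    inertia: float
    seed: int
    n_init: int

    def to_json(self, path=None) -> str:
        s = json.dumps({"k": self.k, "centroids": self.centroids.tolist(),
                        "inertia": self.inertia, "seed": self.seed,
                        "n_init": self.n_init}, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    def predict(self, scores) -> np.ndarray:
        x = _as_array(scores)
        d = ((x[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1) + 1


@dataclass
class KSelectionReport:
    k_range: list[int]
    inertia: dict[int, float]
    silhouette: dict[int, float]
    calinski_harabasz: dict[int, float]
    recommended: dict[str, int]      # per score + 'consensus'

    def to_json(self, path=None) -> str:
        s = json.dumps({
            "k_range": self.k_range,
            "inertia": self.inertia,
            "silhouette": self.silhouette,
            "calinski_harabasz": self.calinski_harabasz,
            "recommended": self.recommended}, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def fit_kmeans(scores, k: int, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """k-means++ with ``n_init`` restarts, relabeled by ascending centroid PC1."""
    x = _as_array(scores)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(x) <= k:
        raise ValueError(f"need more than k={k} points, got {len(x)}")
    if len(np.unique(x, axis=0)) < k:
        raise ValueError("fewer distinct points than clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(x)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(1, k + 1)
    return ClusterModel(k=k, centroids=km.cluster_centers_[order].copy(),
                        labels=relabel[raw], inertia=float(km.inertia_),
                        seed=seed, n_init=n_init)


def _elbow_k(ks: np.ndarray, inertias: np.ndarray) -> int:
    """Knee = maximum perpendicular distance to the first-to-last chord."""
    p0 = np.array([ks[0], inertias[0]], dtype=float)
    p1 = np.array([ks[-1], inertias[-1]], dtype=float)
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return int(ks[0])
    pts = np.column_stack([ks, inertias]).astype(float) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    return int(ks[int(np.argmax(dist))])


def select_k(scores, k_range=range(3, 12), seed: int = 0, n_init: int = 10) -> KSelectionReport:
    """Evaluate K-Means over ``k_range`` and recommend a cluster count."""
    x = _as_array(scores)
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 2 or ks[-1] > len(x) - 1:
        raise ValueError(f"k_range must lie within [2, n-1] = [2, {len(x) - 1}]")
    if len(x) < ks[-1] + 1:
        raise ValueError("not enough points for the largest k")
    inertia, sil, ch = {}, {}, {}
    for k in ks:
        model = fit_kmeans(x, k, seed=seed, n_init=n_init)
        inertia[k] = model.inertia
        lab = model.labels
        sil[k] = float(silhouette_score(x, lab))
        ch[k] = float(calinski_harabasz_score(x, lab))
    rec = {
        "silhouette": max(ks, key=lambda k: sil[k]),
        "calinski_harabasz": max(ks, key=lambda k: ch[k]),
        "elbow": _elbow_k(np.array(ks), np.array([inertia[k] for k in ks])),
    }
    votes = Counter(rec.values())
    top = votes.most_common()
    if len(top) == 1 or top[0][1] > top[1][1]:
        rec["consensus"] = int(top[0][0])
    else:
        rec["consensus"] = int(rec["silhouette"])    # tie -> silhouette winner
    return KSelectionReport(k_range=ks, inertia=inertia, silhouette=sil,
                            calinski_harabasz=ch, recommended=rec)


@dataclass
class ClusterProfile:
    sizes: dict[int, int]
    table: pd.DataFrame              # rows: cluster; columns: <col>_mean, <col>_sd

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def profile_clusters(model: ClusterModel, features: pd.DataFrame,
                     scores: pd.DataFrame | None = None) -> ClusterProfile:
    """Per-cluster size and mean ± SD of each numeric feature and PC."""
    if len(features) != len(model.labels):
        raise ValueError("feature rows do not align with cluster labels")
    df = features.copy()
    if scores is not None:
        if len(scores) != len(model.labels):
            raise ValueError("score rows do not align with cluster labels")
        for c in scores.columns:
            df[c] = np.asarray(scores[c])
    num = df.select_dtypes(include=[np.number]).copy()
    num["cluster"] = model.labels
    g = num.groupby("cluster")
    means = g.mean().add_suffix("_mean")
    sds = g.std(ddof=1).add_suffix("_sd")
    table = pd.concat([means, sds], axis=1).sort_index(axis=1)
    sizes = {int(c): int(n) for c, n in num["cluster"].value_counts().items()}
    return ClusterProfile(sizes=sizes, table=table)


@dataclass
class ShiftMap:
    cluster_id: int
    groups: tuple[str, str]          # (reference/control, comparison/learner)
    grid_x: np.ndarray               # PC1 axis
    grid_y: np.ndarray               # PC2 axis
    density: dict[str, np.ndarray]   # group -> (ny, nx) grid, integrates to 1
    centroids: dict[str, np.ndarray]
    shift: np.ndarray                # comparison centroid − reference centroid

    def to_json(self, path=None) -> str:
        s = json.dumps({
            "cluster_id": self.cluster_id,
            "groups": list(self.groups),
            "grid_x": self.grid_x.tolist(), "grid_y": self.grid_y.tolist(),
            "density": {g: d.tolist() for g, d in self.density.items()},
            "centroids": {g: c.tolist() for g, c in self.centroids.items()},
            "shift": self.shift.tolist()})
        if path is not None:
            Path(path).write_text(s)
        return s


def kde_shift(scores, labels, groups, cluster_id: int,
              group_pair: tuple[str, str] | None = None,
              grid_size: int = 100, min_members: int = 10) -> ShiftMap:
    """Per-group Gaussian KDE of a cluster's members in (PC1, PC2).

    Uses Scott's bandwidth on a ``grid_size``² grid spanning the pooled data
    range ± 3 bandwidths; each grid is renormalized to integrate to 1 over
    the grid. The shift vector is the difference of the member centroids
    (second group minus first).
    """
    x = _as_array(scores)[:, :2]
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if group_pair is None:
        uniq = list(dict.fromkeys(groups))
        if len(uniq) != 2:
            raise ValueError("group_pair must be given when there are not exactly 2 groups")
        group_pair = (uniq[0], uniq[1])
    members = {g: x[(labels == cluster_id) & (groups == g)] for g in group_pair}
    for g, pts in members.items():
        if len(pts) < min_members:
            raise ValueError(f"group {g!r} has {len(pts)} spines in cluster {cluster_id}; "
                             f"need >= {min_members}")
    pooled = np.vstack(list(members.values()))
    kdes = {g: gaussian_kde(pts.T, bw_method="scott") for g, pts in members.items()}
    bw = max(float(np.sqrt(k.covariance[i, i])) for k in kdes.values() for i in (0, 1))
    lo = pooled.min(axis=0) - 3 * bw
    hi = pooled.max(axis=0) + 3 * bw
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(gx, gy)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    density = {}
    for g, k in kdes.items():
        z = k(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
        density[g] = z / (z.sum() * cell)
    centroids = {g: pts.mean(axis=0) for g, pts in members.items()}
    shift = centroids[group_pair[1]] - centroids[group_pair[0]]
    return ShiftMap(cluster_id=cluster_id, groups=group_pair, grid_x=gx, grid_y=gy,
                    density=density, centroids=centroids, shift=shift)


def plot_shift_map(shift_map: ShiftMap, ax=None, cmaps=("Blues", "Reds")):
    """Contour plot of both group densities with the centroid-shift arrow."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (g, dens), cmap in zip(shift_map.density.items(), cmaps):
        ax.contour(shift_map.grid_x, shift_map.grid_y, dens, levels=5, cmap=cmap)
    c0 = shift_map.centroids[shift_map.groups[0]]
    ax.annotate("", xy=tuple(c0 + shift_map.shift), xytext=tuple(c0),
                arrowprops=dict(color="red", arrowstyle="->", lw=2))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(f"cluster {shift_map.cluster_id}: {shift_map.groups[0]} → {shift_map.groups[1]}")
    return ax
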