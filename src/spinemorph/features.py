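"""Correlation pruning, standardization and PCA of the spine feature table.

The ten raw features are heavily redundant (length-like and size-like
features correlate above 0.9), so pairs correlated at |r| >= 0.9 are pruned,
keeping the conventional feature of each redundant group. The default
priority keeps Length over Average Distance and Surface over Volume / Hull
Volume, yielding the working set {L, S, HR, CVD, OA}. The retained features
are standardized (zero mean, unit population SD) and reduced to three
principal components fitted on the pooled multi-condition dataset; group
comparisons happen downstream in this shared PC space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .morphometry import FEATURE_NAMES

__all__ = [
    "ScalerParams",
    "PCAModel",
    "PruneResult",
    "DEFAULT_PRIORITY",
    "correlation_prune",
    "standardize",
    "apply_scaler",
    "fit_pca",
    "transform_pca",
]

#: preference order when pruning correlated features: widely used descriptors first
DEFAULT_PRIORITY = ("L", "S", "HR", "CVD", "OA", "AD", "V", "HV", "MC", "GC")


@dataclass
class PruneResult:
    matrix: pd.DataFrame
    kept: list[str]
    dropped: dict[str, str]          # dropped feature -> kept feature it correlated with
    correlation: pd.DataFrame


@dataclass
class ScalerParams:
    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray                  # population SD (ddof=0)

    def to_json(self, path=None) -> str:
        s = json.dumps({"feature_names": list(self.feature_names),
                        "mean": self.mean.tolist(), "std": self.std.tolist()}, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, text: str) -> "ScalerParams":
        d = json.loads(text)
        return cls(d["feature_names"], np.asarray(d["mean"]), np.asarray(d["std"]))


@dataclass
class PCAModel:
    feature_names: list[str]
    loadings: np.ndarray             # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray                 # feature means removed before projection

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[0])

    def to_json(self, path=None) -> str:
        s = json.dumps({
            "feature_names": list(self.feature_names),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "mean": self.mean.tolist()}, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, text: str) -> "PCAModel":
        d = json.loads(text)
        return cls(d["feature_names"], np.asarray(d["loadings"]),
                   np.asarray(d["explained_variance_ratio"]), np.asarray(d["mean"]))


def _feature_columns(matrix: pd.DataFrame) -> list[str]:
    numeric = [c for c in matrix.columns if c in FEATURE_NAMES]
    if numeric:
        return numeric
    return [c for c in matrix.columns
            if pd.api.types.is_numeric_dtype(matrix[c])]


def correlation_prune(matrix: pd.DataFrame, threshold: float = 0.9,
                      priority=DEFAULT_PRIORITY) -> PruneResult:
    """Drop features pairwise-correlated at |r| >= threshold.

    Features are visited in ``priority`` order (then by column order for any
    not listed); a feature is kept unless it correlates at or above the
    threshold with an already-kept feature. Row order cannot influence the
    result because Pearson correlation is permutation-invariant.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cols = _feature_columns(matrix)
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    data = matrix[cols].astype(float)
    for c in cols:
        if data[c].std(ddof=0) == 0:
            raise ValueError(f"constant column {c!r}: correlation undefined")
    corr = data.corr(method="pearson")
    order = [f for f in priority if f in cols] + [c for c in cols if c not in priority]
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for f in order:
        partner = next((k for k in kept if abs(corr.loc[f, k]) >= threshold), None)
        if partner is None:
            kept.append(f)
        else:
            dropped[f] = partner
    kept_in_order = [c for c in cols if c in kept]
    meta = [c for c in matrix.columns if c not in cols]
    return PruneResult(matrix=matrix[meta + kept_in_order].copy(),
                       kept=kept_in_order, dropped=dropped, correlation=corr)


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, ScalerParams]:
    """Scale feature columns to zero mean and unit population SD."""
    cols = _feature_columns(matrix)
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to standardize")
    x = matrix[cols].to_numpy(dtype=float)
    scaler = StandardScaler()
    z = scaler.fit_transform(x)
    if np.any(scaler.scale_ == 1.0) and np.any(x.std(axis=0) == 0):
        bad = [c for c, s in zip(cols, x.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance column(s) {bad}: cannot standardize")
    out = matrix.copy()
    out[cols] = z
    return out, ScalerParams(feature_names=cols, mean=scaler.mean_.copy(),
                             std=scaler.scale_.copy())


def apply_scaler(matrix: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    out = matrix.copy()
    x = matrix[params.feature_names].to_numpy(dtype=float)
    out[params.feature_names] = (x - params.mean) / params.std
    return out


def fit_pca(matrix: pd.DataFrame, n_components: int = 3) -> tuple[PCAModel, pd.DataFrame]:
    """Fit PCA on (standardized) feature columns; scores indexed like the input.

    The sign of each component is fixed by making its largest-magnitude
    loading positive, so refits on permuted rows are reproducible.
    """
    cols = _feature_columns(matrix)
    if n_components > len(cols):
        raise ValueError(f"n_components={n_components} exceeds {len(cols)} features")
    x = matrix[cols].to_numpy(dtype=float)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    loadings = pca.components_.copy()
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    model = PCAModel(feature_names=cols, loadings=loadings,
                     explained_variance_ratio=pca.explained_variance_ratio_.copy(),
                     mean=pca.mean_.copy())
    score_df = pd.DataFrame(scores, index=matrix.index,
                            columns=[f"PC{i + 1}" for i in range(n_components)])
    return model, score_df


def transform_pca(matrix: pd.DataFrame, model: PCAModel) -> pd.DataFrame:
    x = matrix[model.feature_names].to_numpy(dtype=float) - model.mean
    scores = x @ model.loadings.T
    return pd.DataFrame(scores, index=matrix.index,
                        columns=[f"PC{i + 1}" for i in range(model.n_components)])
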