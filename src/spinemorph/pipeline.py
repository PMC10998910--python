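"""End-to-end orchestration: segment → mesh → repair → features → prune →
scale → PCA → cluster → group statistics, with a reproducible run manifest.

Each stage is runnable on its own (see :mod:`spinemorph.cli`); this module
wires them together for a full run from a config mapping and writes every
artifact with provenance (config hash, seed) so re-runs with the same config
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import features as _features
from . import stats as _stats
from .morphometry import FEATURE_NAMES, compute_features
from .mesh import load_mesh, repair_mesh

log = logging.getLogger("spinemorph")

__all__ = ["PipelineConfig", "run_pipeline", "measure_meshes",
           "cluster_features", "compare_groups", "write_report"]

_UNITS = {"L": "um", "S": "um^2", "V": "um^3", "HV": "um^3", "HR": "",
          "AD": "um", "CVD": "", "OA": "rad", "MC": "1/um", "GC": "1/um^2"}


@dataclass
class PipelineConfig:
    out_dir: str
    mesh_dir: str | None = None          # directory of pre-cut spine meshes
    features_csv: str | None = None      # or start from an existing feature table
    group_column: str = "group"
    threshold: float = 0.9
    priority: tuple = _features.DEFAULT_PRIORITY
    n_components: int = 3
    k: int | None = 5
    k_range: tuple[int, int] = (3, 11)
    use_pca: bool = True
    seed: int = 0
    icc_grouping: str = "mouse"

    def validate(self) -> None:
        if self.mesh_dir is None and self.features_csv is None:
            raise ValueError("config needs mesh_dir or features_csv")
        for p in (self.mesh_dir, self.features_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def hash(self) -> str:
        payload = json.dumps({k: str(v) for k, v in vars(self).items()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def measure_meshes(mesh_dir, pattern: str = "*.ply", repair: bool = True) -> pd.DataFrame:
    """Load, repair and measure every mesh in a directory."""
    rows = []
    paths = sorted(Path(mesh_dir).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no meshes matching {pattern!r} in {mesh_dir}")
    for p in paths:
        mesh = load_mesh(p)
        if repair:
            mesh, _ = repair_mesh(mesh)
        feats = compute_features(mesh).as_dict()
        rows.append(dict(spine_id=p.stem, **feats))
        log.debug("measured %s", p.name)
    return pd.DataFrame(rows)


def cluster_features(features: pd.DataFrame, config: PipelineConfig):
    """Prune → scale → (PCA) → select k if unset → K-Means."""
    prune = _features.correlation_prune(features, threshold=config.threshold,
                                        priority=config.priority)
    scaled, scaler = _features.standardize(prune.matrix)
    if config.use_pca:
        pca_model, scores = _features.fit_pca(scaled, n_components=config.n_components)
    else:
        pca_model = None
        cols = [c for c in scaled.columns if c in prune.kept]
        scores = scaled[cols].rename(columns={c: f"PC{i + 1}" for i, c in enumerate(cols)})
    kmin, kmax = config.k_range
    report = _cluster.select_k(scores, range(kmin, kmax + 1), seed=config.seed)
    k = config.k if config.k is not None else report.recommended["consensus"]
    model = _cluster.fit_kmeans(scores, k, seed=config.seed)
    return prune, scaler, pca_model, scores, report, model


def compare_groups(features: pd.DataFrame, labels: np.ndarray, k: int,
                   group_column: str = "group") -> dict:
    """Per-feature t/p/d and per-cluster proportion tests between two groups."""
    groups = features[group_column].to_numpy()
    uniq = list(dict.fromkeys(groups))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, found {uniq}")
    ga, gb = uniq
    out = {"groups": [str(ga), str(gb)], "features": {}, "clusters": {}}
    feat_cols = [c for c in features.columns if c in FEATURE_NAMES]
    for c in feat_cols:
        a = features.loc[groups == ga, c].to_numpy(dtype=float)
        b = features.loc[groups == gb, c].to_numpy(dtype=float)
        t, p = _stats.ttest_unpaired(a, b)
        d = _stats.cohens_d(a, b)
        out["features"][c] = {"t": t, "p": p, "d": d.cohens_d,
                              "effect": d.interpretation, "units": _UNITS.get(c, "")}
    res = _stats.compare_cluster_distributions(labels[groups == ga],
                                               labels[groups == gb], k)
    for c, r in res.items():
        out["clusters"][str(c)] = {
            "prop_a": r.p_tilde_1, "prop_b": r.p_tilde_2, "z": r.z,
            "p": r.p_two_sided, "ci95": list(r.ci95)}
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    manifest = {"config_hash": chash, "seed": config.seed, "outputs": {}}

    if config.features_csv is not None:
        features = pd.read_csv(config.features_csv)
    else:
        features = measure_meshes(config.mesh_dir)
    feats_path = out_dir / "features.csv"
    features.to_csv(feats_path, index=False)
    (out_dir / "features_units.json").write_text(json.dumps(_UNITS, indent=2))
    manifest["outputs"]["features"] = str(feats_path)

    prune, scaler, pca_model, scores, report, model = cluster_features(features, config)
    clustered = features.copy()
    clustered["cluster"] = model.labels
    for c in scores.columns:
        clustered[c] = np.asarray(scores[c])
    clusters_path = out_dir / "clusters.csv"
    clustered.to_csv(clusters_path, index=False)
    model_doc = json.loads(model.to_json())
    model_doc.update({"config_hash": chash, "kept_features": prune.kept,
                      "dropped_features": prune.dropped})
    if pca_model is not None:
        model_doc["pca"] = json.loads(pca_model.to_json())
        model_doc["scaler"] = json.loads(scaler.to_json())
    (out_dir / "model.json").write_text(json.dumps(model_doc, indent=2))
    report.to_json(out_dir / "k_selection.json")
    manifest["outputs"].update({"clusters": str(clusters_path),
                                "model": str(out_dir / "model.json"),
                                "k_selection": str(out_dir / "k_selection.json")})

    results = {"config_hash": chash, "seed": config.seed,
               "k_selection": json.loads(report.to_json()),
               "cluster_sizes": _cluster.profile_clusters(model, features, scores).sizes}
    if config.group_column in features.columns \
            and features[config.group_column].nunique() == 2:
        results["group_comparison"] = compare_groups(
            features, model.labels, model.k, config.group_column)
    report_paths = write_report(results, out_dir)
    manifest["outputs"].update(report_paths)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_report(results: dict, out_dir) -> dict:
    """Write the JSON report plus a human-readable text summary.

    Sections absent from ``results`` are written as explicit
    ``missing`` markers rather than silently dropped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(results, indent=2, default=str))

    lines = ["spinemorph run report", "=" * 21,
             f"config hash: {results.get('config_hash', 'missing')}",
             f"seed: {results.get('seed', 'missing')}", ""]
    for section in ("density", "k_selection", "cluster_sizes", "group_comparison"):
        lines.append(f"[{section}]")
        if section not in results:
            lines.append("  missing")
        elif section == "k_selection":
            rec = results[section].get("recommended", {})
            lines.append("  recommended k: " + ", ".join(f"{k}={v}" for k, v in rec.items()))
        elif section == "cluster_sizes":
            for c, n in sorted(results[section].items()):
                lines.append(f"  cluster {c}: n = {n}")
        elif section == "group_comparison":
            gc = results[section]
            lines.append(f"  groups: {gc['groups'][0]} vs {gc['groups'][1]}")
            for f, r in gc["features"].items():
                lines.append(f"  {f}: t = {r['t']:.3f}, p = {r['p']:.4g}, "
                             f"d = {r['d']:.3f} ({r['effect']})")
            for c, r in gc["clusters"].items():
                lines.append(f"  cluster {c}: {100 * r['prop_a']:.1f}% vs "
                             f"{100 * r['prop_b']:.1f}%, p = {r['p']:.4g}")
        else:
            lines.append(f"  {results[section]}")
        lines.append("")
    txt_path = out_dir / "report.txt"
    txt_path.write_text("\n".join(lines))
    return {"report_json": str(json_path), "report_txt": str(txt_path)}
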