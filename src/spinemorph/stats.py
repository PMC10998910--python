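"""Group-level statistics: densities, t-tests, effect sizes, Agresti-Caffo
two-proportion tests and the one-way intraclass correlation.

The Agresti-Caffo test compares two independent proportions after adding one
success and one failure to each group: p̃ᵢ = (xᵢ+1)/(nᵢ+2). The z statistic
of the adjusted difference is referred to the standard normal for a
two-sided p-value, and the 95% interval is diff ± 1.96·SE. The adjustment
gives well-calibrated coverage even for small or extreme counts, which is
why it is the test of choice for per-cluster spine proportions.

The ICC assesses pseudo-replication (many spines share a cell and an
animal): ICC(1) from the one-way random-effects ANOVA decomposition,
(MSB − MSW) / (MSB + (k̄−1)·MSW), with k̄ the balanced-equivalent group size
k̄ = (N − Σnᵢ²/N) / (a−1) for unbalanced designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DensityRecord",
    "ProportionTestResult",
    "EffectSize",
    "ICCResult",
    "spine_density",
    "density_summary",
    "ttest_unpaired",
    "cohens_d",
    "agresti_caffo",
    "compare_cluster_distributions",
    "icc_oneway",
    "holm_correction",
]


@dataclass(frozen=True)
class DensityRecord:
    cell_id: str
    mouse_id: str
    group: str
    spine_count: int
    dendrite_length: float           # µm

    @property
    def density(self) -> float:
        return spine_density(self.spine_count, self.dendrite_length)


@dataclass(frozen=True)
class ProportionTestResult:
    p_tilde_1: float
    p_tilde_2: float
    diff: float
    se: float
    z: float
    p_two_sided: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class EffectSize:
    cohens_d: float
    interpretation: str


@dataclass(frozen=True)
class ICCResult:
    icc: float
    grouping: str
    model: str = "one-way random effects (ICC1)"


def spine_density(spine_count: int, dendrite_length: float) -> float:
    """Spines per µm of dendrite."""
    if dendrite_length <= 0:
        raise ValueError("dendrite_length must be > 0")
    if spine_count < 0:
        raise ValueError("spine_count must be >= 0")
    return spine_count / dendrite_length


def density_summary(records) -> pd.DataFrame:
    """Per-group mean ± SD density with cell and mouse counts."""
    rows = [dict(group=r.group, mouse_id=r.mouse_id, density=r.density) for r in records]
    df = pd.DataFrame(rows)
    g = df.groupby("group")
    out = pd.DataFrame({
        "mean_density": g["density"].mean(),
        "sd_density": g["density"].std(ddof=1),
        "n_cells": g.size(),
        "n_mice": g["mouse_id"].nunique(),
    })
    return out


def ttest_unpaired(a, b) -> tuple[float, float]:
    """Classical pooled-variance two-sample Student t-test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


_D_BANDS = ((0.01, "very small"), (0.20, "small"), (0.50, "medium"),
            (0.80, "large"), (1.20, "very large"))


def cohens_d(a, b) -> EffectSize:
    """Standardized mean difference with n−1-weighted pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    d = (a.mean() - b.mean()) / pooled
    label = "huge"
    for cut, name in _D_BANDS:
        if abs(d) < cut:
            label = name
            break
    return EffectSize(cohens_d=float(d), interpretation=label)


def agresti_caffo(x1: int, n1: int, x2: int, n2: int) -> ProportionTestResult:
    """Adjusted two-proportion z test (add one success and one failure per group)."""
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("each group needs at least one trial")
        if not 0 <= x <= n:
            raise ValueError(f"successes {x} outside [0, {n}]")
    p1 = (x1 + 1) / (n1 + 2)
    p2 = (x2 + 1) / (n2 + 2)
    se = float(np.sqrt(p1 * (1 - p1) / (n1 + 2) + p2 * (1 - p2) / (n2 + 2)))
    if se == 0:
        raise ValueError("zero standard error: test undefined")
    diff = p1 - p2
    z = diff / se
    p = float(2 * sps.norm.sf(abs(z)))
    return ProportionTestResult(p_tilde_1=p1, p_tilde_2=p2, diff=diff, se=se,
                                z=float(z), p_two_sided=p,
                                ci95=(diff - 1.96 * se, diff + 1.96 * se))


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def compare_cluster_distributions(labels_a, labels_b, k: int,
                                  holm: bool = False) -> dict[int, ProportionTestResult]:
    """Per-cluster Agresti-Caffo comparison of cluster membership proportions.

    Raw per-cluster p-values by default; pass ``holm=True`` for a Holm
    step-down correction across the k tests.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if len(labels_a) == 0 or len(labels_b) == 0:
        raise ValueError("both groups must be non-empty")
    for lab in (labels_a, labels_b):
        if lab.min() < 1 or lab.max() > k:
            raise ValueError(f"labels must lie in 1..{k}")
    na, nb = len(labels_a), len(labels_b)
    results = {c: agresti_caffo(int((labels_a == c).sum()), na,
                                int((labels_b == c).sum()), nb)
               for c in range(1, k + 1)}
    if holm:
        adj = holm_correction([results[c].p_two_sided for c in range(1, k + 1)])
        results = {c: ProportionTestResult(
            p_tilde_1=r.p_tilde_1, p_tilde_2=r.p_tilde_2, diff=r.diff, se=r.se,
            z=r.z, p_two_sided=float(adj[c - 1]), ci95=r.ci95)
            for c, r in results.items()}
    return results


def icc_oneway(values, group_ids, grouping: str = "mouse") -> ICCResult:
    """One-way random-effects intraclass correlation ICC(1)."""
    values = np.asarray(values, dtype=float)
    group_ids = np.asarray(group_ids)
    uniq = pd.unique(group_ids)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([(group_ids == g).sum() for g in uniq])
    if ns.max() < 2:
        raise ValueError("need at least 2 observations in at least one group")
    N, a = len(values), len(uniq)
    grand = values.mean()
    means = np.array([values[group_ids == g].mean() for g in uniq])
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((values[group_ids == g] - m) ** 2).sum()
                    for g, m in zip(uniq, means)))
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    kbar = (N - (ns ** 2).sum() / N) / (a - 1)
    icc = (msb - msw) / (msb + (kbar - 1) * msw)
    return ICCResult(icc=float(icc), grouping=grouping)
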