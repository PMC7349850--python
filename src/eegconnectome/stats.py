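"""Group-level inference: one-way ANOVA, pooled t, Bonferroni, Pearson tests.

The inferential layer mirrors the standard neurophysiology reporting style:
a one-way ANOVA across the four diagnostic groups per metric and scope,
followed — only when the omnibus test is significant — by pairwise
independent-sample t-tests with pooled variance (identified by the reported
degrees of freedom ``n_a + n_b - 2``), interpreted against a Bonferroni
level of ``alpha / 6`` for the six pairwise contrasts of four groups.
Metric-score associations use the Pearson correlation with the exact
t-distributed null, uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, DegenerateVarianceError


@dataclass
class PairwiseResult:
    groups: tuple[str, str]
    t: float
    df: int
    p: float


@dataclass
class GroupComparison:
    metric: str
    scope: str
    F: float
    df_between: int
    df_within: int
    p_anova: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    bonferroni_level: float = 0.05 / 6


def one_way_anova(samples: Mapping[str, Sequence[float]]) -> tuple[float, int, int, float]:
    """F statistic, (df_between, df_within) and upper-tail p."""
    groups = {g: np.asarray(v, float) for g, v in samples.items()}
    if len(groups) < 2:
        raise ConfigError("ANOVA needs at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ConfigError(f"group {g!r} needs at least 2 values")
        if not np.isfinite(v).all():
            raise ConfigError(f"group {g!r} contains non-finite values")
    k = len(groups)
    n_total = sum(v.size for v in groups.values())
    grand = np.concatenate(list(groups.values())).mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, df_b, df_w, 1.0
        raise DegenerateVarianceError(
            "zero within-group variance with unequal group means"
        )
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def pooled_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Two-sample Student t with pooled variance; two-tailed p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ConfigError("samples contain non-finite values")
    df = a.size + b.size - 2
    ssa = ((a - a.mean()) ** 2).sum()
    ssb = ((b - b.mean()) ** 2).sum()
    sp2 = (ssa + ssb) / df
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise DegenerateVarianceError("both samples constant with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), df, p


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise adjusted per-test level ``alpha / m``."""
    if m < 1:
        raise ConfigError("number of comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    return alpha / m


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and its two-tailed p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("pearson_test needs two equal-length vectors")
    n = x.size
    if n < 3:
        raise ConfigError("pearson_test needs n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx = np.sqrt(np.dot(xd, xd))
    sy = np.sqrt(np.dot(yd, yd))
    if sx == 0 or sy == 0:
        raise DegenerateVarianceError("constant vector in pearson_test")
    r = float(np.clip(np.dot(xd, yd) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    metric: str,
    scope: str,
    alpha: float = 0.05,
) -> GroupComparison:
    """Omnibus ANOVA with pairwise t-tests gated on omnibus significance."""
    f, df_b, df_w, p = one_way_anova(samples)
    n_pairs = len(list(combinations(samples, 2)))
    level = bonferroni(alpha, n_pairs)
    pairwise: list[PairwiseResult] = []
    if p < alpha:
        for ga, gb in combinations(samples, 2):
            t, df, pt = pooled_t(samples[ga], samples[gb])
            pairwise.append(PairwiseResult(groups=(ga, gb), t=t, df=df, p=pt))
    return GroupComparison(
        metric=metric, scope=scope, F=f, df_between=df_b, df_within=df_w,
        p_anova=p, pairwise=pairwise, bonferroni_level=level,
    )
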