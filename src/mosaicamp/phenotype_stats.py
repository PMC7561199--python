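"""Phenotype quantities and genotype-dose statistics.

Group summaries are mean +/- SEM (sample SD with n-1 denominator over sqrt n).
Dose-phenotype association uses the Pearson product-moment correlation.  Group
comparisons use one-way ANOVA, Dunnett's many-to-one test against a control
(family-wise adjusted by seeded Monte-Carlo sampling of the max-|t| null), and
the two-tailed unpaired Student t-test (pooled variance, not Welch).
Significance threshold alpha = 0.05 throughout unless overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float | None  # undefined for n = 1

    def __str__(self) -> str:
        if self.sem is None:
            return f"{self.mean:.1f} (n=1, SEM undefined)"
        return f"{self.mean:.1f} ± {self.sem:.1f}"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class DunnettResult:
    t_statistics: tuple[float, ...]
    adjusted_p: tuple[float, ...]
    alpha: float
    significant: tuple[bool, ...]
    n_draws: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def mean_sem(values: Sequence[float]) -> GroupSummary:
    """Mean and standard error of the mean; SEM is undefined for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    sem = None if v.size < 2 else float(v.std(ddof=1) / math.sqrt(v.size))
    return GroupSummary(n=int(v.size), mean=float(v.mean()), sem=sem)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation of paired observations (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input vector")
    r = stats.pearsonr(x, y).statistic
    return CorrelationResult(r=float(r), n=int(x.size))


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Omnibus one-way ANOVA over >= 2 groups, each with n >= 2."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups each with n >= 2")
    res = stats.f_oneway(*arrays)
    k = len(arrays)
    N = sum(a.size for a in arrays)
    return AnovaResult(
        F=float(res.statistic),
        df_between=k - 1,
        df_within=N - k,
        p=float(res.pvalue),
    )


def t_test_two_tailed(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-tailed unpaired Student t-test with pooled variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(
        t=float(res.statistic), df=int(x.size + y.size - 2), p=float(res.pvalue)
    )


def dunnett_test(
    control: Sequence[float],
    treatments: Sequence[Sequence[float]],
    alpha: float = 0.05,
    n_draws: int = 200_000,
    seed: int = 0,
) -> DunnettResult:
    """Dunnett's many-to-one comparisons against a control.

    Per-treatment t statistics use the variance pooled over all groups.  The
    family-wise adjusted p-value of treatment i is P(max_j |T_j| >= |t_i|)
    under the joint null, estimated by seeded Monte-Carlo sampling (shared
    chi-square variance draw plus correlated group-mean draws, which is what
    makes the comparisons dependent through the common control).
    """
    c = np.asarray(control, dtype=float)
    groups = [np.asarray(t, dtype=float) for t in treatments]
    if c.size < 2 or not groups or any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    N = c.size + ns.sum()
    df = int(N - (k + 1))
    ss_within = ((c - c.mean()) ** 2).sum() + sum(
        ((g - g.mean()) ** 2).sum() for g in groups
    )
    s2 = ss_within / df
    se = np.sqrt(s2 * (1.0 / ns + 1.0 / c.size))
    t_obs = np.array([g.mean() for g in groups]) - c.mean()
    t_obs /= se
    rng = np.random.default_rng(seed)
    # simulate the joint null in blocks to bound memory
    exceed = np.zeros(k, dtype=np.int64)
    block = 50_000
    done = 0
    abs_obs = np.abs(t_obs)
    while done < n_draws:
        b = min(block, n_draws - done)
        zc = rng.normal(0.0, 1.0 / math.sqrt(c.size), size=b)
        zi = rng.normal(0.0, 1.0, size=(b, k)) / np.sqrt(ns)
        s2_sim = rng.chisquare(df, size=b) / df
        t_sim = (zi - zc[:, None]) / (
            np.sqrt(s2_sim)[:, None] * np.sqrt(1.0 / ns + 1.0 / c.size)
        )
        max_abs = np.abs(t_sim).max(axis=1)
        exceed += (max_abs[:, None] >= abs_obs[None, :]).sum(axis=0)
        done += b
    adj_p = (exceed + 1) / (n_draws + 1)
    return DunnettResult(
        t_statistics=tuple(float(t) for t in t_obs),
        adjusted_p=tuple(float(p) for p in adj_p),
        alpha=alpha,
        significant=tuple(bool(p < alpha) for p in adj_p),
        n_draws=n_draws,
    )


def tubule_density(count: int, area_mm2: float) -> float:
    """Terminal tubules per mm^2 of lung section."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / area_mm2


def spc_positive_ratio(
    per_field: Sequence[tuple[int, int]],
) -> GroupSummary:
    """SPC-positive cell percentage summarized over microscope fields.

    Each field contributes 100 * positive / total; the summary is mean +/- SEM
    over fields (eight fields is the conventional design)."""
    if not per_field:
        raise ValueError("need at least one field")
    percents = []
    for positive, total in per_field:
        if total <= 0:
            raise ValueError("zero-total field")
        if not 0 <= positive <= total:
            raise ValueError("positive count outside [0, total]")
        percents.append(100.0 * positive / total)
    return mean_sem(percents)


def polyline_length(points: Sequence[tuple[float, float]]) -> float:
    """Length of a polyline through ordered 2-D points (e.g. a traced cecum):
    the sum of Euclidean segment lengths."""
    if len(points) < 2:
        raise ValueError("need >= 2 points")
    pts = np.asarray(points, dtype=float)
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())
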