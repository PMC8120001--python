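"""Group-comparison statistics with normality routing.

Cell-level measurements are aggregated to per-fish means (fish are the
independent units).  Comparisons are routed by normality: every group
must pass its normality test (D'Agostino-Pearson omnibus for n >= 8,
Shapiro-Wilk otherwise) at ``alpha_normality`` for the parametric route.
Two groups then use Student's unpaired two-tailed t-test or the
Mann-Whitney test; more than two use ordinary one-way ANOVA with Tukey's
post-test or Kruskal-Wallis with Dunn's post-test (Bonferroni-adjusted).
Proportions are compared with Fisher's exact test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """Outcome of one group comparison."""

    test_name: str
    groups: list[str]
    statistic: float | None
    p_value: float | None
    route: str  # "parametric" | "nonparametric" | "degenerate" | "exact"
    normality_pvalues: dict[str, float] = field(default_factory=dict)
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def aggregate_per_fish(measurements: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Mean of cell-level values per (group, fish).

    ``measurements`` needs columns ``group``, ``fish`` and ``value_col``;
    rows with NaN values are dropped (a fish left with no cells is
    excluded and logged).
    """
    df = measurements.copy()
    n_before = df.groupby(["group", "fish"], sort=True).size()
    df = df.dropna(subset=[value_col])
    agg = (df.groupby(["group", "fish"], sort=True)[value_col]
             .mean().reset_index())
    kept = set(map(tuple, agg[["group", "fish"]].itertuples(index=False)))
    for (group, fish) in n_before.index:
        if (group, fish) not in kept:
            logger.warning("fish %r in group %r has no cells; excluded", fish, group)
    return agg


def _normality_p(values: np.ndarray) -> float:
    """D'Agostino-Pearson for n >= 8, Shapiro-Wilk otherwise."""
    values = np.asarray(values, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(values) >= 8:
            return float(sps.normaltest(values).pvalue)
        return float(sps.shapiro(values).pvalue)


def compare_groups(grouped: Mapping[str, Sequence[float]],
                   alpha_normality: float = 0.05) -> TestResult:
    """Normality-routed comparison of two or more groups.

    Each group needs n >= 3.  If any group has zero variance the data are
    degenerate for these tests and no p-value is emitted.
    """
    names = list(grouped)
    arrays = [np.asarray(grouped[g], dtype=float) for g in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for g, a in zip(names, arrays):
        if len(a) < 3:
            raise ValueError(f"group {g!r} has n={len(a)} < 3: insufficient data")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {g!r} contains non-finite values")

    if any(np.ptp(a) == 0 for a in arrays):
        return TestResult(test_name="degenerate", groups=names, statistic=None,
                          p_value=None, route="degenerate")

    norm_p = {g: _normality_p(a) for g, a in zip(names, arrays)}
    parametric = all(p > alpha_normality for p in norm_p.values())

    if len(names) == 2:
        if parametric:
            stat, p = sps.ttest_ind(arrays[0], arrays[1])
            name = "t-test"
        else:
            stat, p = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
            name = "mann-whitney"
        return TestResult(test_name=name, groups=names, statistic=float(stat),
                          p_value=float(p),
                          route="parametric" if parametric else "nonparametric",
                          normality_pvalues=norm_p)

    if parametric:
        stat, p = sps.f_oneway(*arrays)
        tk = sps.tukey_hsd(*arrays)
        posthoc = {(names[i], names[j]): float(tk.pvalue[i, j])
                   for i, j in combinations(range(len(names)), 2)}
        name = "anova+tukey"
    else:
        stat, p = sps.kruskal(*arrays)
        posthoc = dunn_posthoc(arrays, names)
        name = "kruskal+dunn"
    return TestResult(test_name=name, groups=names, statistic=float(stat),
                      p_value=float(p),
                      route="parametric" if parametric else "nonparametric",
                      normality_pvalues=norm_p, posthoc=posthoc)


def dunn_posthoc(arrays: Sequence[np.ndarray], names: Sequence[str],
                 ) -> dict[tuple[str, str], float]:
    """Dunn's pairwise rank comparisons with Bonferroni adjustment.

    z for pair (i, j) uses pooled mid-ranks with the tie correction
    ``sum(t^3 - t) / (12 (N - 1))`` subtracted from ``N (N + 1) / 12``.
    """
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + len(a)].mean())
        start += len(a)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(arrays) * (len(arrays) - 1) // 2
    out = {}
    for i, j in combinations(range(len(arrays)), 2):
        se = np.sqrt(base_var * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(z)
        out[(names[i], names[j])] = float(min(1.0, p * m))
    return out


def compare_proportions(successes_a: int, n_a: int, successes_b: int, n_b: int) -> TestResult:
    """Two-tailed Fisher's exact test on the 2x2 table
    [[successes_a, n_a - successes_a], [successes_b, n_b - successes_b]]."""
    for s, n in ((successes_a, n_a), (successes_b, n_b)):
        if n < 1 or not 0 <= s <= n:
            raise ValueError(f"invalid counts: {s}/{n}")
    table = [[successes_a, n_a - successes_a], [successes_b, n_b - successes_b]]
    res = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(test_name="fisher-exact", groups=["a", "b"],
                      statistic=float(res.statistic), p_value=float(res.pvalue),
                      route="exact")


def significance_label(p: float | None) -> str:
    """Standard significance annotation: n.s. / * / ** / *** / ****."""
    if p is None:
        return "n.a."
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
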