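"""Reconstruction of baseline-characteristics comparisons from summary rows.

Published baseline tables report continuous rows as mean ± SD with a group
size and categorical rows as event counts. Both tests are exact functions
of those summaries:

* continuous rows — unpaired Student's t-test with pooled variance
  (sp² = ((n1−1)s1² + (n2−1)s2²)/(n1+n2−2), df = n1+n2−2), identical to a
  t-test on any raw samples having those means/SDs/sizes;
* categorical rows — Pearson chi-square without continuity correction by
  default, or Fisher's exact test; the rule is configurable, including an
  expected-count rule (chi-square only when all expected cells ≥ 5).

Rows may carry their own per-group n (missing data make row ns smaller
than the column-header n), and a multi-level categorical row is tested as
an R×2 chi-square with an exact Freeman–Halton fallback.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import ContingencyTable, fisher_two_sided

logger = logging.getLogger(__name__)

__all__ = [
    "ContinuousSummary",
    "CategoricalSummary",
    "MultiCategoricalSummary",
    "ComparisonResult",
    "BaselineRow",
    "pooled_t_from_summary",
    "categorical_test",
    "multi_categorical_test",
    "compare_baseline",
]


@dataclass(frozen=True)
class ContinuousSummary:
    """mean ± SD over n observations of one continuous row in one group."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"{self.label}: sd must be positive")
        if self.n < 2:
            raise ValueError(f"{self.label}: n must be >= 2")


@dataclass(frozen=True)
class CategoricalSummary:
    """k events out of n for one binary row in one group."""

    label: str
    k: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.label}: group size must be >= 1")
        if not 0 <= self.k <= self.n:
            raise ValueError(f"{self.label}: event count outside [0, n]")


@dataclass(frozen=True)
class MultiCategoricalSummary:
    """Counts over >= 2 ordered levels of one row in one group."""

    label: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ValueError(f"{self.label}: need >= 2 levels")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"{self.label}: negative count")
        if sum(self.counts) < 1:
            raise ValueError(f"{self.label}: empty group")

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    df: Optional[int]
    p_two_sided: float
    method: str  # pooled-t | chi-square | fisher-exact


def pooled_t_from_summary(
    g1: ContinuousSummary, g2: ContinuousSummary
) -> ComparisonResult:
    """Unpaired Student's t-test (pooled variance) from two summary rows."""
    n1, n2 = g1.n, g2.n
    if n1 + n2 < 3:
        raise ValueError("need n1 + n2 >= 3")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2) / df
    if sp2 == 0.0:
        if g1.mean == g2.mean:
            return ComparisonResult(0.0, df, 1.0, "pooled-t")
        raise ValueError("zero pooled variance with unequal means")
    t = (g1.mean - g2.mean) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(float(t), df, float(min(1.0, p)), "pooled-t")


def _chi2_2x2(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    stat, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def _expected_min(rows: Sequence[Sequence[int]]) -> float:
    obs = np.asarray(rows, dtype=float)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    return float(exp.min())


def categorical_test(
    g1: CategoricalSummary,
    g2: CategoricalSummary,
    method_rule: str = "chi-square",
) -> ComparisonResult:
    """Two-group comparison of event proportions.

    ``method_rule``:

    * ``"chi-square"`` (default) — Pearson chi-square, no continuity
      correction, regardless of expected counts;
    * ``"fisher"`` — Fisher's exact test always;
    * ``"expected-count"`` — chi-square when all expected cells are ≥ 5,
      Fisher's exact otherwise.
    """
    if method_rule == "expected-count":
        rule = (
            "chi-square"
            if _expected_min([[g1.k, g1.n - g1.k], [g2.k, g2.n - g2.k]]) >= 5.0
            else "fisher"
        )
    else:
        rule = method_rule
    if rule == "chi-square":
        if g1.k / g1.n == g2.k / g2.n:
            return ComparisonResult(0.0, 1, 1.0, "chi-square")
        stat, p = _chi2_2x2(g1.k, g1.n, g2.k, g2.n)
        return ComparisonResult(stat, 1, p, "chi-square")
    if rule == "fisher":
        p = fisher_two_sided(ContingencyTable(g1.k, g1.n, g2.k, g2.n))
        return ComparisonResult(math.nan, None, p, "fisher-exact")
    raise ValueError(f"unknown method rule {method_rule!r}")


def _freeman_halton_rx2(c1: Sequence[int], c2: Sequence[int]) -> float:
    """Exact R×2 test by enumeration of tables with the observed margins.

    Probability of a table with column counts (x_i, r_i − x_i) is
    ∏ C(r_i, x_i) / C(N, s1); the two-sided P sums the probabilities of
    all tables no more likely than the observed one. Intended for the
    small row totals of a baseline table.
    """
    r = [a + b for a, b in zip(c1, c2)]
    s1 = sum(c1)
    log_denom = (
        math.lgamma(sum(r) + 1) - math.lgamma(s1 + 1) - math.lgamma(sum(r) - s1 + 1)
    )

    def log_prob(xs: Sequence[int]) -> float:
        lp = -log_denom
        for ri, xi in zip(r, xs):
            lp += math.lgamma(ri + 1) - math.lgamma(xi + 1) - math.lgamma(ri - xi + 1)
        return lp

    lp_obs = log_prob(c1)
    total = 0.0
    extreme = 0.0
    ranges = [range(ri + 1) for ri in r[:-1]]
    for head in product(*ranges):
        tail = s1 - sum(head)
        if not 0 <= tail <= r[-1]:
            continue
        lp = log_prob([*head, tail])
        p = math.exp(lp)
        total += p
        if lp <= lp_obs + 1e-9:
            extreme += p
    return min(1.0, extreme / total)


def multi_categorical_test(
    g1: MultiCategoricalSummary,
    g2: MultiCategoricalSummary,
    method_rule: str = "chi-square",
) -> ComparisonResult:
    """R×2 comparison of a multi-level categorical row between two groups."""
    if len(g1.counts) != len(g2.counts):
        raise ValueError("groups must share the category levels")
    obs = np.array([g1.counts, g2.counts], dtype=float).T  # levels × groups
    if method_rule == "expected-count":
        rule = "chi-square" if _expected_min(obs) >= 5.0 else "fisher"
    else:
        rule = method_rule
    if rule == "chi-square":
        stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
        return ComparisonResult(float(stat), int(df), float(p), "chi-square")
    if rule == "fisher":
        p = _freeman_halton_rx2(g1.counts, g2.counts)
        return ComparisonResult(math.nan, None, p, "fisher-exact")
    raise ValueError(f"unknown method rule {method_rule!r}")


Summary = Union[ContinuousSummary, CategoricalSummary, MultiCategoricalSummary]


@dataclass
class BaselineRow:
    """One baseline-table row: its kind and the per-group summaries."""

    label: str
    kind: str  # continuous | categorical | multi-categorical
    groups: dict[str, Summary]

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical", "multi-categorical"):
            raise ValueError(f"unknown row kind {self.kind!r}")


def compare_baseline(
    rows: Sequence[BaselineRow],
    group_pairs: Sequence[tuple[str, str]],
    method_rule: str = "chi-square",
) -> pd.DataFrame:
    """One comparison per (row, group pair), in a baseline-table-shaped frame.

    Rows missing a summary for a requested group are skipped for that pair
    with a logged warning. Returns columns: label, kind, group1, group2,
    statistic, df, p, method.
    """
    records = []
    for row in rows:
        for gname1, gname2 in group_pairs:
            if gname1 not in row.groups or gname2 not in row.groups:
                logger.warning(
                    "row %r: missing summary for pair (%s, %s); skipped",
                    row.label, gname1, gname2,
                )
                continue
            g1, g2 = row.groups[gname1], row.groups[gname2]
            if row.kind == "continuous":
                res = pooled_t_from_summary(g1, g2)
            elif row.kind == "categorical":
                res = categorical_test(g1, g2, method_rule=method_rule)
            else:
                res = multi_categorical_test(g1, g2, method_rule=method_rule)
            records.append(
                {
                    "label": row.label,
                    "kind": row.kind,
                    "group1": gname1,
                    "group2": gname2,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p_two_sided,
                    "method": res.method,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["label", "kind", "group1", "group2", "statistic", "df", "p", "method"],
    )
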