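"""Exact 2×2 burden inference on carrier counts.

The collapsing burden test compares the proportion of qualifying-variant
carriers between cases (a / n1) and controls (b / n2). Conditioning on all
margins of the 2×2 table, the case-carrier count follows a hypergeometric
distribution under the null and a Fisher noncentral hypergeometric
distribution with odds parameter ψ (the conditional odds ratio) otherwise.
This module provides:

* ``fisher_two_sided`` — the exact two-sided P-value under the
  minimum-likelihood summation rule (sum of the probabilities of all
  tables no more likely than the observed one);
* ``odds_ratio_sample`` — the cross-product estimate a(n2−b)/((n1−a)b);
* ``odds_ratio_cmle`` — the conditional maximum-likelihood estimate,
  the ψ at which the noncentral-hypergeometric mean equals the observed
  count;
* ``odds_ratio_ci`` — exact-conditional (tail-inversion) or log-Woolf
  confidence intervals;
* ``burden_test`` / ``meta_pool`` / ``calibration_synonymous`` — the
  assembled per-class test, naive count pooling across cohorts, and the
  synonymous-variant negative-control check.

All quantities are pure functions of the four counts; P-values are kept at
full double precision (rounding belongs to the report layer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

__all__ = [
    "ContingencyTable",
    "BurdenResult",
    "CalibrationResult",
    "fisher_two_sided",
    "odds_ratio_sample",
    "odds_ratio_cmle",
    "odds_ratio_ci",
    "burden_test",
    "meta_pool",
    "calibration_synonymous",
]

# relative tolerance when comparing table probabilities in the two-sided
# summation rule; guards against ties lost to floating-point rounding
_P_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Carriers / totals in cases vs controls: a/n1 vs b/n2."""

    a: int
    n1: int
    b: int
    n2: int

    def __post_init__(self) -> None:
        for name in ("a", "n1", "b", "n2"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("group totals must be positive")
        if not 0 <= self.a <= self.n1:
            raise ValueError(f"case carriers {self.a} outside [0, {self.n1}]")
        if not 0 <= self.b <= self.n2:
            raise ValueError(f"control carriers {self.b} outside [0, {self.n2}]")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(a, n1−a, b, n2−b)."""
        return (self.a, self.n1 - self.a, self.b, self.n2 - self.b)

    def swapped_groups(self) -> "ContingencyTable":
        return ContingencyTable(self.b, self.n2, self.a, self.n1)


def _support_and_logpmf(table: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric support and null log-pmf for the case-carrier count."""
    n1, n2, k = table.n1, table.n2, table.a + table.b
    lo = max(0, k - n2)
    hi = min(k, n1)
    x = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(n1 + 1) - gammaln(x + 1) - gammaln(n1 - x + 1)
        + gammaln(n2 + 1) - gammaln(k - x + 1) - gammaln(n2 - k + x + 1)
        - (gammaln(n1 + n2 + 1) - gammaln(k + 1) - gammaln(n1 + n2 - k + 1))
    )
    return x, logpmf


def fisher_two_sided(table: ContingencyTable) -> float:
    """Two-sided exact P by the minimum-likelihood summation rule.

    All hypergeometric outcomes whose point probability does not exceed
    that of the observed table (up to a small relative tolerance) are
    summed. Deterministic; matches the convention of mainstream
    statistical software.
    """
    x, logpmf = _support_and_logpmf(table)
    pmf = np.exp(logpmf - logpmf.max())
    p_obs = pmf[np.searchsorted(x, table.a)]
    p = pmf[pmf <= p_obs * (1.0 + _P_REL_TOL)].sum() / pmf.sum()
    return float(min(1.0, p))


def odds_ratio_sample(table: ContingencyTable) -> float:
    """Cross-product odds-ratio estimate a·(n2−b) / ((n1−a)·b).

    Returns ``inf`` when the control carrier cell (or the case
    non-carrier cell) is empty but cases carry, ``0.0`` in the mirrored
    situation, and ``nan`` for the degenerate all-zero-carrier table.
    """
    a, c, b, d = table.cells
    if a == 0 and b == 0:
        return math.nan
    num, den = a * d, c * b
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def _nchg_logweights(table: ContingencyTable, log_psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised log-weights of the Fisher noncentral hypergeometric."""
    n1, n2, k = table.n1, table.n2, table.a + table.b
    lo = max(0, k - n2)
    hi = min(k, n1)
    x = np.arange(lo, hi + 1)
    logw = (
        gammaln(n1 + 1) - gammaln(x + 1) - gammaln(n1 - x + 1)
        + gammaln(n2 + 1) - gammaln(k - x + 1) - gammaln(n2 - k + x + 1)
        + x * log_psi
    )
    return x, logw


def _nchg_tail(table: ContingencyTable, log_psi: float, upper: bool) -> float:
    """P(X >= a | psi) if upper else P(X <= a | psi), X the case-carrier count."""
    x, logw = _nchg_logweights(table, log_psi)
    mask = x >= table.a if upper else x <= table.a
    return float(np.exp(logsumexp(logw[mask]) - logsumexp(logw)))


def _nchg_mean(table: ContingencyTable, log_psi: float) -> float:
    x, logw = _nchg_logweights(table, log_psi)
    w = np.exp(logw - logw.max())
    return float((x * w).sum() / w.sum())


def _solve_log_psi(f, lo: float = -40.0, hi: float = 40.0) -> float:
    """Root of a monotone function of log-ψ, expanding the bracket as needed."""
    flo, fhi = f(lo), f(hi)
    tries = 0
    while flo * fhi > 0 and tries < 5:
        lo, hi = lo * 2, hi * 2
        flo, fhi = f(lo), f(hi)
        tries += 1
    if flo * fhi > 0:
        raise ArithmeticError("failed to bracket the root in log-odds space")
    return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)


def odds_ratio_cmle(table: ContingencyTable) -> float:
    """Conditional maximum-likelihood odds ratio.

    The ψ maximising the Fisher noncentral hypergeometric likelihood with
    all margins fixed, i.e. the ψ at which the conditional mean equals the
    observed case-carrier count. 0 and ``inf`` at the support boundaries.
    """
    x, _ = _support_and_logpmf(table)
    if table.a == x[0]:
        return 0.0 if table.a + table.b > 0 else math.nan
    if table.a == x[-1]:
        return math.inf
    return math.exp(_solve_log_psi(lambda lp: _nchg_mean(table, lp) - table.a))


def odds_ratio_ci(
    table: ContingencyTable,
    level: float = 0.95,
    method: str = "exact-conditional",
) -> tuple[float, float]:
    """Confidence interval for the odds ratio.

    ``exact-conditional`` inverts the one-sided tails of the Fisher
    noncentral hypergeometric distribution by monotone root-finding: the
    bounds are the ψ values at which P(X ≥ a) and P(X ≤ a) equal
    (1−level)/2. At the support boundaries the corresponding bound is 0 or
    ``inf`` (a one-sided interval). ``log-woolf`` is
    exp(log OR ± z·sqrt(1/a + 1/(n1−a) + 1/b + 1/(n2−b))) and requires all
    four cells positive.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1): {level}")
    alpha = (1.0 - level) / 2.0
    if method == "exact-conditional":
        x, _ = _support_and_logpmf(table)
        if table.a == x[0]:
            low = 0.0
        else:
            low = math.exp(
                _solve_log_psi(lambda lp: _nchg_tail(table, lp, upper=True) - alpha)
            )
        if table.a == x[-1]:
            high = math.inf
        else:
            high = math.exp(
                _solve_log_psi(lambda lp: _nchg_tail(table, lp, upper=False) - alpha)
            )
        return low, high
    if method == "log-woolf":
        a, c, b, d = table.cells
        if min(a, c, b, d) == 0:
            raise ValueError("log-woolf interval requires all cells positive")
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha)
        log_or = math.log(a * d / (c * b))
        se = math.sqrt(1 / a + 1 / c + 1 / b + 1 / d)
        return math.exp(log_or - z * se), math.exp(log_or + z * se)
    raise ValueError(f"unknown CI method {method!r}")


@dataclass
class BurdenResult:
    """Exact burden test result for one qualifying class."""

    table: ContingencyTable
    p_two_sided: float
    or_sample: float
    ci_low: float
    ci_high: float
    class_label: str = ""
    ci_level: float = 0.95
    ci_method: str = "exact-conditional"
    or_cmle: Optional[float] = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = {
            "class_label": self.class_label,
            "case_carriers": self.table.a,
            "n_cases": self.table.n1,
            "ctrl_carriers": self.table.b,
            "n_controls": self.table.n2,
            "p_two_sided": self.p_two_sided,
            "or_sample": self.or_sample,
            "or_cmle": self.or_cmle,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
            "degenerate": self.degenerate,
        }
        return d


def burden_test(
    case_carriers: int,
    n_cases: int,
    ctrl_carriers: int,
    n_ctrls: int,
    class_label: str = "",
    level: float = 0.95,
    ci_method: str = "exact-conditional",
    include_cmle: bool = True,
) -> BurdenResult:
    """Assemble the full exact burden result from the four counts."""
    table = ContingencyTable(case_carriers, n_cases, ctrl_carriers, n_ctrls)
    p = fisher_two_sided(table)
    or_s = odds_ratio_sample(table)
    degenerate = math.isnan(or_s)
    ci = odds_ratio_ci(table, level=level, method=ci_method)
    cmle = odds_ratio_cmle(table) if include_cmle else None
    return BurdenResult(
        table=table,
        p_two_sided=p,
        or_sample=or_s,
        ci_low=ci[0],
        ci_high=ci[1],
        class_label=class_label,
        ci_level=level,
        ci_method=ci_method,
        or_cmle=cmle,
        degenerate=degenerate,
    )


def meta_pool(
    cohorts: Sequence[tuple[int, int]],
    sample_id_sets: Optional[Sequence[Iterable[str]]] = None,
) -> tuple[int, int]:
    """Naive pooling across cohorts: carriers and totals are summed.

    Matches published pooled counts that are exact sums of the per-cohort
    counts. When per-cohort sample identifier sets are supplied, any
    overlap between cohorts raises (pooling would double-count).
    """
    if not cohorts:
        raise ValueError("meta_pool needs at least one cohort")
    for carriers, total in cohorts:
        if total <= 0 or not 0 <= carriers <= total:
            raise ValueError(f"invalid cohort counts ({carriers}, {total})")
    if sample_id_sets is not None:
        seen: set[str] = set()
        for ids in sample_id_sets:
            ids = set(ids)
            overlap = seen & ids
            if overlap:
                raise ValueError(
                    f"cohorts share sample identifiers: {sorted(overlap)[:5]}"
                )
            seen |= ids
    carriers = sum(c for c, _ in cohorts)
    total = sum(t for _, t in cohorts)
    return carriers, total


@dataclass
class CalibrationResult:
    """Synonymous-variant negative-control verdict."""

    burden: BurdenResult
    calibrated: bool
    threshold: float = 0.05


def calibration_synonymous(
    case_syn_carriers: int,
    n_cases: int,
    ctrl_syn_carriers: int,
    n_ctrls: int,
    threshold: float = 0.05,
    **kwargs,
) -> CalibrationResult:
    """Burden test on synonymous carriers with a comparability verdict.

    Synonymous variants are not expected to differ between cases and
    controls; a non-significant synonymous burden (P ≥ ``threshold``)
    indicates the cohorts are comparable and the significant classes are
    unlikely to reflect systematic case-control bias.
    """
    result = burden_test(
        case_syn_carriers, n_cases, ctrl_syn_carriers, n_ctrls,
        class_label="synonymous", **kwargs,
    )
    return CalibrationResult(
        burden=result,
        calibrated=result.p_two_sided >= threshold,
        threshold=threshold,
    )
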