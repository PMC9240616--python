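"""Synthetic case/control cohorts with the structure the burden test assumes.

The generator emulates a gene-level collapsing analysis: per consequence
class it plants a handful of rare sites (allele frequencies from a heavy-
tailed spectrum truncated to the rare range, REVEL/VEST3 scores from a
two-component score model) and makes each individual a carrier of the
class by a Bernoulli draw — controls at the baseline carrier probability
p0, cases at the probability whose odds are the baseline odds scaled by
the class enrichment odds ratio θ:

    p1 = θ·p0 / (1 − p0 + θ·p0)

Carriers are then attached to concrete sites uniformly. Enrichment is
injected at the carrier level because the collapsing statistic only sees
carrier status; per-site realism (LD, haplotypes, recurrence patterns) is
deliberately absent.

Default parameters are the study conditions of the motivating analysis:
793 cases vs 4,523 reference controls; control carrier probabilities from
the observed control counts (truncating 4/4523, missense 46/4523,
synonymous 15/4523); enrichment odds ratios from the observed study-cohort
cross-products (≈5.73, ≈3.17, 1.0 — synonymous variants are the null
class); 3/22/6 sites per class with 3 of the 22 missense sites deleterious.

Determinism: one master seed expands to per-stage child seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))`` with fixed stage
indices (0 sites, 1 carriers, 2 clinical, 3 replicates), so stages can be
re-run independently and results are identical across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clinical import (
    BaselineRow,
    CategoricalSummary,
    ContinuousSummary,
)
from .filtering import FilterConfig, select_qualifying
from .stats import BurdenResult, burden_test
from .variants import VariantRecord

_STAGE_SITES, _STAGE_CARRIERS, _STAGE_CLINICAL, _STAGE_REPLICATES = 0, 1, 2, 3

_CLASS_TOKENS = {
    "truncating": ("stop_gained", "frameshift insertion", "splice_donor_variant"),
    "missense": ("missense_variant",),
    "synonymous": ("synonymous SNV",),
}
_BASES = ("A", "C", "G", "T")


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Child generator for one pipeline stage of one master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class ClassModel:
    """Carrier model for one consequence class."""

    p0: float  # control carrier probability
    odds_ratio: float  # case enrichment θ (1.0 = null)
    n_sites: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 out of [0,1]: {self.p0}")
        if self.odds_ratio <= 0:
            raise ValueError(f"odds ratio must be positive: {self.odds_ratio}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")

    @property
    def p1(self) -> float:
        """Case carrier probability: odds scaled by the enrichment OR."""
        p = self.odds_ratio * self.p0 / (1.0 - self.p0 + self.odds_ratio * self.p0)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"case carrier probability outside [0,1]: {p}")
        return p


@dataclass(frozen=True)
class AFSpectrum:
    """Rare-tail allele-frequency model: Beta(alpha, beta) scaled to (0, scale).

    ``frac_common`` of sites instead get one subpopulation frequency at or
    above the rarity threshold, for exercising the filter.
    """

    alpha: float = 0.5
    beta: float = 1.0
    scale: float = 1e-4
    frac_common: float = 0.0
    common_max: float = 1e-2

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.scale <= 0:
            raise ValueError("spectrum parameters must be positive")
        if not 0.0 <= self.frac_common <= 1.0:
            raise ValueError("frac_common out of [0,1]")


@dataclass(frozen=True)
class ScoreModel:
    """Two-component REVEL/VEST3 model for missense sites.

    A ``deleterious_fraction`` of missense sites draw both scores from the
    high range, the rest from the low range; the ranges straddle any
    threshold choice in between, so deleterious calls do not hinge on the
    exact cutoff.
    """

    deleterious_fraction: float = 3 / 22
    high: tuple[float, float] = (0.75, 0.98)
    low: tuple[float, float] = (0.02, 0.35)

    def __post_init__(self) -> None:
        if not 0.0 <= self.deleterious_fraction <= 1.0:
            raise ValueError("deleterious_fraction out of [0,1]")


def _default_classes() -> dict[str, ClassModel]:
    return {
        "truncating": ClassModel(p0=4 / 4523, odds_ratio=5.73, n_sites=3),
        "missense": ClassModel(p0=46 / 4523, odds_ratio=3.17, n_sites=22),
        "synonymous": ClassModel(p0=15 / 4523, odds_ratio=1.0, n_sites=6),
    }


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic case/control cohort."""

    n_cases: int = 793
    n_controls: int = 4523
    classes: dict[str, ClassModel] = field(default_factory=_default_classes)
    gene: str = "GENE1"
    chrom: str = "15"
    transcript: str = "TX000001.1"
    subpops: tuple[str, ...] = ("EAS", "NFE", "AFR")
    af_spectrum: AFSpectrum = AFSpectrum()
    score_model: ScoreModel = ScoreModel()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be positive")
        if not self.classes:
            raise ValueError("at least one class model is required")
        for model in self.classes.values():
            model.p1  # validates the odds transformation


@dataclass
class SyntheticCohort:
    """Roster, variant records with carriers, and the generating parameters."""

    cases: list[str]
    controls: list[str]
    variants: list[VariantRecord]
    config: SimConfig

    @property
    def roster(self) -> list[str]:
        return self.cases + self.controls

    def carrier_counts(
        self, class_label: str, filter_config: Optional[FilterConfig] = None
    ) -> tuple[int, int]:
        """(case carriers, control carriers) of one qualifying class."""
        qs = select_qualifying(
            self.variants, self.config.gene, class_label, filter_config
        )
        ids = qs.carrier_ids
        case_set = set(self.cases)
        a = len(ids & case_set)
        return a, len(ids) - a


def simulate_sites(config: SimConfig) -> list[VariantRecord]:
    """Generate per-class variant sites (no carriers yet); seed-deterministic."""
    rng = stage_rng(config.seed, _STAGE_SITES)
    spectrum = config.af_spectrum
    records: list[VariantRecord] = []
    pos = 1000
    for label in sorted(config.classes):
        tokens = _CLASS_TOKENS[label]
        n_sites = config.classes[label].n_sites
        for i in range(n_sites):
            pos += int(rng.integers(50, 500))
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            afs = {
                pop: float(rng.beta(spectrum.alpha, spectrum.beta) * spectrum.scale)
                for pop in config.subpops
            }
            if spectrum.frac_common > 0 and rng.random() < spectrum.frac_common:
                pop = config.subpops[int(rng.integers(len(config.subpops)))]
                afs[pop] = float(
                    rng.uniform(spectrum.scale, spectrum.common_max)
                )
            revel = vest3 = None
            if label == "missense":
                lo, hi = (
                    config.score_model.high
                    if rng.random() < config.score_model.deleterious_fraction
                    else config.score_model.low
                )
                revel = float(rng.uniform(lo, hi))
                vest3 = float(rng.uniform(lo, hi))
            records.append(
                VariantRecord(
                    chrom=config.chrom,
                    pos=pos,
                    ref=str(ref),
                    alt=str(alt),
                    gene=config.gene,
                    transcript=config.transcript,
                    raw_consequence=tokens[i % len(tokens)],
                    subpop_af=afs,
                    revel=revel,
                    vest3=vest3,
                )
            )
    return records


def simulate_carriers(
    sites: Sequence[VariantRecord], config: SimConfig
) -> SyntheticCohort:
    """Draw carrier status per individual and attach carriers to sites."""
    rng = stage_rng(config.seed, _STAGE_CARRIERS)
    cases = [f"case{i:05d}" for i in range(config.n_cases)]
    controls = [f"ctrl{i:05d}" for i in range(config.n_controls)]
    site_carriers: dict[int, set[str]] = {i: set() for i in range(len(sites))}
    class_sites = {
        label: [i for i, s in enumerate(sites)
                if s.consequence_class.value == _class_value(label)]
        for label in config.classes
    }
    for label in sorted(config.classes):
        model = config.classes[label]
        idx = class_sites[label]
        if not idx:
            raise ValueError(f"no sites available for class {label!r}")
        for roster, p in ((cases, model.p1), (controls, model.p0)):
            flags = rng.random(len(roster)) < p
            carriers = np.nonzero(flags)[0]
            assigned = rng.integers(0, len(idx), size=len(carriers))
            for sample_i, site_j in zip(carriers, assigned):
                site_carriers[idx[site_j]].add(roster[sample_i])
    variants = [
        replace(site, carrier_ids=frozenset(site_carriers[i]))
        for i, site in enumerate(sites)
    ]
    return SyntheticCohort(cases=cases, controls=controls, variants=variants,
                           config=config)


def _class_value(label: str) -> str:
    return {"truncating": "truncating", "missense": "missense",
            "synonymous": "synonymous"}[label]


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Convenience: sites then carriers under one config."""
    return simulate_carriers(simulate_sites(config), config)


def simulate_tables(
    p0: float,
    odds_ratio: float,
    n_cases: int,
    n_controls: int,
    n_tables: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Carrier-count 2×2 tables drawn directly from the carrier model.

    Marginally identical to collapsing a full simulated cohort; used for
    large calibration/coverage runs. Returns an (n_tables, 2) array of
    (case carriers, control carriers).
    """
    model = ClassModel(p0=p0, odds_ratio=odds_ratio, n_sites=1)
    a = rng.binomial(n_cases, model.p1, size=n_tables)
    b = rng.binomial(n_controls, p0, size=n_tables)
    return np.column_stack([a, b])


# ---------------------------------------------------------------------------
# clinical fixtures


@dataclass
class ClinicalFixture:
    """Baseline-table rows plus the raw samples that generated them."""

    rows: list[BaselineRow]
    raw: dict[tuple[str, str], np.ndarray]


def simulate_clinical(
    group_params: Sequence[tuple[str, str, dict]],
    seed: int = 0,
) -> ClinicalFixture:
    """Draw a baseline-table fixture from per-row group parameters.

    ``group_params`` rows are ``(label, kind, params_by_group)`` with
    ``(mean, sd, n)`` per group for continuous rows and ``(prob, n)`` for
    categorical rows. Continuous summaries are the sample mean and SD of
    the drawn values, so summary-based and raw-based tests must agree.
    """
    rng = stage_rng(seed, _STAGE_CLINICAL)
    rows: list[BaselineRow] = []
    raw: dict[tuple[str, str], np.ndarray] = {}
    for label, kind, params in group_params:
        groups: dict = {}
        for gname in sorted(params):
            if kind == "continuous":
                mean, sd, n = params[gname]
                if sd <= 0:
                    raise ValueError(f"{label}/{gname}: sd must be positive")
                sample = rng.normal(mean, sd, size=int(n))
                raw[(label, gname)] = sample
                groups[gname] = ContinuousSummary(
                    label, float(sample.mean()), float(sample.std(ddof=1)),
                    int(n),
                )
            elif kind == "categorical":
                prob, n = params[gname]
                k = int(rng.binomial(int(n), float(prob)))
                events = np.zeros(int(n), dtype=int)
                events[:k] = 1
                raw[(label, gname)] = events
                groups[gname] = CategoricalSummary(label, k, int(n))
            else:
                raise ValueError(f"unknown row kind {kind!r}")
        rows.append(BaselineRow(label=label, kind=kind, groups=groups))
    return ClinicalFixture(rows=rows, raw=raw)


# ---------------------------------------------------------------------------
# parameter recovery


def recovery_experiment(
    config: SimConfig,
    n_replicates: int,
    alpha: float = 0.05,
    filter_config: Optional[FilterConfig] = None,
    level: float = 0.95,
) -> "RecoveryReport":
    """Simulate → filter → collapse → test, repeatedly; report recovery.

    Per replicate and class: realized counts, exact P, sample OR and
    exact-conditional CI. The aggregate reports, per class, the mean
    estimated log-OR against the generating value, the empirical coverage
    of the CI, and the rejection rate at ``alpha`` (the type-I error rate
    when the generating odds ratio is 1).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    master = np.random.SeedSequence(config.seed, spawn_key=(_STAGE_REPLICATES,))
    child_seeds = master.generate_state(n_replicates) >> 1  # keep below 2**31
    records = []
    for r in range(n_replicates):
        rep_config = replace(config, seed=int(child_seeds[r]))
        cohort = simulate_cohort(rep_config)
        for label, model in sorted(config.classes.items()):
            a, b = cohort.carrier_counts(label, filter_config)
            res = burden_test(
                a, config.n_cases, b, config.n_controls,
                class_label=label, level=level, include_cmle=False,
            )
            theta = model.odds_ratio
            records.append(
                {
                    "replicate": r,
                    "class_label": label,
                    "case_carriers": a,
                    "ctrl_carriers": b,
                    "p": res.p_two_sided,
                    "or_sample": res.or_sample,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "true_or": theta,
                    "covered": bool(res.ci_low <= theta <= res.ci_high),
                    "rejected": bool(res.p_two_sided < alpha),
                }
            )
    replicates = pd.DataFrame.from_records(records)
    summary = (
        replicates.groupby("class_label")
        .apply(_summarise_class, include_groups=False)
        .reset_index()
    )
    return RecoveryReport(replicates=replicates, summary=summary, alpha=alpha)


def _summarise_class(g: pd.DataFrame) -> pd.Series:
    finite = g["or_sample"].replace([np.inf, -np.inf], np.nan).dropna()
    finite = finite[finite > 0]
    return pd.Series(
        {
            "true_or": g["true_or"].iloc[0],
            "n_replicates": len(g),
            "mean_log_or": float(np.log(finite).mean()) if len(finite) else math.nan,
            "true_log_or": float(np.log(g["true_or"].iloc[0])),
            "ci_coverage": float(g["covered"].mean()),
            "rejection_rate": float(g["rejected"].mean()),
        }
    )


@dataclass
class RecoveryReport:
    replicates: pd.DataFrame
    summary: pd.DataFrame
    alpha: float
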