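"""Qualifying-variant selection and carrier collapsing.

A variant *qualifies* for a burden class when it is rare — allele frequency
strictly below the MAF threshold in **every** reference subpopulation — and
belongs to the requested consequence class. The ``deleterious_missense``
class additionally requires both REVEL and VEST3 at or above their
thresholds (a conjunction, to limit false positives). Inframe indels and
OTHER consequences never qualify.

Collapsing is at the individual level: a carrier is a sample with at least
one alternate allele at at least one qualifying variant, counted once no
matter how many qualifying variants it carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .variants import ConsequenceClass, VariantRecord

#: burden / calibration classes recognised by :func:`select_qualifying`
CLASS_LABELS = ("truncating", "missense", "deleterious_missense", "synonymous")

_CLASS_TO_CONSEQUENCE = {
    "truncating": ConsequenceClass.TRUNCATING,
    "missense": ConsequenceClass.MISSENSE,
    "deleterious_missense": ConsequenceClass.MISSENSE,
    "synonymous": ConsequenceClass.SYNONYMOUS,
}


class UsageError(ValueError):
    """An operation was applied to an argument it is not defined for."""


@dataclass
class FilterConfig:
    """Thresholds and missing-data policies for qualifying-variant selection.

    Parameters
    ----------
    maf_threshold
        Rarity cutoff; a variant is rare iff every present subpopulation
        allele frequency is strictly below this value. Default ``1e-4``.
    revel_threshold, vest3_threshold
        Missense deleteriousness cutoffs in [0, 1]; a missense variant is
        deleterious iff **both** scores are at or above their thresholds.
    missing_af_policy
        ``"treat-as-rare"`` (default): a variant absent from all frequency
        resources passes the rarity filter (novel variants are rare);
        ``"exclude"``: it fails.
    missing_score_policy
        ``"not-deleterious"`` (default): a missense variant lacking either
        score is not deleterious; ``"exclude"`` is an alias with the same
        effect on selection.
    """

    maf_threshold: float = 1e-4
    revel_threshold: float = 0.5
    vest3_threshold: float = 0.5
    missing_af_policy: str = "treat-as-rare"
    missing_score_policy: str = "not-deleterious"

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold <= 0.5:
            raise ValueError(f"maf_threshold must be in (0, 0.5]: {self.maf_threshold}")
        for name in ("revel_threshold", "vest3_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]: {v}")
        if self.missing_af_policy not in ("treat-as-rare", "exclude"):
            raise ValueError(f"unknown missing_af_policy {self.missing_af_policy!r}")
        if self.missing_score_policy not in ("not-deleterious", "exclude"):
            raise ValueError(
                f"unknown missing_score_policy {self.missing_score_policy!r}"
            )


@dataclass
class QualifyingSet:
    """Qualifying variants of one class in one gene, collapsed to carriers."""

    gene: str
    class_label: str
    variants: list[VariantRecord] = field(default_factory=list)
    carrier_count: int = 0
    n_samples: Optional[int] = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise UsageError(f"unknown class label {self.class_label!r}")
        if self.carrier_count < 0:
            raise ValueError("carrier_count must be non-negative")
        if self.n_samples is not None and self.carrier_count > self.n_samples:
            raise ValueError("carrier_count exceeds n_samples")

    @property
    def carrier_ids(self) -> frozenset[str]:
        ids: set[str] = set()
        for v in self.variants:
            ids |= v.carrier_ids
        return frozenset(ids)


def is_rare(
    subpop_af: dict[str, float],
    maf_threshold: float = 1e-4,
    missing_af_policy: str = "treat-as-rare",
) -> bool:
    """Rarity filter: strictly below threshold in every subpopulation.

    An empty frequency mapping follows ``missing_af_policy``: by default
    such variants are treated as rare (a variant unseen by every reference
    resource cannot be common).
    """
    for pop, af in subpop_af.items():
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency for {pop} out of [0,1]: {af}")
    if not subpop_af:
        return missing_af_policy == "treat-as-rare"
    return all(af < maf_threshold for af in subpop_af.values())


def scores_deleterious(
    revel: Optional[float], vest3: Optional[float], config: FilterConfig
) -> bool:
    """True iff both pathogenicity scores meet their thresholds.

    A missing score follows ``missing_score_policy`` (both settings make
    the variant non-deleterious; they differ only in intent bookkeeping).
    """
    if revel is None or vest3 is None:
        return False
    return revel >= config.revel_threshold and vest3 >= config.vest3_threshold


def is_deleterious_missense(variant: VariantRecord, config: FilterConfig) -> bool:
    """Deleteriousness call for a missense variant.

    Raises :class:`UsageError` when applied to a non-missense variant:
    the REVEL/VEST3 intersection is defined for missense variants only.
    """
    if variant.consequence_class is not ConsequenceClass.MISSENSE:
        raise UsageError(
            "is_deleterious_missense is defined for missense variants only; "
            f"got {variant.consequence_class.value} at {variant.key}"
        )
    return scores_deleterious(variant.revel, variant.vest3, config)


def select_qualifying(
    variants: Iterable[VariantRecord],
    gene: str,
    class_label: str,
    config: Optional[FilterConfig] = None,
    n_samples: Optional[int] = None,
) -> QualifyingSet:
    """Select the qualifying variants of one class in one gene.

    Variants must already be normalized and classified. INFRAME_INDEL and
    OTHER consequences never enter a burden class. The returned set's
    ``carrier_count`` is the number of distinct carrier identifiers across
    the selected variants (zero when no carrier data are attached).
    """
    if class_label not in CLASS_LABELS:
        raise UsageError(
            f"unknown class label {class_label!r}; expected one of {CLASS_LABELS}"
        )
    config = config or FilterConfig()
    wanted = _CLASS_TO_CONSEQUENCE[class_label]
    selected: list[VariantRecord] = []
    for v in variants:
        if v.gene != gene or v.consequence_class is not wanted:
            continue
        if not is_rare(v.subpop_af, config.maf_threshold, config.missing_af_policy):
            continue
        if class_label == "deleterious_missense" and not scores_deleterious(
            v.revel, v.vest3, config
        ):
            continue
        selected.append(v)
    qs = QualifyingSet(gene=gene, class_label=class_label, variants=selected,
                       n_samples=n_samples)
    qs.carrier_count = len(qs.carrier_ids)
    if n_samples is not None and qs.carrier_count > n_samples:
        raise ValueError(
            f"{qs.carrier_count} carriers exceed cohort size {n_samples}"
        )
    return qs


def count_carriers(
    qualifying: QualifyingSet, roster: Optional[Sequence[str]] = None
) -> int:
    """Distinct individuals with >= 1 alternate allele at >= 1 qualifying variant.

    An individual carrying several qualifying variants counts once. When a
    cohort ``roster`` is given, every carrier must be on it (a carrier off
    the roster indicates inconsistent genotype data) and the count is
    bounded by the roster size.
    """
    carriers = qualifying.carrier_ids
    if roster is not None:
        roster_set = set(roster)
        stray = carriers - roster_set
        if stray:
            raise ValueError(
                f"carriers absent from the cohort roster: {sorted(stray)[:5]}"
            )
    return len(carriers)
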