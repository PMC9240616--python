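"""Domain model for annotated variants and consequence classification.

A :class:`VariantRecord` is one biallelic variant allele with its gene /
transcript annotation, per-subpopulation allele frequencies, in-silico
missense pathogenicity scores (REVEL, VEST3), and optionally the set of
sample identifiers carrying at least one alternate allele.

Consequence classification maps annotation tokens — in either
Sequence-Ontology-style ("stop_gained", "missense_variant") or
ANNOVAR-style ("stopgain", "nonsynonymous SNV") spellings — onto the four
analysis classes used by a collapsing burden test:

* ``TRUNCATING`` — frameshift, stop-gained, canonical splice acceptor/donor;
* ``MISSENSE`` — amino-acid-changing single-nucleotide variants;
* ``SYNONYMOUS`` — protein-silent coding variants (negative-control class);
* ``INFRAME_INDEL`` — inframe insertions/deletions, excluded from burden
  classes because their pathogenicity is hard to ascertain;
* ``OTHER`` — everything else on a documented list (UTR, intronic,
  extended splice region, ...).

Only canonical splice acceptor/donor annotations (the ±1/±2 intronic
positions) count as truncating; extended splice-region tokens map to OTHER.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class ConsequenceClass(Enum):
    """Analysis class of a variant; exactly one per record."""

    TRUNCATING = "truncating"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


class ClassificationError(ValueError):
    """Raised for a consequence token outside the shipped vocabulary."""


_WS = re.compile(r"[\s_\-]+")


def _norm_token(token: str) -> str:
    return _WS.sub(" ", token.strip().lower())


# Shipped vocabulary. Keys are normalised (lower case, separators collapsed
# to single spaces). Both SO-style and ANNOVAR-style spellings are covered.
CONSEQUENCE_VOCABULARY: dict[str, ConsequenceClass] = {
    # --- truncating -------------------------------------------------------
    "frameshift variant": ConsequenceClass.TRUNCATING,
    "frameshift insertion": ConsequenceClass.TRUNCATING,
    "frameshift deletion": ConsequenceClass.TRUNCATING,
    "frameshift substitution": ConsequenceClass.TRUNCATING,
    "stop gained": ConsequenceClass.TRUNCATING,
    "stopgain": ConsequenceClass.TRUNCATING,
    "splice acceptor": ConsequenceClass.TRUNCATING,
    "splice acceptor variant": ConsequenceClass.TRUNCATING,
    "splice donor": ConsequenceClass.TRUNCATING,
    "splice donor variant": ConsequenceClass.TRUNCATING,
    # ANNOVAR's bare "splicing" flags the canonical +/-2 positions only,
    # so it belongs with the truncating class.
    "splicing": ConsequenceClass.TRUNCATING,
    "splice site": ConsequenceClass.TRUNCATING,
    # --- missense ---------------------------------------------------------
    "missense variant": ConsequenceClass.MISSENSE,
    "missense": ConsequenceClass.MISSENSE,
    "nonsynonymous snv": ConsequenceClass.MISSENSE,
    # --- synonymous -------------------------------------------------------
    "synonymous variant": ConsequenceClass.SYNONYMOUS,
    "synonymous snv": ConsequenceClass.SYNONYMOUS,
    # --- inframe indel ----------------------------------------------------
    "inframe insertion": ConsequenceClass.INFRAME_INDEL,
    "inframe deletion": ConsequenceClass.INFRAME_INDEL,
    "nonframeshift insertion": ConsequenceClass.INFRAME_INDEL,
    "nonframeshift deletion": ConsequenceClass.INFRAME_INDEL,
    "nonframeshift substitution": ConsequenceClass.INFRAME_INDEL,
    # --- documented "other" list ------------------------------------------
    "splice region variant": ConsequenceClass.OTHER,
    "start lost": ConsequenceClass.OTHER,
    "startloss": ConsequenceClass.OTHER,
    "stop lost": ConsequenceClass.OTHER,
    "stoploss": ConsequenceClass.OTHER,
    "stop retained variant": ConsequenceClass.OTHER,
    "intron variant": ConsequenceClass.OTHER,
    "intronic": ConsequenceClass.OTHER,
    "5 prime utr variant": ConsequenceClass.OTHER,
    "3 prime utr variant": ConsequenceClass.OTHER,
    "utr5": ConsequenceClass.OTHER,
    "utr3": ConsequenceClass.OTHER,
    "upstream": ConsequenceClass.OTHER,
    "upstream gene variant": ConsequenceClass.OTHER,
    "downstream": ConsequenceClass.OTHER,
    "downstream gene variant": ConsequenceClass.OTHER,
    "intergenic": ConsequenceClass.OTHER,
    "intergenic variant": ConsequenceClass.OTHER,
    "ncrna exonic": ConsequenceClass.OTHER,
    "unknown": ConsequenceClass.OTHER,
}


def classify_consequence(raw_consequence: str) -> ConsequenceClass:
    """Map an annotation-consequence token onto its analysis class.

    The mapping is deterministic, case-insensitive, and total over the
    shipped vocabulary; tokens outside it raise :class:`ClassificationError`
    rather than being silently binned as OTHER.
    """
    if not raw_consequence or not raw_consequence.strip():
        raise ClassificationError("empty consequence token")
    token = _norm_token(raw_consequence)
    try:
        return CONSEQUENCE_VOCABULARY[token]
    except KeyError:
        raise ClassificationError(
            f"unknown consequence token {raw_consequence!r}; "
            "extend CONSEQUENCE_VOCABULARY if this spelling is legitimate"
        ) from None


def normalize_variant(
    chrom: str, pos: int, ref: str, alt: str
) -> tuple[str, int, str, str]:
    """Trim shared leading then trailing bases from an allele pair.

    The position advances by one for every trimmed leading base; at least
    one base is always retained in each allele. SNVs are returned
    unchanged, and the operation is idempotent.

    Raises
    ------
    ValueError
        If ``ref == alt`` (not a variant).
    """
    if not ref or not alt:
        raise ValueError("alleles must be non-empty")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r}): not a variant")
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return chrom, pos, ref, alt


@dataclass
class VariantRecord:
    """One annotated, biallelic variant site.

    Multi-allelic sites must be decomposed into one record per alternate
    allele before construction (the VCF reader does this). Coordinates are
    1-based and fully closed, matching VCF convention.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    raw_consequence: str = ""
    subpop_af: dict[str, float] = field(default_factory=dict)
    revel: Optional[float] = None
    vest3: Optional[float] = None
    carrier_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for pop, af in self.subpop_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency for {pop} out of [0,1]: {af}")
        for name, score in (("revel", self.revel), ("vest3", self.vest3)):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValueError(f"{name} score out of [0,1]: {score}")
        self.carrier_ids = frozenset(self.carrier_ids)

    @property
    def consequence_class(self) -> ConsequenceClass:
        return classify_consequence(self.raw_consequence)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Locus/allele identity, usable as a dict key."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def normalized(self) -> "VariantRecord":
        """Return a copy with trimmed, left-aligned alleles."""
        chrom, pos, ref, alt = normalize_variant(
            self.chrom, self.pos, self.ref, self.alt
        )
        if (chrom, pos, ref, alt) == self.key:
            return self
        return VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=self.gene,
            transcript=self.transcript,
            raw_consequence=self.raw_consequence,
            subpop_af=dict(self.subpop_af),
            revel=self.revel,
            vest3=self.vest3,
            carrier_ids=self.carrier_ids,
        )
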