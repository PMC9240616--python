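"""Reference fixtures reconstructed from published per-class counts.

The motivating analysis reports, for a single gene, the per-class
qualifying-variant and carrier counts of a 793-case discovery cohort, a
419-case validation cohort, a 4,523-sample reference control set (counts
only, gnomAD-controls style), and a baseline clinical table of group
summaries. Those printed counts fully determine the collapsing burden
analysis, so this module rebuilds variant-level fixtures with exactly that
structure:

* discovery cohort — 31 rare variants: six synonymous (6 carriers),
  22 missense (25 carriers, three variants scored deleterious with one
  carrier each), one frameshift insertion and two stop-gained
  (4 distinct truncating carriers; one stop-gained variant recurs in two
  individuals — the published counts do not resolve variant-to-carrier
  multiplicity, and this is the assumption used);
* validation cohort — one frameshift deletion, one stop-gained, one
  canonical splice-site variant (3 truncating carriers), 14 missense
  (15 carriers, one deleterious with one carrier), two synonymous
  (2 carriers);
* control counts — truncating 4, missense 46, deleterious missense 1,
  synonymous 15, of 4,523;
* the baseline table — mean ± SD + n and k/n rows for carriers vs
  sarcomere-positive vs sarcomere-negative patients.

Allele frequencies are below 1e-4 everywhere (several variants are novel,
i.e. absent from all frequency resources); neutral missense scores sit
below 0.4 and deleterious ones above 0.7, so the deleterious-missense
subset is invariant to any threshold choice in [0.4, 0.7].
"""

from __future__ import annotations

from .clinical import (
    BaselineRow,
    CategoricalSummary,
    ContinuousSummary,
    MultiCategoricalSummary,
)
from .variants import VariantRecord

GENE = "ALPK3"
CHROM = "15"
TRANSCRIPT = "NM_020778.5"

N_STUDY = 793
N_VALIDATION = 419
N_CONTROLS = 4523
N_DCM = 1041

_SUBPOPS = ("EAS", "NFE", "AFR", "SAS", "AMR")


def study_roster() -> list[str]:
    return [f"S{i:04d}" for i in range(1, N_STUDY + 1)]


def validation_roster() -> list[str]:
    return [f"V{i:04d}" for i in range(1, N_VALIDATION + 1)]


def _afs(i: int) -> dict[str, float]:
    """Deterministic sub-threshold frequency mapping; every third variant novel."""
    if i % 3 == 0:
        return {}
    base = 1e-6 * (1 + (i * 7) % 90)  # in [1e-6, 9.0e-5]
    return {pop: (base if j == i % len(_SUBPOPS) else 0.0)
            for j, pop in enumerate(_SUBPOPS)}


def _mk(
    pos: int,
    consequence: str,
    carriers: tuple[str, ...],
    i: int,
    revel: float | None = None,
    vest3: float | None = None,
    ref: str = "C",
    alt: str = "T",
) -> VariantRecord:
    return VariantRecord(
        chrom=CHROM,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=GENE,
        transcript=TRANSCRIPT,
        raw_consequence=consequence,
        subpop_af=_afs(i),
        revel=revel,
        vest3=vest3,
        carrier_ids=frozenset(carriers),
    )


def study_variant_records() -> list[VariantRecord]:
    """The 31-variant discovery fixture; carrier ids are disjoint by design."""
    records: list[VariantRecord] = []
    pos = 84840000
    i = 0
    # truncating: one stop-gained in two individuals, one in one, one frameshift
    trunc_carriers = [("S0001", "S0002"), ("S0003",), ("S0004",)]
    trunc_cons = ["stop_gained", "stop_gained", "frameshift insertion"]
    for cons, carr in zip(trunc_cons, trunc_carriers):
        i += 1
        pos += 997
        ref, alt = ("C", "CA") if "frameshift" in cons else ("C", "T")
        records.append(_mk(pos, cons, carr, i, ref=ref, alt=alt))
    # missense: 22 variants, 25 carriers (three variants seen twice);
    # the first three are deleterious, with one carrier each
    sample = 5
    for j in range(22):
        i += 1
        pos += 1013
        n_carr = 2 if j in (3, 4, 5) else 1
        carr = tuple(f"S{sample + k:04d}" for k in range(n_carr))
        sample += n_carr
        if j < 3:
            revel, vest3 = 0.74 + 0.05 * j, 0.78 + 0.04 * j
        else:
            revel, vest3 = 0.04 + 0.015 * j, 0.38 - 0.015 * j
        records.append(
            _mk(pos, "nonsynonymous SNV", carr, i, revel=revel, vest3=vest3,
                ref="G", alt="A")
        )
    # synonymous: 6 variants, 6 carriers
    for j in range(6):
        i += 1
        pos += 1009
        records.append(_mk(pos, "synonymous SNV", (f"S{sample:04d}",), i,
                           ref="T", alt="C"))
        sample += 1
    return records


def validation_variant_records() -> list[VariantRecord]:
    """The validation-cohort fixture: 17 non-synonymous + 2 synonymous variants."""
    records: list[VariantRecord] = []
    pos = 84840500
    i = 40
    for cons, carr, (ref, alt) in (
        ("frameshift deletion", ("V0001",), ("CT", "C")),
        ("stop_gained", ("V0002",), ("C", "T")),
        ("splice_donor_variant", ("V0003",), ("G", "C")),
    ):
        i += 1
        pos += 991
        records.append(_mk(pos, cons, carr, i, ref=ref, alt=alt))
    sample = 4
    for j in range(14):  # 15 carriers; the first variant is deleterious
        i += 1
        pos += 1019
        n_carr = 2 if j == 7 else 1
        carr = tuple(f"V{sample + k:04d}" for k in range(n_carr))
        sample += n_carr
        if j == 0:
            revel, vest3 = 0.82, 0.88
        else:
            revel, vest3 = 0.05 + 0.02 * j, 0.36 - 0.02 * j
        records.append(
            _mk(pos, "missense_variant", carr, i, revel=revel, vest3=vest3,
                ref="A", alt="G")
        )
    for j in range(2):
        i += 1
        pos += 1021
        records.append(_mk(pos, "synonymous_variant", (f"V{sample:04d}",), i,
                           ref="T", alt="A"))
        sample += 1
    return records


def control_carrier_counts() -> dict[str, tuple[int, int]]:
    """Reference-control carriers per class (counts only, no genotypes)."""
    return {
        "truncating": (4, N_CONTROLS),
        "missense": (46, N_CONTROLS),
        "deleterious_missense": (1, N_CONTROLS),
        "synonymous": (15, N_CONTROLS),
    }


def dcm_carrier_counts() -> dict[str, tuple[int, int]]:
    """Dilated-cardiomyopathy cohort carriers per class (counts only)."""
    return {
        "truncating": (1, N_DCM),
        "missense": (18, N_DCM),
    }


GROUP_CARRIER = "carrier"
GROUP_SARC_POS = "sarc_pos"
GROUP_SARC_NEG = "sarc_neg"

# label, kind, {group: (mean, sd, n) | (k, n) | (counts...,)}
_BASELINE = [
    ("Gender = male", "categorical",
     {GROUP_CARRIER: (16, 28), GROUP_SARC_POS: (54, 82), GROUP_SARC_NEG: (439, 621)}),
    ("Age of onset (years)", "continuous",
     {GROUP_CARRIER: (53.50, 17.21, 28), GROUP_SARC_POS: (45.17, 14.01, 82),
      GROUP_SARC_NEG: (51.95, 14.20, 621)}),
    ("Age at enrollment (years)", "continuous",
     {GROUP_CARRIER: (54.00, 17.18, 28), GROUP_SARC_POS: (48.00, 13.73, 82),
      GROUP_SARC_NEG: (53.06, 14.17, 621)}),
    ("Family history of HCM", "categorical",
     {GROUP_CARRIER: (2, 28), GROUP_SARC_POS: (7, 82), GROUP_SARC_NEG: (13, 621)}),
    ("Family history of SCD", "categorical",
     {GROUP_CARRIER: (0, 28), GROUP_SARC_POS: (2, 82), GROUP_SARC_NEG: (3, 621)}),
    ("Family history of stroke", "categorical",
     {GROUP_CARRIER: (3, 28), GROUP_SARC_POS: (4, 82), GROUP_SARC_NEG: (33, 621)}),
    ("Smoke", "categorical",
     {GROUP_CARRIER: (8, 28), GROUP_SARC_POS: (25, 82), GROUP_SARC_NEG: (229, 621)}),
    ("Alcohol intake", "categorical",
     {GROUP_CARRIER: (3, 28), GROUP_SARC_POS: (19, 82), GROUP_SARC_NEG: (158, 621)}),
    # NYHA class I / II / III-IV; row-specific ns (missing data)
    ("NYHA heart function class", "multi-categorical",
     {GROUP_CARRIER: (3, 2, 8), GROUP_SARC_POS: (5, 19, 13),
      GROUP_SARC_NEG: (69, 145, 117)}),
    ("Episode of syncope", "categorical",
     {GROUP_CARRIER: (1, 28), GROUP_SARC_POS: (5, 82), GROUP_SARC_NEG: (37, 621)}),
    ("QTc (ms)", "continuous",
     {GROUP_CARRIER: (459.52, 36.63, 28), GROUP_SARC_POS: (460.90, 37.08, 82),
      GROUP_SARC_NEG: (458.79, 42.13, 621)}),
    ("QTc > 450 ms", "categorical",
     {GROUP_CARRIER: (16, 27), GROUP_SARC_POS: (44, 72), GROUP_SARC_NEG: (331, 599)}),
    ("Atrial fibrillation", "categorical",
     {GROUP_CARRIER: (7, 28), GROUP_SARC_POS: (19, 82), GROUP_SARC_NEG: (77, 621)}),
    ("Non-sustained ventricular tachycardia", "categorical",
     {GROUP_CARRIER: (3, 28), GROUP_SARC_POS: (20, 82), GROUP_SARC_NEG: (52, 621)}),
    ("Atrioventricular block", "categorical",
     {GROUP_CARRIER: (1, 28), GROUP_SARC_POS: (4, 82), GROUP_SARC_NEG: (25, 621)}),
    ("Any arrhythmia", "categorical",
     {GROUP_CARRIER: (11, 28), GROUP_SARC_POS: (41, 82), GROUP_SARC_NEG: (193, 621)}),
    ("Non-fatal stroke", "categorical",
     {GROUP_CARRIER: (6, 28), GROUP_SARC_POS: (3, 82), GROUP_SARC_NEG: (80, 621)}),
    ("CAD", "categorical",
     {GROUP_CARRIER: (6, 28), GROUP_SARC_POS: (6, 82), GROUP_SARC_NEG: (214, 621)}),
    ("Diabetes mellitus", "categorical",
     {GROUP_CARRIER: (3, 28), GROUP_SARC_POS: (7, 82), GROUP_SARC_NEG: (128, 621)}),
    ("Max wall thickness (mm)", "continuous",
     {GROUP_CARRIER: (19.36, 5.09, 28), GROUP_SARC_POS: (21.15, 5.18, 82),
      GROUP_SARC_NEG: (17.16, 3.69, 621)}),
    ("Max wall thickness >= 30 mm", "categorical",
     {GROUP_CARRIER: (1, 28), GROUP_SARC_POS: (5, 82), GROUP_SARC_NEG: (10, 621)}),
    ("IVS (mm)", "continuous",
     {GROUP_CARRIER: (18.43, 5.57, 28), GROUP_SARC_POS: (20.50, 5.76, 82),
      GROUP_SARC_NEG: (16.78, 3.88, 621)}),
    ("LVPW (mm)", "continuous",
     {GROUP_CARRIER: (12.11, 3.29, 28), GROUP_SARC_POS: (11.06, 2.84, 82),
      GROUP_SARC_NEG: (12.36, 3.05, 621)}),
    ("Apex (mm)", "continuous",
     {GROUP_CARRIER: (11.89, 4.30, 28), GROUP_SARC_POS: (11.07, 3.32, 82),
      GROUP_SARC_NEG: (10.84, 2.50, 621)}),
    ("LAD (mm)", "continuous",
     {GROUP_CARRIER: (39.41, 5.63, 28), GROUP_SARC_POS: (42.00, 9.57, 82),
      GROUP_SARC_NEG: (41.62, 7.59, 621)}),
    ("LVEDD (mm)", "continuous",
     {GROUP_CARRIER: (46.22, 5.53, 28), GROUP_SARC_POS: (44.37, 7.82, 82),
      GROUP_SARC_NEG: (48.67, 8.21, 621)}),
    ("LVEF (%)", "continuous",
     {GROUP_CARRIER: (61.33, 9.21, 28), GROUP_SARC_POS: (63.84, 11.30, 82),
      GROUP_SARC_NEG: (57.82, 13.23, 621)}),
    ("LVOTG >= 30 mm Hg", "categorical",
     {GROUP_CARRIER: (8, 28), GROUP_SARC_POS: (30, 82), GROUP_SARC_NEG: (178, 621)}),
]


def baseline_rows() -> list[BaselineRow]:
    """Baseline-table rows: carriers vs sarcomere-positive vs -negative."""
    rows: list[BaselineRow] = []
    for label, kind, per_group in _BASELINE:
        groups: dict = {}
        for gname, vals in per_group.items():
            if kind == "continuous":
                mean, sd, n = vals
                groups[gname] = ContinuousSummary(label, mean, sd, n)
            elif kind == "categorical":
                k, n = vals
                groups[gname] = CategoricalSummary(label, k, n)
            else:
                groups[gname] = MultiCategoricalSummary(label, tuple(vals))
        rows.append(BaselineRow(label=label, kind=kind, groups=groups))
    return rows


BASELINE_PAIRS = [
    (GROUP_CARRIER, GROUP_SARC_POS),
    (GROUP_CARRIER, GROUP_SARC_NEG),
]
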