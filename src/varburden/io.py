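"""Readers, writers, pipeline configuration, and the end-to-end runner.

Documented table dialects (all tab-separated, UTF-8, header row required):

* annotated-variant table — one row per biallelic variant allele:
  ``chrom  pos  ref  alt  gene  transcript  consequence  af_<POP>...
  revel  vest3  carriers`` where ``af_<POP>`` columns carry subpopulation
  allele frequencies, score columns may be empty, and ``carriers`` is an
  optional semicolon-separated list of sample identifiers;
* carrier-count table — ``class_label  cohort  carriers  total`` for
  count-only cohorts (reference controls ship no genotypes);
* baseline table — long format, one row per (row label, group):
  ``label  type  group  mean  sd  n  k  counts`` with ``type`` one of
  ``cont`` / ``cat`` / ``multi-cat`` and ``counts`` a semicolon list for
  multi-level rows.

A minimal VCF 4.x path (sites + GT, optional INFO keys GENE, TRANSCRIPT,
CSQ, REVEL, VEST3, AF_<POP>) is provided through pysam; multi-allelic
records are decomposed into one biallelic record per alternate allele
before normalization and classification.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam
import yaml

from . import __version__
from .clinical import (
    BaselineRow,
    CategoricalSummary,
    ContinuousSummary,
    MultiCategoricalSummary,
    compare_baseline,
)
from .filtering import CLASS_LABELS, FilterConfig, select_qualifying
from .stats import burden_test, calibration_synonymous, meta_pool
from .variants import VariantRecord, classify_consequence

logger = logging.getLogger(__name__)

MANDATORY_VARIANT_COLUMNS = (
    "chrom", "pos", "ref", "alt", "gene", "transcript", "consequence",
)


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unusable header."""


# ---------------------------------------------------------------------------
# annotated-variant TSV


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read, validate, normalize, and classify an annotated-variant TSV.

    Malformed rows are reported together with their 1-based line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    records: list[VariantRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            subpop_af = {
                c[3:].upper(): float(row[c]) for c in af_cols if row[c] != ""
            }
            carriers = frozenset(
                s for s in str(row.get("carriers", "")).split(";") if s
            )
            rec = VariantRecord(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                transcript=row["transcript"],
                raw_consequence=row["consequence"],
                subpop_af=subpop_af,
                revel=float(row["revel"]) if row.get("revel", "") != "" else None,
                vest3=float(row["vest3"]) if row.get("vest3", "") != "" else None,
                carrier_ids=carriers,
            )
            rec.consequence_class  # validates the token against the vocabulary
            records.append(rec.normalized())
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    logger.info("read %d variant records from %s", len(records), path)
    return records


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records in the annotated-variant TSV dialect."""
    subpops = sorted({pop for r in records for pop in r.subpop_af})
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene,
            "transcript": r.transcript,
            "consequence": r.raw_consequence,
        }
        for pop in subpops:
            row[f"af_{pop.lower()}"] = (
                repr(r.subpop_af[pop]) if pop in r.subpop_af else ""
            )
        row["revel"] = "" if r.revel is None else repr(r.revel)
        row["vest3"] = "" if r.vest3 is None else repr(r.vest3)
        row["carriers"] = ";".join(sorted(r.carrier_ids))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# minimal VCF


def read_vcf(path: str | Path, default_gene: str = "") -> list[VariantRecord]:
    """Read a minimal VCF: sites + GT, optional annotation INFO keys.

    Multi-allelic records are decomposed; a sample is a carrier of an
    alternate allele iff its GT contains that allele's index.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info = rec.info
            present = set(info.keys())  # .get on undeclared keys raises
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                carriers = frozenset(
                    s for s in samples
                    if alt_index in (rec.samples[s].get("GT") or ())
                )
                subpop_af = {
                    key[3:]: float(_scalar(info[key]))
                    for key in present
                    if key.startswith("AF_")
                }
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=str(_scalar(info["GENE"])) if "GENE" in present
                        else default_gene,
                        transcript=str(_scalar(info["TRANSCRIPT"]))
                        if "TRANSCRIPT" in present else "",
                        raw_consequence=str(_scalar(info["CSQ"]))
                        if "CSQ" in present else "unknown",
                        subpop_af=subpop_af,
                        revel=_opt_float(info["REVEL"]) if "REVEL" in present
                        else None,
                        vest3=_opt_float(info["VEST3"]) if "VEST3" in present
                        else None,
                        carrier_ids=carriers,
                    ).normalized()
                )
    logger.info("read %d variant records from %s", len(records), path)
    return records


def _scalar(value):
    if isinstance(value, tuple):
        return value[0]
    return value


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    return float(_scalar(value))


def write_vcf(
    records: Sequence[VariantRecord],
    roster: Sequence[str],
    path: str | Path,
) -> None:
    """Write biallelic records as a plain-text VCF with GT columns."""
    header = pysam.VariantHeader()
    contigs = sorted({r.chrom for r in records})
    for contig in contigs:
        header.contigs.add(contig)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("TRANSCRIPT", 1, "String", "Transcript identifier")
    header.info.add("CSQ", 1, "String", "Consequence token (underscored)")
    header.info.add("REVEL", 1, "Float", "REVEL missense pathogenicity score")
    header.info.add("VEST3", 1, "Float", "VEST3 missense pathogenicity score")
    subpops = sorted({pop for r in records for pop in r.subpop_af})
    for pop in subpops:
        header.info.add(f"AF_{pop}", 1, "Float",
                        f"Allele frequency in subpopulation {pop}")
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in roster:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda v: (v.chrom, v.pos)):
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            rec.info["GENE"] = r.gene
            if r.transcript:
                rec.info["TRANSCRIPT"] = r.transcript
            rec.info["CSQ"] = r.raw_consequence.replace(" ", "_")
            if r.revel is not None:
                rec.info["REVEL"] = r.revel
            if r.vest3 is not None:
                rec.info["VEST3"] = r.vest3
            for pop, af in r.subpop_af.items():
                rec.info[f"AF_{pop}"] = af
            for sample in roster:
                rec.samples[sample]["GT"] = (
                    (0, 1) if sample in r.carrier_ids else (0, 0)
                )
            out.write(rec)


# ---------------------------------------------------------------------------
# carrier-count TSV


def read_carrier_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("class_label", "cohort", "carriers", "total")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    bad = df[(df["carriers"] < 0) | (df["carriers"] > df["total"]) | (df["total"] <= 0)]
    if len(bad):
        raise ValueError(f"{path}: invalid counts in rows {list(bad.index + 2)}")
    return df


def write_carrier_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# baseline-table TSV


def read_baseline_table(path: str | Path) -> list[BaselineRow]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("label", "type", "group") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    kind_map = {"cont": "continuous", "cat": "categorical",
                "multi-cat": "multi-categorical"}
    rows: dict[str, BaselineRow] = {}
    for idx, row in df.iterrows():
        label, group = row["label"], row["group"]
        try:
            kind = kind_map[row["type"]]
            if kind == "continuous":
                summary = ContinuousSummary(
                    label, float(row["mean"]), float(row["sd"]), int(row["n"])
                )
            elif kind == "categorical":
                summary = CategoricalSummary(label, int(row["k"]), int(row["n"]))
            else:
                counts = tuple(int(c) for c in row["counts"].split(";"))
                summary = MultiCategoricalSummary(label, counts)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: line {idx + 2}: {exc}") from None
        rows.setdefault(label, BaselineRow(label=label, kind=kind, groups={}))
        if rows[label].kind != kind:
            raise ValueError(f"{path}: row {label!r} mixes types")
        rows[label].groups[group] = summary
    return list(rows.values())


def write_baseline_table(rows: Sequence[BaselineRow], path: str | Path) -> None:
    kind_map = {"continuous": "cont", "categorical": "cat",
                "multi-categorical": "multi-cat"}
    out = []
    for row in rows:
        for group, s in row.groups.items():
            rec = {"label": row.label, "type": kind_map[row.kind], "group": group,
                   "mean": "", "sd": "", "n": "", "k": "", "counts": ""}
            if row.kind == "continuous":
                rec.update(mean=repr(s.mean), sd=repr(s.sd), n=s.n)
            elif row.kind == "categorical":
                rec.update(k=s.k, n=s.n)
            else:
                rec.update(counts=";".join(str(c) for c in s.counts))
            out.append(rec)
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline configuration and runner


@dataclass
class CohortSpec:
    """One genotype-level cohort: a variant table or VCF plus its size."""

    name: str
    n: int
    variant_table: Optional[str] = None
    vcf: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"cohort {self.name}: n must be positive")
        if not (self.variant_table or self.vcf):
            raise ValueError(f"cohort {self.name}: needs variant_table or vcf")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; loadable from YAML/JSON."""

    gene: str
    cohorts: list[CohortSpec]
    control_counts: str  # carrier-count TSV for the reference controls
    n_controls: Optional[int] = None  # taken from the count table if omitted
    transcript: str = ""
    classes: tuple[str, ...] = ("truncating", "missense", "deleterious_missense")
    calibration_class: str = "synonymous"
    filter: FilterConfig = field(default_factory=FilterConfig)
    ci_method: str = "exact-conditional"
    ci_level: float = 0.95
    categorical_rule: str = "chi-square"
    baseline_table: Optional[str] = None
    baseline_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for label in (*self.classes, self.calibration_class):
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown analysis class {label!r}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        raw["cohorts"] = [CohortSpec(**c) for c in raw.get("cohorts", [])]
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "classes" in raw:
            raw["classes"] = tuple(raw["classes"])
        if "baseline_pairs" in raw:
            raw["baseline_pairs"] = [tuple(p) for p in raw["baseline_pairs"]]
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Per gene and class: qualify, collapse, test, pool, calibrate, report.

    Returns the result bundle as a JSON-ready dict; when ``out_dir`` is
    given, writes ``burden_results.tsv``, ``results.json``,
    ``clinical_results.tsv`` (if a baseline table is configured) and a run
    manifest, removing partial outputs if any stage fails.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    try:
        bundle = _run(config)
    except Exception as exc:
        if out_path is not None:
            shutil.rmtree(out_path, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("pipeline", str(exc)) from exc
    if out_path is not None:
        _write_bundle(bundle, config, out_path)
    return bundle


def _run(config: PipelineConfig) -> dict:
    # stage: read cohorts
    cohort_variants: dict[str, list[VariantRecord]] = {}
    for spec in config.cohorts:
        try:
            if spec.variant_table:
                cohort_variants[spec.name] = read_variant_table(spec.variant_table)
            else:
                cohort_variants[spec.name] = read_vcf(spec.vcf, config.gene)
        except Exception as exc:
            raise PipelineError("read-cohorts", f"cohort {spec.name}: {exc}") from exc
        logger.info("stage read-cohorts: %s -> %d records",
                    spec.name, len(cohort_variants[spec.name]))

    # stage: read control counts
    try:
        control_df = read_carrier_counts(config.control_counts)
        controls = {
            row["class_label"]: (int(row["carriers"]), int(row["total"]))
            for _, row in control_df.iterrows()
        }
    except Exception as exc:
        raise PipelineError("read-controls", str(exc)) from exc
    n_controls = config.n_controls or (
        int(control_df["total"].iloc[0]) if len(control_df) else 0
    )
    logger.info("stage read-controls: %d classes", len(controls))

    analysis_classes = (*config.classes, config.calibration_class)

    # stage: qualify + collapse
    per_cohort: dict[str, dict[str, dict]] = {}
    for spec in config.cohorts:
        per_cohort[spec.name] = {}
        for label in analysis_classes:
            qs = select_qualifying(
                cohort_variants[spec.name], config.gene, label, config.filter,
                n_samples=spec.n,
            )
            per_cohort[spec.name][label] = {
                "n_variants": len(qs.variants),
                "carriers": qs.carrier_count,
                "n": spec.n,
            }
        logger.info(
            "stage qualify: cohort %s -> %s", spec.name,
            {c: per_cohort[spec.name][c]["carriers"] for c in analysis_classes},
        )

    # stage: burden tests per cohort and pooled
    burden: dict[str, dict] = {}
    for label in config.classes:
        if label not in controls:
            raise PipelineError(
                "burden", f"control counts missing class {label!r}"
            )
        b, n2 = controls[label]
        burden[label] = {}
        pool_input = []
        for spec in config.cohorts:
            a = per_cohort[spec.name][label]["carriers"]
            res = burden_test(a, spec.n, b, n2, class_label=label,
                              level=config.ci_level, ci_method=config.ci_method)
            burden[label][spec.name] = res.to_dict()
            pool_input.append((a, spec.n))
        if len(pool_input) > 1:
            pooled_a, pooled_n = meta_pool(pool_input)
            res = burden_test(pooled_a, pooled_n, b, n2, class_label=label,
                              level=config.ci_level, ci_method=config.ci_method)
            burden[label]["meta"] = res.to_dict()
        logger.info("stage burden: class %s done", label)

    # stage: synonymous calibration
    calibration: dict[str, dict] = {}
    syn = config.calibration_class
    if syn in controls:
        b, n2 = controls[syn]
        for spec in config.cohorts:
            a = per_cohort[spec.name][syn]["carriers"]
            cal = calibration_synonymous(a, spec.n, b, n2,
                                         level=config.ci_level,
                                         ci_method=config.ci_method)
            calibration[spec.name] = {
                **cal.burden.to_dict(),
                "calibrated": cal.calibrated,
                "threshold": cal.threshold,
            }
        logger.info("stage calibration: %d cohorts", len(calibration))

    # stage: clinical baseline
    clinical = None
    if config.baseline_table:
        try:
            rows = read_baseline_table(config.baseline_table)
            report = compare_baseline(rows, config.baseline_pairs,
                                      method_rule=config.categorical_rule)
            clinical = report.to_dict(orient="records")
        except Exception as exc:
            raise PipelineError("clinical", str(exc)) from exc
        logger.info("stage clinical: %d comparisons", len(clinical))

    return {
        "gene": config.gene,
        "qualifying": per_cohort,
        "burden": burden,
        "calibration": calibration,
        "clinical": clinical,
        "n_controls": n_controls,
    }


def _forest_table(bundle: dict) -> pd.DataFrame:
    """Forest-plot-ready rows: class, cohort, counts, OR, CI, P."""
    rows = []
    for label, by_cohort in bundle["burden"].items():
        for cohort, res in by_cohort.items():
            rows.append(
                {
                    "class_label": label,
                    "cohort": cohort,
                    "N_cases": f"{res['case_carriers']}/{res['n_cases']}",
                    "N_controls": f"{res['ctrl_carriers']}/{res['n_controls']}",
                    "OR": res["or_sample"],
                    "CI95_low": res["ci_low"],
                    "CI95_high": res["ci_high"],
                    "P": res["p_two_sided"],
                }
            )
    return pd.DataFrame(rows)


def _write_bundle(bundle: dict, config: PipelineConfig, out_path: Path) -> None:
    _forest_table(bundle).to_csv(out_path / "burden_results.tsv", sep="\t",
                                 index=False)
    if bundle["clinical"] is not None:
        pd.DataFrame(bundle["clinical"]).to_csv(
            out_path / "clinical_results.tsv", sep="\t", index=False
        )
    with open(out_path / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=_json_default)
    manifest = {
        "package": "varburden",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }
    with open(out_path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)
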