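"""Cohort-level frequency summaries and the end-to-end pipeline.

Frequencies follow the conventions of population pharmacogenomic reports:
each individual contributes two haplotype units per gene (denominator 2N; a
duplicated allele counts as one unit under its ``xN`` label) and one
diplotype/phenotype unit (denominator N).  "Common" alleles are those with
frequency strictly > 0.05; the rare bins are strictly < 0.05 and < 0.01.
Percentages are rounded half-up to one decimal, matching printed style.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import reference_data as ref
from .phenotyper import phenotype_cohort
from .risk_medications import (
    MedicationRecord,
    annotate_risk,
    any_high_risk,
    cohort_interaction_summary,
    flag_interactions,
)
from .star_caller import call_cohort
from .synthetic_cohort import (
    CohortConfig,
    ConfigurationError,
    emit_depth,
    emit_phased_vcf,
    sample_cohort,
    sample_medications,
    write_demographics_csv,
    write_medications_csv,
)
from .util import percent, round_half_up
from .phenotyper import activity_score_of

logger = logging.getLogger("pgxcohort")

__all__ = [
    "haplotype_frequencies",
    "diplotype_frequencies",
    "phenotype_frequencies",
    "count_alleles_by_threshold",
    "function_class_composition",
    "demographics_summary",
    "rsid_scan",
    "run_pipeline",
]


def _freq_table(units: pd.DataFrame, unit_col: str) -> pd.DataFrame:
    counts = (
        units.groupby(["gene", unit_col], sort=True).size().reset_index(name="count")
    )
    totals = counts.groupby("gene")["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    return counts.rename(columns={unit_col: "label"})


def haplotype_frequencies(calls: pd.DataFrame) -> pd.DataFrame:
    """Haplotype (star-allele) frequencies per gene; denominator 2N."""
    units = pd.concat(
        [
            calls[["gene", "allele1"]].rename(columns={"allele1": "allele"}),
            calls[["gene", "allele2"]].rename(columns={"allele2": "allele"}),
        ],
        ignore_index=True,
    )
    return _freq_table(units, "allele")


def diplotype_frequencies(calls: pd.DataFrame) -> pd.DataFrame:
    return _freq_table(calls[["gene", "diplotype"]], "diplotype")


def phenotype_frequencies(assignments: pd.DataFrame) -> pd.DataFrame:
    return _freq_table(assignments[["gene", "phenotype"]], "phenotype")


def count_alleles_by_threshold(
    freq_table: pd.DataFrame, thresholds: Sequence[float] = (0.05, 0.01)
) -> dict[str, int]:
    """Partition distinct allele labels by frequency.

    ``total = below_<t0> + at_or_above_<t0>`` always holds for the first
    threshold (the bins are strict: < t vs >= t).
    """
    freqs = freq_table["frequency"].to_numpy() if len(freq_table) else np.array([])
    out = {"total": int(len(freqs))}
    for t in thresholds:
        out[f"below_{t:g}"] = int((freqs < t).sum())
    t0 = thresholds[0]
    out[f"at_or_above_{t0:g}"] = int((freqs >= t0).sum())
    return out


def function_class_composition(
    freq_table: pd.DataFrame,
    defs: Mapping[str, ref.AlleleDefinitionTable],
    threshold: float = 0.05,
) -> dict[str, float]:
    """Share of each function class among alleles with frequency > threshold."""
    common = freq_table[freq_table["frequency"] > threshold]
    if common.empty:
        return {}
    classes = []
    for row in common.itertuples():
        table = defs[row.gene]
        label = row.label
        if label == table.deletion_allele_name or label == "*DEL":
            score: float | None = 0.0
        else:
            try:
                score = activity_score_of(label, table.activity_scores())
            except KeyError:
                raise ref.ValidationError(
                    f"{row.gene}: allele {label} missing from definition table"
                ) from None
        classes.append(ref.function_class_from_score(score))
    series = pd.Series(classes)
    return (series.value_counts() / len(series)).sort_index().to_dict()


def demographics_summary(demographics: pd.DataFrame) -> dict:
    """Counts/percentages for sex and color/race, median age and IQR."""
    n = len(demographics)
    if n == 0:
        raise ValueError("empty cohort")
    out: dict = {"n": n}
    sex_counts = demographics["sex"].value_counts().sort_index()
    out["sex"] = {
        k: {"count": int(v), "pct": percent(int(v), n)} for k, v in sex_counts.items()
    }
    ages = demographics["age"].to_numpy(dtype=float)
    out["age"] = {
        "median": float(np.median(ages)),
        "iqr": [float(np.percentile(ages, 25)), float(np.percentile(ages, 75))],
    }
    race_counts = demographics["color_race"].value_counts().sort_index()
    out["color_race"] = {
        k: {"count": int(v), "pct": percent(int(v), n)} for k, v in race_counts.items()
    }
    return out


def rsid_scan(vcf_path: str | Path, rsids: Iterable[str]) -> pd.DataFrame:
    """Targeted per-rsID scan: alt-allele frequency, het and hom-alt carriers.

    An rsID absent from the VCF is reported with ``found = False``, never an
    error.
    """
    wanted = list(dict.fromkeys(rsids))
    rows = {r: None for r in wanted}
    vcf = VCF(str(vcf_path))
    n_samples = len(vcf.samples)
    for rec in vcf:
        if rec.ID in rows and rows[rec.ID] is None:
            het = hom = alt = 0
            for gt in rec.genotypes:
                a = [x for x in gt[:-1] if x >= 0]
                n_alt = sum(1 for x in a if x > 0)
                alt += n_alt
                if len(a) == 2:
                    if n_alt == 1:
                        het += 1
                    elif n_alt == 2:
                        hom += 1
            rows[rec.ID] = {
                "rsid": rec.ID,
                "found": True,
                "n_samples": n_samples,
                "het_count": het,
                "hom_alt_count": hom,
                "allele_frequency": alt / (2 * n_samples) if n_samples else 0.0,
            }
    vcf.close()
    out = [
        rows[r]
        or {
            "rsid": r,
            "found": False,
            "n_samples": n_samples,
            "het_count": 0,
            "hom_alt_count": 0,
            "allele_frequency": 0.0,
        }
        for r in wanted
    ]
    return pd.DataFrame(
        out,
        columns=["rsid", "found", "n_samples", "het_count", "hom_alt_count", "allele_frequency"],
    )


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(
    config: CohortConfig | str | Path,
    out_dir: str | Path,
    defs: Mapping[str, ref.AlleleDefinitionTable] | None = None,
    rsids: Sequence[str] = (),
) -> dict:
    """simulate -> call -> phenotype -> risk -> interact -> summarize.

    Writes all intermediate TSV/CSV artifacts plus ``report.json`` into
    ``out_dir`` and returns the report.  Deterministic given the config seed.
    """
    if not isinstance(config, CohortConfig):
        config = CohortConfig.from_yaml(config)
    if config.n < 1:
        raise ConfigurationError("pipeline requires n >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: n=%d seed=%d", config.n, config.seed)
    if defs is None:
        defs = ref.load_allele_definitions()
    tables = ref.load_translation_tables()
    risk_tables = ref.load_ehr_risk_tables()
    pairs = ref.load_drug_gene_pairs()
    synonyms = ref.load_drug_synonyms()

    cohort = sample_cohort(config, defs)
    cohort = sample_medications(config, cohort)
    vcf_path = emit_phased_vcf(cohort, defs, out_dir / "cohort.vcf")
    depth_path = emit_depth(cohort, defs, config, out_dir / "depth.tsv")
    write_demographics_csv(cohort, out_dir / "demographics.csv")
    write_medications_csv(cohort, out_dir / "medications.csv")

    logger.info("stage call")
    sim_genes = set(config.haplotype_frequencies) | set(config.diplotype_frequencies)
    call_defs = {g: t for g, t in defs.items() if g in sim_genes}
    calls = call_cohort(vcf_path, depth_path, call_defs)
    calls.to_csv(out_dir / "calls.tsv", sep="\t", index=False)

    logger.info("stage phenotype")
    assignments = phenotype_cohort(calls, tables, defs)
    assignments.to_csv(out_dir / "phenotypes.tsv", sep="\t", index=False)

    logger.info("stage risk")
    annotations = annotate_risk(assignments, risk_tables)
    annotations.to_csv(out_dir / "risk.tsv", sep="\t", index=False)
    risk_any = any_high_risk(annotations, ref.LEVEL_1A_GENES)

    logger.info("stage interact")
    records = [
        MedicationRecord(ind.id, tuple(ind.medications), ind.missing_medications)
        for ind in cohort
    ]
    flags = flag_interactions(records, annotations, pairs, synonyms)
    pd.DataFrame(
        [(f.sample, f.drug, f.gene, f.phenotype) for f in flags],
        columns=["sample", "drug", "gene", "phenotype"],
    ).to_csv(out_dir / "interactions.tsv", sep="\t", index=False)
    med_summary = cohort_interaction_summary(records, annotations, pairs, synonyms)

    logger.info("stage summarize")
    hap_freqs = haplotype_frequencies(calls)
    hap_freqs.to_csv(out_dir / "haplotype_frequencies.tsv", sep="\t", index=False)
    dip_freqs = diplotype_frequencies(calls)
    dip_freqs.to_csv(out_dir / "diplotype_frequencies.tsv", sep="\t", index=False)
    phen_freqs = phenotype_frequencies(assignments)
    phen_freqs.to_csv(out_dir / "phenotype_frequencies.tsv", sep="\t", index=False)

    demo = pd.read_csv(out_dir / "demographics.csv")
    report = {
        "seed": config.seed,
        "n": config.n,
        "demographics": demographics_summary(demo),
        "star_alleles": count_alleles_by_threshold(hap_freqs),
        "function_class_composition_common": {
            k: round_half_up(v, 4) for k, v in function_class_composition(hap_freqs, defs).items()
        },
        "pct_any_high_risk_level1a": percent(int(risk_any.sum()), config.n),
        "per_gene_high_risk_pct": {
            gene: percent(
                int(annotations[(annotations["gene"] == gene) & annotations["high_risk"]][
                    "sample"
                ].nunique()),
                config.n,
            )
            for gene in sorted(annotations["gene"].unique())
        },
        "medications": med_summary,
    }
    if rsids:
        report["rsid_scan"] = rsid_scan(vcf_path, rsids).to_dict(orient="records")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
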