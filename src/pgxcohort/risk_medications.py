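"""EHR priority risk annotation and gene-drug interaction flagging.

A predicted phenotype is *high-risk* for a gene when the EHR Priority Result
Notation flags it (e.g. CYP2C19 rapid/ultrarapid/intermediate/poor, TPMT
indeterminate, CYP3A5 normal/intermediate — the expressers).  An individual
has a *potential gene-drug interaction* when they take a drug from the
curated evidence level 1A pair list whose partner gene carries a high-risk
phenotype in that individual.  Individuals with missing medication data
produce no flags and are excluded from medication denominators.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference_data import DrugGenePair, EhrRiskTable, ValidationError
from .util import percent

__all__ = [
    "MedicationRecord",
    "InteractionFlag",
    "normalize_drug_name",
    "load_medications_csv",
    "annotate_risk",
    "any_high_risk",
    "flag_interactions",
    "cohort_interaction_summary",
]


@dataclass(frozen=True)
class MedicationRecord:
    sample: str
    drugs: tuple[str, ...] = ()
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing and self.drugs:
            raise ValidationError(f"{self.sample}: missing medication record cannot list drugs")


@dataclass(frozen=True)
class InteractionFlag:
    sample: str
    drug: str
    gene: str
    phenotype: str


def normalize_drug_name(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Lower-case, trim, and map brand names/misspellings to generics."""
    name = name.strip().lower()
    if synonyms:
        name = synonyms.get(name, name)
    return name


def load_medications_csv(path: str | Path) -> list[MedicationRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples():
        missing = row.missing in ("1", "True", "true")
        drugs = tuple(d for d in row.drugs.split(";") if d) if not missing else ()
        records.append(MedicationRecord(row.id, drugs, missing))
    return records


def annotate_risk(
    assignments: pd.DataFrame,
    risk_tables: Mapping[str, EhrRiskTable],
) -> pd.DataFrame:
    """Attach EHR priority status to each phenotype assignment row."""
    high_risk = []
    priority = []
    for row in assignments.itertuples():
        if row.gene not in risk_tables:
            raise ValidationError(f"no EHR risk table for gene {row.gene}")
        table = risk_tables[row.gene]
        if row.phenotype not in table.vocabulary:
            raise ValidationError(
                f"{row.gene}: phenotype {row.phenotype!r} absent from EHR risk vocabulary"
            )
        high_risk.append(row.phenotype in table.high_risk_phenotypes)
        priority.append(table.priority_labels[row.phenotype])
    out = assignments.copy()
    out["high_risk"] = high_risk
    out["priority_label"] = priority
    return out


def any_high_risk(
    annotations: pd.DataFrame, genes: Iterable[str] | None = None
) -> pd.Series:
    """Per-sample indicator: carries >= 1 high-risk phenotype in ``genes``."""
    sub = annotations if genes is None else annotations[annotations["gene"].isin(set(genes))]
    flags = sub.groupby("sample")["high_risk"].any()
    return flags.reindex(sorted(annotations["sample"].unique()), fill_value=False)


def flag_interactions(
    records: Sequence[MedicationRecord],
    annotations: pd.DataFrame,
    pairs: Sequence[DrugGenePair],
    synonyms: Mapping[str, str] | None = None,
) -> list[InteractionFlag]:
    """One flag per (sample, drug, gene) where the drug is taken and the
    sample's annotation for the paired gene is high-risk."""
    genes_by_drug: dict[str, list[str]] = {}
    for p in pairs:
        genes_by_drug.setdefault(normalize_drug_name(p.drug), []).append(p.gene)
    risk_by_sample_gene = {
        (row.sample, row.gene): row.phenotype
        for row in annotations.itertuples()
        if row.high_risk
    }
    flags: list[InteractionFlag] = []
    for rec in records:
        if rec.missing:
            continue
        seen: set[tuple[str, str]] = set()
        for raw in rec.drugs:
            drug = normalize_drug_name(raw, synonyms)
            for gene in genes_by_drug.get(drug, ()):
                phen = risk_by_sample_gene.get((rec.sample, gene))
                if phen is not None and (drug, gene) not in seen:
                    seen.add((drug, gene))
                    flags.append(InteractionFlag(rec.sample, drug, gene, phen))
    return flags


def cohort_interaction_summary(
    records: Sequence[MedicationRecord],
    annotations: pd.DataFrame,
    pairs: Sequence[DrugGenePair],
    synonyms: Mapping[str, str] | None = None,
) -> dict:
    """Cohort-level medication/interaction summary.

    Medication percentages use the individuals with non-missing medication
    data as denominator.  The share of individuals with >= 1 interaction is
    reported against two denominators — the informative cohort and the users
    of any listed drug — because both readings appear in practice.
    """
    if not records:
        raise ValueError("empty cohort")
    informative = [r for r in records if not r.missing]
    n_informative = len(informative)
    if n_informative == 0:
        raise ValueError("no individuals with medication data")

    level1a_drugs = {normalize_drug_name(p.drug) for p in pairs}
    genes_by_drug: dict[str, set[str]] = {}
    for p in pairs:
        genes_by_drug.setdefault(normalize_drug_name(p.drug), set()).add(p.gene)

    normalized = {
        r.sample: {normalize_drug_name(d, synonyms) for d in r.drugs} for r in informative
    }
    users = [r.sample for r in informative if normalized[r.sample] & level1a_drugs]
    flags = flag_interactions(records, annotations, pairs, synonyms)
    per_sample_pairs: dict[str, set[tuple[str, str]]] = {}
    for f in flags:
        per_sample_pairs.setdefault(f.sample, set()).add((f.drug, f.gene))
    n_ge1 = sum(1 for s in per_sample_pairs if per_sample_pairs[s])
    n_gt1 = sum(1 for s in per_sample_pairs if len(per_sample_pairs[s]) > 1)

    drug_counts = [len(r.drugs) for r in informative]
    risk_by_sample_gene = {
        (row.sample, row.gene) for row in annotations.itertuples() if row.high_risk
    }

    per_gene: dict[str, dict] = {}
    for gene in sorted({p.gene for p in pairs}):
        gene_drugs = {normalize_drug_name(p.drug) for p in pairs if p.gene == gene}
        taking = [s for s, meds in normalized.items() if meds & gene_drugs]
        taking_risk = [s for s in taking if (s, gene) in risk_by_sample_gene]
        per_gene[gene] = {
            "n_taking": len(taking),
            "pct_taking": percent(len(taking), n_informative),
            "n_taking_high_risk": len(taking_risk),
            "pct_taking_high_risk": percent(len(taking_risk), n_informative),
        }

    return {
        "n": len(records),
        "n_informative": n_informative,
        "n_taking_any_level1a": len(users),
        "pct_taking_any_level1a": percent(len(users), n_informative),
        "n_with_ge1_interaction": n_ge1,
        "pct_with_ge1_interaction_of_cohort": percent(n_ge1, n_informative),
        "pct_with_ge1_interaction_of_users": (
            percent(n_ge1, len(users)) if users else 0.0
        ),
        "n_with_gt1_interaction": n_gt1,
        "pct_with_gt1_interaction": percent(n_gt1, n_informative),
        "median_drug_count": float(statistics.median(drug_counts)),
        "pct_taking_ge5_drugs": percent(sum(1 for c in drug_counts if c >= 5), n_informative),
        "per_gene": per_gene,
    }
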