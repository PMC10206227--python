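"""Reference tables underpinning the pharmacogenomic pipeline.

Star alleles are named haplotypes of a pharmacogene, each defined by a set of
SNVs/indels on a fixed genome build (hg19 here); ``*1`` is by convention the
reference haplotype.  Each allele carries an activity score (AS): 0 for
loss-of-function, 0.5 for decreased, 1.0 for normal and >=1.5 for increased
function; alleles without an assigned AS have unknown function.  This module
loads and validates the four table kinds the pipeline needs:

* allele definition tables (allele -> defining variants + AS),
* diplotype -> phenotype translation tables,
* EHR priority (high-risk phenotype) tables,
* curated drug-gene pair lists (PharmGKB evidence level 1A tier).

A minimal curated fixture bundle for eleven genes (the nine level-1A genes
plus CYP4F2 and VKORC1, whose phenotypes follow warfarin dosing rules) ships
with the package; full tables in the same TSV formats load identically.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "VariantKey",
    "StarAlleleDef",
    "AlleleDefinitionTable",
    "TranslationTable",
    "EhrRiskTable",
    "DrugGenePair",
    "FormatError",
    "ValidationError",
    "REFERENCE_ALLELE",
    "LEVEL_1A_GENES",
    "WARFARIN_GENES",
    "CONTROL_REGION",
    "normalize_chrom",
    "function_class_from_score",
    "load_gene_regions",
    "load_allele_definitions",
    "load_translation_tables",
    "load_ehr_risk_tables",
    "load_drug_gene_pairs",
    "load_drug_synonyms",
    "write_allele_definitions",
    "write_translation_tables",
    "bundled_path",
]


class FormatError(ValueError):
    """A reference file is structurally malformed (bad columns, duplicates)."""


class ValidationError(ValueError):
    """A reference file parses but violates a semantic invariant."""


REFERENCE_ALLELE = "*1"

#: The nine genes with PharmGKB evidence level 1A drug pairs analysed for
#: EHR priority risk; CYP4F2/VKORC1 are handled via warfarin dose rules.
LEVEL_1A_GENES = (
    "CYP2B6",
    "CYP2C9",
    "CYP2C19",
    "CYP2D6",
    "CYP3A5",
    "NUDT15",
    "SLCO1B1",
    "TPMT",
    "UGT1A1",
)

WARFARIN_GENES = ("CYP4F2", "VKORC1")

#: Deletion-allele label per gene; CYP2D6 uses the conventional *5.
DELETION_ALLELE_NAMES: dict[str, str] = {"CYP2D6": "*5"}
DEFAULT_DELETION_ALLELE = "*DEL"

#: hg19 region of the VDR locus, used as the intrasample depth-normalization
#: control (diploid in all individuals simulated here).
CONTROL_REGION = ("chr12", 48235320, 48298814)

PHENOTYPE_VOCABULARY = frozenset(
    {
        "Ultrarapid Metabolizer",
        "Rapid Metabolizer",
        "Normal Metabolizer",
        "Intermediate Metabolizer",
        "Poor Metabolizer",
        "Increased Function",
        "Normal Function",
        "Decreased Function",
        "Poor Function",
        "Higher Warfarin Dose",
        "Normal Warfarin Dose",
        "Decreased Warfarin Dose",
        "Indeterminate",
        "Unknown",
    }
)


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label to the ``chrN`` spelling."""
    chrom = str(chrom).strip()
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def function_class_from_score(activity_score: float | None) -> str:
    """Derive the function class of an allele from its activity score.

    0 -> loss, (0, 1) -> decreased, [1, 1.5) -> normal, >= 1.5 -> increased,
    undefined -> unknown.  The class is always derived, never stored, so the
    two can never disagree.
    """
    if activity_score is None or (isinstance(activity_score, float) and math.isnan(activity_score)):
        return "unknown"
    if activity_score == 0:
        return "loss"
    if activity_score < 1.0:
        return "decreased"
    if activity_score < 1.5:
        return "normal"
    return "increased"


@dataclass(frozen=True)
class VariantKey:
    """A single variant site on hg19 (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class StarAlleleDef:
    """One star allele: name, defining variants and activity score."""

    gene: str
    name: str
    defining_variants: frozenset[VariantKey]
    activity_score: float | None

    @property
    def function_class(self) -> str:
        return function_class_from_score(self.activity_score)

    @property
    def is_reference(self) -> bool:
        return self.name == REFERENCE_ALLELE

    @property
    def is_composite(self) -> bool:
        """Composite/tandem-arrangement alleles (e.g. ``*68+*4``) are named
        units with their own AS but no defining-variant set."""
        return "+" in self.name


@dataclass
class AlleleDefinitionTable:
    """All star alleles of one gene, in file order (order breaks match ties)."""

    gene: str
    alleles: list[StarAlleleDef]
    region: tuple[str, int, int] | None = None
    deletion_allele_name: str = DEFAULT_DELETION_ALLELE

    def __post_init__(self) -> None:
        names = [a.name for a in self.alleles]
        if len(names) != len(set(names)):
            raise FormatError(f"{self.gene}: duplicate allele names in table")
        refs = [a for a in self.alleles if a.is_reference]
        if len(refs) != 1:
            raise ValidationError(
                f"{self.gene}: expected exactly one reference allele {REFERENCE_ALLELE}, found {len(refs)}"
            )
        ref = refs[0]
        if ref.defining_variants or ref.activity_score != 1.0:
            raise ValidationError(
                f"{self.gene}: reference allele must have no defining variants and AS 1.0"
            )
        if self.region is not None:
            chrom, start, end = self.region
            for allele in self.alleles:
                for v in allele.defining_variants:
                    if v.chrom != chrom or not (start <= v.pos <= end):
                        raise ValidationError(
                            f"{self.gene} {allele.name}: variant {v.chrom}:{v.pos} outside "
                            f"gene region {chrom}:{start}-{end}"
                        )
    @property
    def reference_allele(self) -> StarAlleleDef:
        return next(a for a in self.alleles if a.is_reference)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.alleles]

    def get(self, name: str) -> StarAlleleDef:
        for a in self.alleles:
            if a.name == name:
                return a
        raise KeyError(f"{self.gene}: no allele named {name}")

    def __contains__(self, name: str) -> bool:
        return any(a.name == name for a in self.alleles)

    def activity_scores(self) -> dict[str, float | None]:
        return {a.name: a.activity_score for a in self.alleles}

    def all_variants(self) -> set[VariantKey]:
        out: set[VariantKey] = set()
        for a in self.alleles:
            out |= a.defining_variants
        return out


@dataclass
class TranslationTable:
    """Symmetric diplotype -> phenotype lookup for one gene."""

    gene: str
    entries: dict[tuple[str, str], str]

    @staticmethod
    def key(allele1: str, allele2: str) -> tuple[str, str]:
        return tuple(sorted((allele1, allele2)))  # type: ignore[return-value]

    def lookup(self, allele1: str, allele2: str) -> str | None:
        return self.entries.get(self.key(allele1, allele2))

    @property
    def phenotypes(self) -> set[str]:
        return set(self.entries.values())


@dataclass
class EhrRiskTable:
    """EHR Priority Result Notation for one gene: which predicted phenotypes
    are flagged high-risk for gene-drug interaction."""

    gene: str
    high_risk_phenotypes: set[str]
    priority_labels: dict[str, str]

    @property
    def vocabulary(self) -> set[str]:
        return set(self.priority_labels)


@dataclass(frozen=True)
class DrugGenePair:
    drug: str
    gene: str
    evidence_level: str = "1A"


# ---------------------------------------------------------------------------
# loading


def bundled_path(name: str) -> Path:
    """Path of a fixture table shipped inside the package."""
    return Path(str(resources.files("pgxcohort.data").joinpath(name)))


def _read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def load_gene_regions(path: str | Path | None = None) -> dict[str, tuple[str, int, int]]:
    path = bundled_path("gene_regions.tsv") if path is None else path
    df = _read_tsv(path, ["gene", "chrom", "start", "end"])
    return {
        r.gene: (normalize_chrom(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    }


def load_allele_definitions(
    path: str | Path | None = None,
    regions: Mapping[str, tuple[str, int, int]] | None = None,
) -> dict[str, AlleleDefinitionTable]:
    """Load star-allele definition tables, one per gene found in the file.

    The TSV carries one variant per row; alleles with several defining
    variants repeat their allele row; rows with empty variant fields declare
    variant-free alleles (the reference, whole-gene deletions, composites).
    """
    if path is None:
        path = bundled_path("allele_definitions.tsv")
        if regions is None:
            regions = load_gene_regions()
    df = _read_tsv(path, ["gene", "allele", "chrom", "pos", "ref", "alt", "rsid", "activity_score"])

    tables: dict[str, AlleleDefinitionTable] = {}
    for gene in df["gene"].drop_duplicates():
        sub = df[df["gene"] == gene]
        order: list[str] = []
        variants: dict[str, list[VariantKey]] = {}
        scores: dict[str, float | None] = {}
        declared_empty: set[str] = set()
        for row in sub.itertuples():
            name = row.allele
            score = float(row.activity_score) if row.activity_score != "" else None
            if name not in order:
                order.append(name)
                variants[name] = []
                scores[name] = score
            else:
                if scores[name] != score and not (
                    scores[name] is None and score is None
                ):
                    raise FormatError(
                        f"{gene} {name}: conflicting activity scores across rows"
                    )
            if row.chrom == "" and row.pos == "":
                if name in declared_empty or variants[name]:
                    raise FormatError(f"{gene}: allele {name} listed more than once")
                declared_empty.add(name)
                continue
            if name in declared_empty:
                raise FormatError(f"{gene}: allele {name} listed more than once")
            key = VariantKey(
                row.chrom, int(row.pos), row.ref, row.alt, row.rsid or None
            )
            if key in variants[name]:
                raise FormatError(
                    f"{gene} {name}: duplicate defining variant {key.chrom}:{key.pos} {key.ref}>{key.alt}"
                )
            variants[name].append(key)

        alleles = [
            StarAlleleDef(gene, name, frozenset(variants[name]), scores[name])
            for name in order
        ]
        region = regions.get(gene) if regions else None
        if region is None:
            sites = [v for name in order for v in variants[name]]
            if sites:
                region = (sites[0].chrom, min(v.pos for v in sites) - 2000, max(v.pos for v in sites) + 2000)
        tables[gene] = AlleleDefinitionTable(
            gene,
            alleles,
            region=region,
            deletion_allele_name=DELETION_ALLELE_NAMES.get(gene, DEFAULT_DELETION_ALLELE),
        )
    return tables


def load_translation_tables(path: str | Path | None = None) -> dict[str, TranslationTable]:
    path = bundled_path("translation_tables.tsv") if path is None else path
    df = _read_tsv(path, ["gene", "allele1", "allele2", "phenotype"])
    tables: dict[str, TranslationTable] = {}
    for row in df.itertuples():
        if row.phenotype not in PHENOTYPE_VOCABULARY:
            raise ValidationError(f"{path}: phenotype label {row.phenotype!r} not in controlled vocabulary")
        table = tables.setdefault(row.gene, TranslationTable(row.gene, {}))
        key = TranslationTable.key(row.allele1, row.allele2)
        existing = table.entries.get(key)
        if existing is not None and existing != row.phenotype:
            raise ValidationError(
                f"{row.gene}: conflicting phenotypes for unordered pair {key}: "
                f"{existing!r} vs {row.phenotype!r}"
            )
        table.entries[key] = row.phenotype
    return tables


def load_ehr_risk_tables(
    path: str | Path | None = None, known_genes: Iterable[str] | None = None
) -> dict[str, EhrRiskTable]:
    path = bundled_path("ehr_risk.tsv") if path is None else path
    df = _read_tsv(path, ["gene", "phenotype", "high_risk", "priority_label"])
    known = set(known_genes) if known_genes is not None else None
    tables: dict[str, EhrRiskTable] = {}
    for row in df.itertuples():
        if known is not None and row.gene not in known:
            raise ValidationError(f"{path}: unknown gene symbol {row.gene!r}")
        if row.phenotype not in PHENOTYPE_VOCABULARY:
            raise ValidationError(f"{path}: phenotype label {row.phenotype!r} not in controlled vocabulary")
        table = tables.setdefault(row.gene, EhrRiskTable(row.gene, set(), {}))
        table.priority_labels[row.phenotype] = row.priority_label
        if row.high_risk not in {"0", "1"}:
            raise FormatError(f"{path}: high_risk must be 0/1, got {row.high_risk!r}")
        if row.high_risk == "1":
            table.high_risk_phenotypes.add(row.phenotype)
    return tables


def load_drug_gene_pairs(
    path: str | Path | None = None, known_genes: Iterable[str] | None = None
) -> list[DrugGenePair]:
    path = bundled_path("drug_gene_pairs.tsv") if path is None else path
    df = _read_tsv(path, ["drug", "gene", "level"])
    known = set(known_genes) if known_genes is not None else None
    pairs: list[DrugGenePair] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples():
        drug = row.drug.strip().lower()
        if known is not None and row.gene not in known:
            raise ValidationError(f"{path}: unknown gene symbol {row.gene!r}")
        if (drug, row.gene) in seen:
            raise FormatError(f"{path}: duplicate drug-gene pair ({drug}, {row.gene})")
        seen.add((drug, row.gene))
        pairs.append(DrugGenePair(drug, row.gene, row.level))
    return pairs


def load_drug_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Brand/misspelling -> generic drug-name map (all lower case)."""
    path = bundled_path("drug_synonyms.tsv") if path is None else path
    df = _read_tsv(path, ["name", "generic"])
    return {r.name.strip().lower(): r.generic.strip().lower() for r in df.itertuples()}


# ---------------------------------------------------------------------------
# writing (round-trip support; loading is idempotent through these writers)


def write_allele_definitions(tables: Mapping[str, AlleleDefinitionTable], path: str | Path) -> None:
    rows = []
    for gene in tables:
        for allele in tables[gene].alleles:
            score = "" if allele.activity_score is None else repr(allele.activity_score)
            if allele.defining_variants:
                for v in sorted(allele.defining_variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
                    rows.append((gene, allele.name, v.chrom, v.pos, v.ref, v.alt, v.rsid or "", score))
            else:
                rows.append((gene, allele.name, "", "", "", "", "", score))
    pd.DataFrame(
        rows, columns=["gene", "allele", "chrom", "pos", "ref", "alt", "rsid", "activity_score"]
    ).to_csv(path, sep="\t", index=False)


def write_translation_tables(tables: Mapping[str, TranslationTable], path: str | Path) -> None:
    rows = [
        (gene, a1, a2, phen)
        for gene in tables
        for (a1, a2), phen in sorted(tables[gene].entries.items())
    ]
    pd.DataFrame(rows, columns=["gene", "allele1", "allele2", "phenotype"]).to_csv(
        path, sep="\t", index=False
    )
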