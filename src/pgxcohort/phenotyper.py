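"""Diplotype -> predicted phenotype translation.

Three rule families, applied per gene:

* **table** — the curated diplotype-phenotype translation table, looked up
  symmetrically; a diplotype absent from the table is ``Unknown``;
* **activity score** (CYP2D6 only) — the phenotype follows the sum of the two
  alleles' activity scores, because many observed CYP2D6 diplotypes are not
  tabulated.  An ``xN`` duplication multiplies the base allele's AS by N;
  composite alleles carry their own AS.  Consensus bins: total 0 -> Poor,
  (0, 1.25) -> Intermediate, [1.25, 2.25] -> Normal, > 2.25 -> Ultrarapid;
  any allele without an AS makes the diplotype Indeterminate;
* **warfarin rule** (CYP4F2, VKORC1) — no translation tables exist for these
  genes; carriers of one or two copies of CYP4F2 *3 get the higher-warfarin-
  dose phenotype and carriers of VKORC1 *2 the decreased-warfarin-dose
  phenotype, the two flags being independent.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .reference_data import AlleleDefinitionTable, TranslationTable
from .util import canonical_pair, diplotype_string, parse_multiplier

__all__ = [
    "PhenotypeAssignment",
    "activity_score_of",
    "cyp2d6_phenotype",
    "translate_diplotype",
    "warfarin_phenotype",
    "phenotype_cohort",
    "AS_GENE",
]

#: the one gene phenotyped by activity-score sum when the table misses
AS_GENE = "CYP2D6"

PHENOTYPE_RANK = {
    "Poor Metabolizer": 0,
    "Intermediate Metabolizer": 1,
    "Normal Metabolizer": 2,
    "Ultrarapid Metabolizer": 3,
}


@dataclass(frozen=True)
class PhenotypeAssignment:
    sample: str
    gene: str
    diplotype: str
    phenotype: str
    method: str  # table | activity_score | warfarin_rule | unknown
    activity_score_total: float | None = None


def activity_score_of(label: str, as_map: Mapping[str, float | None]) -> float | None:
    """AS of one haplotype label; xN multiplies the base allele's AS by N."""
    base, mult = parse_multiplier(label)
    if base in as_map:
        score = as_map[base]
    elif label in as_map:
        score, mult = as_map[label], 1
    else:
        raise KeyError(f"allele {label} has no activity-score entry")
    return None if score is None else score * mult


def _as_bin(total: float) -> str:
    if total == 0:
        return "Poor Metabolizer"
    if total < 1.25:
        return "Intermediate Metabolizer"
    if total <= 2.25:
        return "Normal Metabolizer"
    return "Ultrarapid Metabolizer"


def cyp2d6_phenotype(
    diplotype: tuple[str, str] | str,
    as_map: Mapping[str, float | None],
    sample: str = "",
) -> PhenotypeAssignment:
    """Phenotype from the CYP2D6 activity-score sum."""
    pair = tuple(diplotype.split("/")) if isinstance(diplotype, str) else tuple(diplotype)
    scores = [activity_score_of(a, as_map) for a in pair]
    dip = diplotype_string(*canonical_pair(*pair))
    if any(s is None for s in scores):
        return PhenotypeAssignment(sample, AS_GENE, dip, "Indeterminate", "activity_score", None)
    total = float(sum(scores))  # type: ignore[arg-type]
    return PhenotypeAssignment(sample, AS_GENE, dip, _as_bin(total), "activity_score", total)


def translate_diplotype(
    gene: str,
    diplotype: tuple[str, str] | str,
    table: TranslationTable,
    as_map: Mapping[str, float | None] | None = None,
    sample: str = "",
) -> PhenotypeAssignment:
    """Symmetric table lookup; a miss is ``Unknown`` except for CYP2D6, which
    falls back to the activity-score sum."""
    pair = tuple(diplotype.split("/")) if isinstance(diplotype, str) else tuple(diplotype)
    dip = diplotype_string(*canonical_pair(*pair))
    phen = table.lookup(*pair)
    if phen is not None:
        return PhenotypeAssignment(sample, gene, dip, phen, "table", None)
    if gene == AS_GENE and as_map is not None:
        return cyp2d6_phenotype(pair, as_map, sample=sample)
    return PhenotypeAssignment(sample, gene, dip, "Unknown", "unknown", None)


def _carries(pair: tuple[str, str], allele: str) -> bool:
    return any(parse_multiplier(a)[0] == allele for a in pair)


def warfarin_phenotype(
    cyp4f2_diplotype: tuple[str, str] | str,
    vkorc1_diplotype: tuple[str, str] | str,
) -> tuple[str, str]:
    """Warfarin dose-phenotype flags for (CYP4F2, VKORC1), independently.

    One or two copies of CYP4F2 *3 -> higher dose requirement; one or two
    copies of VKORC1 *2 -> decreased dose (warfarin sensitivity).
    """
    p4f2 = tuple(cyp4f2_diplotype.split("/")) if isinstance(cyp4f2_diplotype, str) else tuple(cyp4f2_diplotype)
    pvk = tuple(vkorc1_diplotype.split("/")) if isinstance(vkorc1_diplotype, str) else tuple(vkorc1_diplotype)
    cyp4f2 = "Higher Warfarin Dose" if _carries(p4f2, "*3") else "Normal Warfarin Dose"
    vkorc1 = "Decreased Warfarin Dose" if _carries(pvk, "*2") else "Normal Warfarin Dose"
    return cyp4f2, vkorc1


def phenotype_cohort(
    calls: pd.DataFrame,
    tables: Mapping[str, TranslationTable],
    defs: Mapping[str, AlleleDefinitionTable],
    warfarin_genes: tuple[str, str] = ("CYP4F2", "VKORC1"),
) -> pd.DataFrame:
    """One phenotype assignment per (sample, gene) row of a call table.

    Requires a translation table for every called gene except CYP2D6 (AS
    fallback) and the two warfarin-rule genes.
    """
    for gene in calls["gene"].unique():
        if gene not in tables and gene != AS_GENE and gene not in warfarin_genes:
            raise KeyError(f"no translation table for called gene {gene}")
    rows = []
    for row in calls.itertuples():
        pair = (row.allele1, row.allele2)
        if row.gene in warfarin_genes:
            if row.gene == "CYP4F2":
                phen = warfarin_phenotype(pair, ("*1", "*1"))[0]
            else:
                phen = warfarin_phenotype(("*1", "*1"), pair)[1]
            assignment = PhenotypeAssignment(
                row.sample, row.gene, diplotype_string(*pair), phen, "warfarin_rule", None
            )
        else:
            as_map = defs[row.gene].activity_scores() if row.gene == AS_GENE else None
            table = tables.get(row.gene, TranslationTable(row.gene, {}))
            assignment = translate_diplotype(
                row.gene, pair, table, as_map=as_map, sample=row.sample
            )
        rows.append(
            {
                "sample": assignment.sample,
                "gene": assignment.gene,
                "diplotype": assignment.diplotype,
                "phenotype": assignment.phenotype,
                "method": assignment.method,
                "activity_score_total": assignment.activity_score_total,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "gene", "diplotype", "phenotype", "method", "activity_score_total"],
    )
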