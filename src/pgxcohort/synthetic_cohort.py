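"""Synthetic pharmacogenomic cohort generator.

Emulates the statistical structure of a population-based elderly cohort so
the calling/phenotyping/risk pipeline can be exercised end to end without
restricted individual-level data:

* per-gene diplotypes drawn either from haplotype frequencies under
  Hardy-Weinberg equilibrium (two independent draws) or from an explicit
  diplotype distribution (one joint draw);
* a phased multi-sample VCF carrying each haplotype's defining variants;
* a per-position read-depth table in which whole-gene deletions and
  duplications leave their copy-number signal (0.5x per deleted haplotype,
  1.5x for one duplicated haplotype), normalized against a diploid control
  region, with Gaussian noise;
* medication lists drawn independently per drug, a configurable fraction of
  individuals with missing medication data, and census-style demographics.

What it deliberately does not model: linkage between genes, sequence reads,
partial-gene structural variants, ancestry segments, genotype-medication
correlation, dosage or adherence.
"""
from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .reference_data import (
    CONTROL_REGION,
    AlleleDefinitionTable,
    bundled_path,
)
from .util import canonical_pair, parse_multiplier

__all__ = [
    "CohortConfig",
    "SimulatedIndividual",
    "ConfigurationError",
    "sample_cohort",
    "sample_medications",
    "emit_phased_vcf",
    "emit_depth",
    "write_demographics_csv",
    "write_medications_csv",
    "hwe_diplotype_probs",
    "haplotype_copies",
]

_FREQ_TOL = 1e-9


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class CohortConfig:
    """Simulation parameters; every random choice derives from ``seed``."""

    n: int
    seed: int
    haplotype_frequencies: dict[str, dict[str, float]] = field(default_factory=dict)
    #: genes listed here are drawn jointly from a diplotype distribution
    #: ("a/b" keys) instead of two independent HWE haplotype draws
    diplotype_frequencies: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_coverage: float = 30.0
    depth_sd: float = 3.0
    positions_per_gene: int = 16
    drug_frequencies: dict[str, float] = field(default_factory=dict)
    missing_medication_fraction: float = 0.0
    #: expected count of background (non-level-1A) drugs per individual,
    #: giving realistic total drug counts / polypharmacy rates
    background_drug_rate: float = 0.0
    demographics: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigurationError("n must be >= 0")
        if self.mean_coverage <= 0:
            raise ConfigurationError("mean_coverage must be > 0")
        for gene, freqs in {**self.haplotype_frequencies, **self.diplotype_frequencies}.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > _FREQ_TOL:
                raise ConfigurationError(f"{gene}: frequencies sum to {total}, not 1")
            for label, p in freqs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"{gene} {label}: probability {p} outside [0,1]")
        for drug, p in self.drug_frequencies.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"drug {drug}: probability {p} outside [0,1]")
        if not 0.0 <= self.missing_medication_fraction <= 1.0:
            raise ConfigurationError("missing_medication_fraction outside [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CohortConfig":
        if "seed" not in raw:
            raise ConfigurationError("config must declare a seed")
        cfg = cls(
            n=int(raw["n"]),
            seed=int(raw["seed"]),
            haplotype_frequencies=dict(raw.get("haplotype_frequencies", {})),
            diplotype_frequencies=dict(raw.get("diplotype_frequencies", {})),
            mean_coverage=float(raw.get("mean_coverage", 30.0)),
            depth_sd=float(raw.get("depth_sd", 3.0)),
            positions_per_gene=int(raw.get("positions_per_gene", 16)),
            drug_frequencies=dict(raw.get("drug_frequencies", {})),
            missing_medication_fraction=float(raw.get("missing_medication_fraction", 0.0)),
            background_drug_rate=float(raw.get("background_drug_rate", 0.0)),
            demographics=dict(raw.get("demographics", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def default(cls, **overrides) -> "CohortConfig":
        """The packaged default: a 1,171-individual elderly urban cohort."""
        with open(bundled_path("default_config.yaml")) as fh:
            raw = yaml.safe_load(fh)
        raw.update(overrides)
        return cls.from_dict(raw)


@dataclass
class SimulatedIndividual:
    id: str
    sex: str
    age: int
    color_race: str
    true_diplotypes: dict[str, tuple[str, str]]
    medications: list[str] = field(default_factory=list)
    missing_medications: bool = False


def haplotype_copies(label: str, deletion_name: str) -> int:
    """Gene copies contributed by one haplotype label (deletion 0, xN -> N)."""
    base, mult = parse_multiplier(label)
    if base == deletion_name or base == "*DEL":
        return 0
    return mult


def hwe_diplotype_probs(freqs: Mapping[str, float]) -> dict[tuple[str, str], float]:
    """Closed-form diplotype distribution under HWE: p_i * p_j * (2 - delta_ij)."""
    labels = sorted(freqs)
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i:]:
            p = freqs[a] * freqs[b] * (1 if a == b else 2)
            out[canonical_pair(a, b)] = out.get(canonical_pair(a, b), 0.0) + p
    return out


def _check_alleles_defined(
    config: CohortConfig, defs: Mapping[str, AlleleDefinitionTable]
) -> None:
    for gene, freqs in config.haplotype_frequencies.items():
        if gene not in defs:
            raise ConfigurationError(f"gene {gene} has no allele definition table")
        for label in freqs:
            base, _ = parse_multiplier(label)
            if base not in defs[gene] and base != defs[gene].deletion_allele_name and base != "*DEL":
                raise ConfigurationError(f"{gene}: allele {label} not in definition table")
    for gene, freqs in config.diplotype_frequencies.items():
        if gene not in defs:
            raise ConfigurationError(f"gene {gene} has no allele definition table")
        for dip in freqs:
            for label in dip.split("/"):
                base, _ = parse_multiplier(label)
                if base not in defs[gene] and base != defs[gene].deletion_allele_name and base != "*DEL":
                    raise ConfigurationError(f"{gene}: allele {label} not in definition table")


def sample_cohort(
    config: CohortConfig, defs: Mapping[str, AlleleDefinitionTable]
) -> list[SimulatedIndividual]:
    """Draw demographics and per-gene true diplotypes for ``config.n`` individuals."""
    config.validate()
    _check_alleles_defined(config, defs)
    n = config.n
    demo = config.demographics or {}

    rng_demo = np.random.default_rng([config.seed, 0])
    sex_probs = demo.get("sex", {"F": 0.635, "M": 0.365})
    sex_labels = sorted(sex_probs)
    sexes = rng_demo.choice(sex_labels, size=n, p=[sex_probs[k] for k in sex_labels])
    race_probs = demo.get("color_race", {"White": 1.0})
    race_labels = sorted(race_probs)
    races = rng_demo.choice(race_labels, size=n, p=[race_probs[k] for k in race_labels])
    shape = float(demo.get("age_gamma_shape", 1.4))
    scale = float(demo.get("age_gamma_scale", 10.0))
    age_min = int(demo.get("age_minimum", 60))
    ages = age_min + np.floor(rng_demo.gamma(shape, scale, size=n)).astype(int)

    width = max(4, len(str(n)))
    cohort = [
        SimulatedIndividual(
            id=f"S{i + 1:0{width}d}",
            sex=str(sexes[i]),
            age=int(ages[i]),
            color_race=str(races[i]),
            true_diplotypes={},
        )
        for i in range(n)
    ]

    rng_geno = np.random.default_rng([config.seed, 1])
    genes = sorted(set(config.haplotype_frequencies) | set(config.diplotype_frequencies))
    for gene in genes:
        if gene in config.diplotype_frequencies:
            freqs = config.diplotype_frequencies[gene]
            dips = sorted(freqs)
            draws = rng_geno.choice(len(dips), size=n, p=[freqs[d] for d in dips])
            for i, k in enumerate(draws):
                a, b = dips[k].split("/")
                cohort[i].true_diplotypes[gene] = canonical_pair(a, b)
        else:
            freqs = config.haplotype_frequencies[gene]
            labels = sorted(freqs)
            p = [freqs[x] for x in labels]
            draws = rng_geno.choice(len(labels), size=(n, 2), p=p)
            for i in range(n):
                a, b = labels[draws[i, 0]], labels[draws[i, 1]]
                cohort[i].true_diplotypes[gene] = canonical_pair(a, b)
    return cohort


def sample_medications(
    config: CohortConfig, cohort: Sequence[SimulatedIndividual]
) -> list[SimulatedIndividual]:
    """Attach medication lists: each listed drug independently Bernoulli, plus
    a Poisson count of unlisted background drugs; a configured fraction of
    individuals has missing medication data (and then an empty list)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    drugs = sorted(config.drug_frequencies)
    n = len(cohort)
    missing = rng.random(n) < config.missing_medication_fraction
    takes = {d: rng.random(n) < config.drug_frequencies[d] for d in drugs}
    background = (
        rng.poisson(config.background_drug_rate, size=n)
        if config.background_drug_rate > 0
        else np.zeros(n, dtype=int)
    )
    out = []
    for i, ind in enumerate(cohort):
        if missing[i]:
            meds: list[str] = []
        else:
            meds = [d for d in drugs if takes[d][i]]
            meds += [f"unlisted_{k + 1}" for k in range(background[i])]
        out.append(replace(copy.deepcopy(ind), medications=meds, missing_medications=bool(missing[i])))
    return out


# ---------------------------------------------------------------------------
# signal emission


class EmissionError(ValueError):
    """A sampled diplotype cannot be rendered into VCF signal (composites)."""


def _chrom_order(chrom: str) -> tuple[int, str]:
    m = re.match(r"^chr(\d+)$", chrom)
    return (int(m.group(1)), chrom) if m else (10**6, chrom)


def _haplotype_variants(label: str, table: AlleleDefinitionTable):
    base, _ = parse_multiplier(label)
    if base == table.deletion_allele_name or base == "*DEL":
        return frozenset()
    allele = table.get(base)
    if allele.is_composite:
        raise EmissionError(
            f"{table.gene} {label}: composite alleles carry no defining-variant set "
            "and cannot be emitted to VCF"
        )
    return allele.defining_variants


def emit_phased_vcf(
    cohort: Sequence[SimulatedIndividual],
    defs: Mapping[str, AlleleDefinitionTable],
    path: str | Path,
) -> Path:
    """Write one phased multi-sample VCF (v4.2, hg19) for the whole cohort.

    Haplotype 1 of each sample carries allele 1's defining variants, haplotype
    2 allele 2's.  Deleted haplotypes emit reference genotypes: the deletion
    signal lives in the depth table, not in the VCF.
    """
    path = Path(path)
    genes = sorted({g for ind in cohort for g in ind.true_diplotypes})
    sites: list[tuple[str, object]] = []
    seen = set()
    for gene in genes:
        for v in defs[gene].all_variants():
            key = (v.chrom, v.pos, v.ref, v.alt)
            if key not in seen:
                seen.add(key)
                sites.append((gene, v))
    sites.sort(key=lambda gv: (_chrom_order(gv[1].chrom), gv[1].pos, gv[1].ref, gv[1].alt))

    # per sample, per gene: the two haplotype variant sets
    hap_sets = []
    for ind in cohort:
        per_gene = {}
        for gene, (a1, a2) in ind.true_diplotypes.items():
            table = defs[gene]
            per_gene[gene] = (_haplotype_variants(a1, table), _haplotype_variants(a2, table))
        hap_sets.append(per_gene)

    contigs = sorted({v.chrom for _, v in sites}, key=_chrom_order)
    lines = ["##fileformat=VCFv4.2", "##source=pgxcohort-synthetic", "##reference=hg19"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += [ind.id for ind in cohort]
    lines.append("\t".join(header))
    for gene, v in sites:
        row = [v.chrom, str(v.pos), v.rsid or ".", v.ref, v.alt, ".", "PASS", ".", "GT"]
        for per_gene in hap_sets:
            h1, h2 = per_gene.get(gene, (frozenset(), frozenset()))
            row.append(f"{int(v in h1)}|{int(v in h2)}")
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def emit_depth(
    cohort: Sequence[SimulatedIndividual],
    defs: Mapping[str, AlleleDefinitionTable],
    config: CohortConfig,
    path: str | Path,
) -> Path:
    """Write the per-position read-depth TSV (chrom, pos, one column per sample).

    Expected depth scales with whole-gene copy number: a CN2 gene sits at
    1.0x ``mean_coverage``, each deleted haplotype removes 0.5x, a duplicated
    haplotype adds 0.5x.  Rows for the diploid control region are appended;
    the caller normalizes each sample against its own control mean.
    """
    config.validate()
    path = Path(path)
    rng = np.random.default_rng([config.seed, 3])
    genes = sorted({g for ind in cohort for g in ind.true_diplotypes})
    blocks: list[tuple[str, np.ndarray, np.ndarray]] = []  # chrom, positions, ratios per sample
    for gene in genes:
        table = defs[gene]
        if table.region is None:
            raise EmissionError(f"{gene}: no genomic region declared; cannot emit depth")
        chrom, start, end = table.region
        positions = np.unique(np.linspace(start, end, config.positions_per_gene).astype(int))
        cn = np.array(
            [
                sum(haplotype_copies(a, table.deletion_allele_name) for a in ind.true_diplotypes[gene])
                for ind in cohort
            ],
            dtype=float,
        )
        blocks.append((chrom, positions, cn / 2.0))
    chrom, start, end = CONTROL_REGION
    positions = np.unique(np.linspace(start, end, config.positions_per_gene).astype(int))
    blocks.append((chrom, positions, np.ones(len(cohort))))

    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(ind.id for ind in cohort) + "\n")
        for chrom, positions, ratio in blocks:
            for pos in positions:
                noise = (
                    rng.normal(0.0, config.depth_sd, size=len(cohort))
                    if config.depth_sd > 0
                    else np.zeros(len(cohort))
                )
                depth = np.clip(config.mean_coverage * ratio + noise, 0.0, None)
                fh.write(
                    f"{chrom}\t{pos}\t" + "\t".join(f"{d:.4f}" for d in depth) + "\n"
                )
    return path


def write_demographics_csv(cohort: Sequence[SimulatedIndividual], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id,sex,age,color_race\n")
        for ind in cohort:
            fh.write(f"{ind.id},{ind.sex},{ind.age},{ind.color_race}\n")
    return path


def write_medications_csv(cohort: Sequence[SimulatedIndividual], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id,drugs,missing\n")
        for ind in cohort:
            fh.write(f"{ind.id},{';'.join(ind.medications)},{int(ind.missing_medications)}\n")
    return path
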