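"""Star-allele and copy-number calling from phased variants plus read depth.

The caller mirrors the standard architecture of star-allele genotypers:

1. split each sample's phased genotypes into two per-gene haplotypes;
2. match each haplotype to the star allele whose defining-variant set is the
   largest subset of the haplotype's variants (maximal-subset rule; ties go
   to the earlier allele in the definition table; an empty haplotype or no
   candidate falls back to the reference allele);
3. estimate whole-gene copy number from depth normalized against a diploid
   control region (cn = clamp(round(2 * median ratio), 0, 3));
4. combine the two into a diplotype, rewriting haplotypes as the deletion
   allele (cn 0/1) or adding an "x2" duplication suffix (cn 3).

Phased input is required: an unphased genotype is a hard error rather than a
guess.  Indels must be left-normalized so they match definition rows exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .reference_data import (
    CONTROL_REGION,
    AlleleDefinitionTable,
    VariantKey,
    normalize_chrom,
)
from .util import canonical_pair, diplotype_string

__all__ = [
    "PhasedHaplotype",
    "CopyNumberCall",
    "DiplotypeCall",
    "PhasingError",
    "DepthError",
    "extract_haplotypes",
    "normalize_depth",
    "estimate_copy_number",
    "match_haplotype",
    "call_diplotype",
    "call_cohort",
]


class PhasingError(ValueError):
    """An unphased genotype was encountered where phase is required."""


class DepthError(ValueError):
    """Control or gene depth is unusable for copy-number estimation."""


@dataclass(frozen=True)
class PhasedHaplotype:
    sample: str
    gene: str
    index: int  # 1 or 2
    variants: frozenset[VariantKey]


@dataclass(frozen=True)
class CopyNumberCall:
    sample: str
    gene: str
    cn: int
    mean_ratio: float


@dataclass(frozen=True)
class DiplotypeCall:
    sample: str
    gene: str
    allele1: str
    allele2: str
    cn: int
    exact1: bool = True
    exact2: bool = True

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.allele1, self.allele2)
        if (a, b) != (self.allele1, self.allele2):
            e1, e2 = self.exact2, self.exact1
            object.__setattr__(self, "allele1", a)
            object.__setattr__(self, "allele2", b)
            object.__setattr__(self, "exact1", e1)
            object.__setattr__(self, "exact2", e2)

    @property
    def diplotype(self) -> str:
        return diplotype_string(self.allele1, self.allele2)


def extract_haplotypes(
    vcf_path: str | Path,
    gene_region: tuple[str, int, int],
    gene: str = "",
) -> dict[str, tuple[PhasedHaplotype, PhasedHaplotype]]:
    """Split phased genotypes in ``gene_region`` into two variant sets per sample.

    Haplotype k holds exactly the sites where allele k of the phased GT is
    non-reference.  Any unphased genotype raises :class:`PhasingError` naming
    the sample and site.
    """
    chrom, start, end = gene_region
    chrom = normalize_chrom(chrom)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    hap_vars: list[tuple[set, set]] = [(set(), set()) for _ in samples]
    for rec in vcf:
        if normalize_chrom(rec.CHROM) != chrom or not (start <= rec.POS <= end):
            continue
        for si, gt in enumerate(rec.genotypes):
            if len(gt) < 3:
                raise PhasingError(
                    f"sample {samples[si]} at {rec.CHROM}:{rec.POS}: non-diploid genotype"
                )
            *alleles, phased = gt
            if not phased:
                raise PhasingError(
                    f"sample {samples[si]} at {rec.CHROM}:{rec.POS}: unphased genotype"
                )
            for hap_index, allele_idx in enumerate(alleles[:2]):
                if allele_idx > 0:
                    key = VariantKey(
                        rec.CHROM, rec.POS, rec.REF, rec.ALT[allele_idx - 1], rec.ID
                    )
                    hap_vars[si][hap_index].add(key)
    vcf.close()
    return {
        s: (
            PhasedHaplotype(s, gene, 1, frozenset(hap_vars[si][0])),
            PhasedHaplotype(s, gene, 2, frozenset(hap_vars[si][1])),
        )
        for si, s in enumerate(samples)
    }


def normalize_depth(
    depth_profile: Sequence[float] | pd.Series,
    control_profile: Sequence[float] | pd.Series | float,
) -> np.ndarray:
    """Intrasample normalization: per-position depth over the sample's mean
    control-region depth, so a diploid (CN2) gene sits at ratio 1.0."""
    control_mean = float(np.mean(control_profile))
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise DepthError("control coverage is zero or absent; cannot normalize")
    return np.asarray(depth_profile, dtype=float) / control_mean


def estimate_copy_number(
    ratio_profile: Sequence[float] | np.ndarray,
    sample: str = "",
    gene: str = "",
) -> CopyNumberCall:
    """Whole-gene copy number from a normalized ratio profile.

    cn = clamp(round(2 * median ratio), 0, 3), rounding .5 away from zero.
    """
    ratios = np.asarray(ratio_profile, dtype=float)
    if ratios.size == 0:
        raise DepthError("empty ratio profile")
    med = float(np.median(ratios))
    cn = int(np.floor(2.0 * med + 0.5))  # half away from zero (ratios are >= 0)
    cn = max(0, min(3, cn))
    return CopyNumberCall(sample, gene, cn, med)


def match_haplotype(
    hap: PhasedHaplotype | Iterable[VariantKey],
    table: AlleleDefinitionTable,
) -> tuple[str, bool]:
    """Assign a star allele to one haplotype by the maximal-subset rule.

    Returns ``(allele name, exact)``: candidates are alleles whose defining
    variants are a subset of the haplotype's variants; the candidate with the
    most defining variants wins, ties broken by table order; no candidate (or
    an empty haplotype) yields the reference allele.  ``exact`` is True iff
    the winner's defining set equals the haplotype's variant set — residual
    unmatched variants demote the flag but never fail the call.
    """
    variants = hap.variants if isinstance(hap, PhasedHaplotype) else frozenset(hap)
    best: str | None = None
    best_size = -1
    for allele in table.alleles:
        if allele.is_composite:
            continue
        if allele.defining_variants <= variants and len(allele.defining_variants) > best_size:
            best = allele.name
            best_size = len(allele.defining_variants)
    if best is None:
        best = table.reference_allele.name
        best_size = 0
    return best, best_size == len(variants)


def call_diplotype(
    hap1: PhasedHaplotype,
    hap2: PhasedHaplotype,
    cn_call: CopyNumberCall | int,
    table: AlleleDefinitionTable,
) -> DiplotypeCall:
    """Combine two matched haplotypes and a copy-number call into a diplotype.

    cn 2: both matches stand.  cn 0: homozygous deletion.  cn 1: the deletion
    allele replaces the haplotype with fewer non-reference variants (tie:
    haplotype 2), since read evidence cannot place the deletion.  cn 3: the
    "x2" suffix goes to the unique non-reference allele if there is one,
    otherwise to haplotype 1; when both haplotypes are non-reference and
    distinct the attribution is ambiguous and the exact flag is cleared.
    """
    cn = cn_call.cn if isinstance(cn_call, CopyNumberCall) else int(cn_call)
    if not 0 <= cn <= 3:
        raise ValueError(f"copy number {cn} outside supported range [0, 3]")
    sample, gene = hap1.sample, hap1.gene
    a1, exact1 = match_haplotype(hap1, table)
    a2, exact2 = match_haplotype(hap2, table)
    dele = table.deletion_allele_name
    ref = table.reference_allele.name

    if cn == 0:
        return DiplotypeCall(sample, gene, dele, dele, cn)
    if cn == 1:
        if len(hap1.variants) < len(hap2.variants):
            return DiplotypeCall(sample, gene, dele, a2, cn, True, exact2)
        return DiplotypeCall(sample, gene, a1, dele, cn, exact1, True)
    if cn == 3:
        nonref = [k for k, a in ((1, a1), (2, a2)) if a != ref]
        if len(nonref) == 1:
            if nonref[0] == 1:
                return DiplotypeCall(sample, gene, a1 + "x2", a2, cn, exact1, exact2)
            return DiplotypeCall(sample, gene, a1, a2 + "x2", cn, exact1, exact2)
        ambiguous = len(nonref) == 2 and a1 != a2
        return DiplotypeCall(
            sample, gene, a1 + "x2", a2, cn, exact1 and not ambiguous, exact2
        )
    return DiplotypeCall(sample, gene, a1, a2, cn, exact1, exact2)


def call_cohort(
    vcf_path: str | Path,
    depth_path: str | Path,
    defs: Mapping[str, AlleleDefinitionTable],
) -> pd.DataFrame:
    """Run the full caller over a cohort: one diplotype row per (sample, gene).

    The VCF and depth table must describe the same samples (order may differ).
    Output is sorted by (sample, gene), so it is invariant to record and
    sample ordering in the inputs.
    """
    depth = pd.read_csv(depth_path, sep="\t")
    depth["chrom"] = depth["chrom"].map(normalize_chrom)
    depth_samples = [c for c in depth.columns if c not in ("chrom", "pos")]
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    vcf.close()
    if set(depth_samples) != set(vcf_samples):
        only_vcf = sorted(set(vcf_samples) - set(depth_samples))
        only_depth = sorted(set(depth_samples) - set(vcf_samples))
        raise ValueError(
            f"sample mismatch between VCF and depth table: VCF-only {only_vcf}, depth-only {only_depth}"
        )

    cchrom, cstart, cend = CONTROL_REGION
    control = depth[
        (depth["chrom"] == cchrom) & depth["pos"].between(cstart, cend)
    ]
    if control.empty:
        raise DepthError("depth table has no control-region rows")
    control_means = {s: float(control[s].mean()) for s in depth_samples}

    rows = []
    for gene in sorted(defs):
        table = defs[gene]
        if table.region is None:
            raise DepthError(f"{gene}: no genomic region declared")
        chrom, start, end = table.region
        haps = extract_haplotypes(vcf_path, table.region, gene)
        gene_depth = depth[(depth["chrom"] == chrom) & depth["pos"].between(start, end)]
        if gene_depth.empty:
            raise DepthError(f"{gene}: no depth rows in {chrom}:{start}-{end}")
        for sample in sorted(depth_samples):
            ratios = normalize_depth(gene_depth[sample], control_means[sample])
            cn_call = estimate_copy_number(ratios, sample, gene)
            hap1, hap2 = haps[sample]
            call = call_diplotype(hap1, hap2, cn_call, table)
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "allele1": call.allele1,
                    "allele2": call.allele2,
                    "diplotype": call.diplotype,
                    "cn": call.cn,
                    "exact1": call.exact1,
                    "exact2": call.exact2,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["sample", "gene", "allele1", "allele2", "diplotype", "cn", "exact1", "exact2"],
    )
    return out.sort_values(["sample", "gene"], ignore_index=True)
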