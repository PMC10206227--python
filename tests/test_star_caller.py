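"""Haplotype matching, copy-number estimation and diplotype calling."""
import itertools

import numpy as np
import pandas as pd
import pytest

from pgxcohort import reference_data as rd
from pgxcohort.star_caller import (
    DepthError,
    PhasedHaplotype,
    PhasingError,
    call_cohort,
    call_diplotype,
    estimate_copy_number,
    extract_haplotypes,
    match_haplotype,
    normalize_depth,
)
from pgxcohort.synthetic_cohort import (
    CohortConfig,
    emit_depth,
    emit_phased_vcf,
    sample_cohort,
)
from pgxcohort.util import diplotype_string

from conftest import make_allele_table, write_vcf

V = [("chr1", 100 + i, "A", "G") for i in range(4)]

# three non-reference alleles over four variants; *3's set strictly contains *2's
TOY = make_allele_table(
    "TOY",
    {
        "*1": ([], 1.0),
        "*2": ([V[0]], 1.0),
        "*3": ([V[0], V[1]], 0.5),
        "*4": ([V[2]], 0.0),
    },
    region=("chr1", 1, 1000),
)


def hap(variants, index=1, sample="s", gene="TOY"):
    from pgxcohort.reference_data import VariantKey

    return PhasedHaplotype(sample, gene, index, frozenset(VariantKey(*v) for v in variants))


def oracle_match(variant_subset, table):
    """Exhaustive enumeration: best (largest, earliest-in-table) subset allele."""
    subset = set(variant_subset)
    best = None
    for position, allele in enumerate(table.alleles):
        if allele.is_composite:
            continue
        if set(allele.defining_variants) <= subset:
            key = (-len(allele.defining_variants), position)
            if best is None or key < best[0]:
                best = (key, allele.name)
    if best is None:
        return table.reference_allele.name
    return best[1]


class TestMatchHaplotype:
    def test_known_carrier_examples(self, defs):
        table = defs["CYP4F2"]
        (rs2108622,) = table.get("*3").defining_variants
        assert match_haplotype([rs2108622], table) == ("*3", True)
        assert match_haplotype([], table) == ("*1", True)

    def test_agrees_with_exhaustive_enumeration_on_all_subsets(self):
        from pgxcohort.reference_data import VariantKey

        keys = [VariantKey(*v) for v in V]
        for r in range(len(keys) + 1):
            for subset in itertools.combinations(keys, r):
                name, exact = match_haplotype(set(subset), TOY)
                assert name == oracle_match(subset, TOY), f"subset {subset}"
                assert exact == (
                    set(TOY.get(name).defining_variants) == set(subset)
                )

    def test_monotone_under_variant_addition(self):
        """Adding a variant never shrinks the winning allele's defining set."""
        from pgxcohort.reference_data import VariantKey

        keys = [VariantKey(*v) for v in V]
        for r in range(len(keys)):
            for subset in itertools.combinations(keys, r):
                before = len(TOY.get(match_haplotype(set(subset), TOY)[0]).defining_variants)
                for extra in keys:
                    if extra in subset:
                        continue
                    after = len(
                        TOY.get(match_haplotype(set(subset) | {extra}, TOY)[0]).defining_variants
                    )
                    assert after >= before

    def test_residual_variants_demote_exact_flag(self):
        from pgxcohort.reference_data import VariantKey

        keys = [VariantKey(*v) for v in V]
        name, exact = match_haplotype({keys[0], keys[3]}, TOY)
        assert name == "*2" and not exact


class TestExtractHaplotypes:
    def test_phased_genotype_split(self, tmp_path):
        path = write_vcf(
            tmp_path / "toy.vcf",
            ["s1", "s2"],
            [
                ("chr1", 100, "rs1", "A", "G", ["0|1", "1|1"]),
                ("chr1", 101, "rs2", "A", "G", ["0|0", "1|0"]),
            ],
        )
        haps = extract_haplotypes(path, ("chr1", 1, 1000), "TOY")
        h1, h2 = haps["s1"]
        assert {v.pos for v in h1.variants} == set()
        assert {v.pos for v in h2.variants} == {100}
        h1, h2 = haps["s2"]
        assert {v.pos for v in h1.variants} == {100, 101}
        assert {v.pos for v in h2.variants} == {100}

    def test_unphased_genotype_is_hard_error(self, tmp_path):
        path = write_vcf(
            tmp_path / "unphased.vcf",
            ["s1"],
            [("chr1", 100, "rs1", "A", "G", ["0/1"])],
        )
        with pytest.raises(PhasingError, match="s1"):
            extract_haplotypes(path, ("chr1", 1, 1000))

    def test_matches_independent_text_parse(self, tmp_path):
        rng = np.random.default_rng(0)
        records = []
        gts = {}
        for i in range(10):
            pair = (int(rng.integers(2)), int(rng.integers(2)))
            records.append(("chr1", 100 + i, f"rs{i}", "A", "G", [f"{pair[0]}|{pair[1]}"]))
            gts[100 + i] = pair
        path = write_vcf(tmp_path / "ten.vcf", ["s1"], records)
        h1, h2 = extract_haplotypes(path, ("chr1", 1, 1000))["s1"]
        # brute-force oracle: re-scan the text per haplotype allele
        expected1 = {pos for pos, (a, _) in gts.items() if a == 1}
        expected2 = {pos for pos, (_, b) in gts.items() if b == 1}
        assert {v.pos for v in h1.variants} == expected1
        assert {v.pos for v in h2.variants} == expected2


class TestCopyNumber:
    def test_normalize_depth(self):
        assert np.allclose(normalize_depth([30, 30], [30, 30]), 1.0)
        assert np.allclose(normalize_depth([0, 0], 30.0), 0.0)
        with pytest.raises(DepthError):
            normalize_depth([10.0], [0.0, 0.0])

    @pytest.mark.parametrize(
        "median_ratio, cn",
        [
            (1.0, 2),
            (0.02, 0),
            (1.52, 3),
            (0.5, 1),
            (0.75, 2),  # 2*0.75 = 1.5 rounds half away from zero
            (0.24, 0),
            (2.9, 3),  # capped at 3
        ],
    )
    def test_estimate_copy_number(self, median_ratio, cn):
        assert estimate_copy_number([median_ratio] * 5).cn == cn

    def test_empty_profile_is_error(self):
        with pytest.raises(DepthError):
            estimate_copy_number([])


class TestCallDiplotype:
    def test_homozygous_deletion(self):
        call = call_diplotype(hap([]), hap([], 2), 0, TOY)
        assert call.diplotype == "*DEL/*DEL"

    def test_reference_diplotype(self):
        call = call_diplotype(hap([]), hap([], 2), 2, TOY)
        assert call.diplotype == "*1/*1"

    def test_cn1_deletion_replaces_less_variant_haplotype(self):
        call = call_diplotype(hap([V[0]]), hap([], 2), 1, TOY)
        assert call.diplotype == "*2/*DEL"
        # tie (both empty): haplotype 2 is replaced, deterministic
        call = call_diplotype(hap([]), hap([], 2), 1, TOY)
        assert call.diplotype == "*1/*DEL"

    def test_cn3_duplication_attribution(self):
        call = call_diplotype(hap([]), hap([V[0]], 2), 3, TOY)
        assert call.diplotype == "*1/*2x2"
        assert call.exact1 and call.exact2
        # both non-reference and distinct: haplotype 1 gets x2, flagged inexact
        call = call_diplotype(hap([V[0]]), hap([V[2]], 2), 3, TOY)
        assert call.diplotype == "*2x2/*4"
        assert not (call.exact1 and call.exact2)

    def test_cn_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            call_diplotype(hap([]), hap([], 2), 4, TOY)


def simulate_and_call(defs, cfg, tmp_path, tag=""):
    cohort = sample_cohort(cfg, defs)
    genes = set(cfg.haplotype_frequencies) | set(cfg.diplotype_frequencies)
    call_defs = {g: defs[g] for g in genes}
    vcf = emit_phased_vcf(cohort, call_defs, tmp_path / f"rt{tag}.vcf")
    depth = emit_depth(cohort, call_defs, cfg, tmp_path / f"rt{tag}.tsv")
    calls = call_cohort(vcf, depth, call_defs)
    truth = {
        (ind.id, g): diplotype_string(*dip)
        for ind in cohort
        for g, dip in ind.true_diplotypes.items()
    }
    return calls, truth


class TestCallCohort:
    def test_single_sample_single_gene(self, defs, tmp_path):
        cfg = CohortConfig(
            n=1, seed=2, haplotype_frequencies={"CYP4F2": {"*3": 1.0}}, depth_sd=0.0
        )
        calls, truth = simulate_and_call(defs, cfg, tmp_path)
        assert len(calls) == 1
        assert calls.iloc[0]["diplotype"] == "*3/*3"

    def test_row_count_is_samples_times_genes(self, defs, tmp_path):
        cfg = CohortConfig.default(n=20, seed=4)
        calls, _ = simulate_and_call(defs, cfg, tmp_path)
        assert len(calls) == 20 * len(cfg.haplotype_frequencies)

    def test_round_trip_recovers_truth(self, defs, tmp_path):
        """Caller reproduces every simulated diplotype for SNV-defined alleles
        plus whole-gene deletion and unambiguous duplication events."""
        cfg = CohortConfig.default(n=200, seed=13)
        cfg.haplotype_frequencies["CYP2D6"] = {
            "*1": 0.45, "*2": 0.30, "*4": 0.09, "*10": 0.05, "*41": 0.06, "*5": 0.05
        }
        cfg.diplotype_frequencies = {
            "TPMT": {"*2x2/*1": 0.2, "*2x2/*2": 0.2, "*1x2/*1": 0.2, "*1/*3A": 0.4}
        }
        del cfg.haplotype_frequencies["TPMT"]
        calls, truth = simulate_and_call(defs, cfg, tmp_path)
        mismatches = [
            (r.sample, r.gene, r.diplotype, truth[(r.sample, r.gene)])
            for r in calls.itertuples()
            if r.diplotype != truth[(r.sample, r.gene)]
        ]
        assert mismatches == []

    def test_invariant_to_sample_column_order(self, defs, tmp_path):
        cfg = CohortConfig.default(n=15, seed=8)
        calls, _ = simulate_and_call(defs, cfg, tmp_path)
        depth = pd.read_csv(tmp_path / "rt.tsv", sep="\t")
        samples = [c for c in depth.columns if c not in ("chrom", "pos")]
        shuffled = depth[["chrom", "pos"] + samples[::-1]]
        shuffled.to_csv(tmp_path / "shuffled.tsv", sep="\t", index=False)
        genes = set(cfg.haplotype_frequencies)
        calls2 = call_cohort(
            tmp_path / "rt.vcf", tmp_path / "shuffled.tsv", {g: defs[g] for g in genes}
        )
        pd.testing.assert_frame_equal(calls, calls2)

    def test_sample_mismatch_is_error(self, defs, tmp_path):
        cfg = CohortConfig(
            n=3, seed=2, haplotype_frequencies={"CYP4F2": {"*3": 1.0}}, depth_sd=0.0
        )
        cohort = sample_cohort(cfg, defs)
        table = {"CYP4F2": defs["CYP4F2"]}
        vcf = emit_phased_vcf(cohort, table, tmp_path / "m.vcf")
        depth = emit_depth(cohort[:2], table, cfg, tmp_path / "m.tsv")
        with pytest.raises(ValueError, match="mismatch"):
            call_cohort(vcf, depth, table)
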