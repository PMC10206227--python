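import pytest

from pgxcohort import reference_data as rd
from pgxcohort.reference_data import (
    AlleleDefinitionTable,
    StarAlleleDef,
    VariantKey,
)


@pytest.fixture(scope="session")
def defs():
    return rd.load_allele_definitions()


@pytest.fixture(scope="session")
def translation():
    return rd.load_translation_tables()


@pytest.fixture(scope="session")
def risk_tables():
    return rd.load_ehr_risk_tables()


@pytest.fixture(scope="session")
def pairs():
    return rd.load_drug_gene_pairs()


@pytest.fixture(scope="session")
def synonyms():
    return rd.load_drug_synonyms()


def make_allele_table(gene, alleles, region=None, deletion="*DEL"):
    """Build a toy AlleleDefinitionTable.

    ``alleles`` maps allele name -> (list of (chrom, pos, ref, alt), activity_score).
    """
    defs = [
        StarAlleleDef(
            gene,
            name,
            frozenset(VariantKey(*v) for v in variants),
            score,
        )
        for name, (variants, score) in alleles.items()
    ]
    return AlleleDefinitionTable(gene, defs, region=region, deletion_allele_name=deletion)


def write_vcf(path, samples, records):
    """Write a minimal phased VCF.

    ``records``: list of (chrom, pos, rsid, ref, alt, [gt strings per sample]).
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(r[0] for r in records):
        lines.insert(1, f"##contig=<ID={chrom}>")
    lines.append("\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + list(samples)))
    for chrom, pos, rsid, ref, alt, gts in records:
        lines.append("\t".join([chrom, str(pos), rsid or ".", ref, alt, ".", "PASS", ".", "GT"] + list(gts)))
    path.write_text("\n".join(lines) + "\n")
    return path
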