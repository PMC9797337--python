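"""Qualifying-variant filter, consequence classification and VCF dialects."""

import pytest
from hypothesis import given, settings, strategies as st

from pathburden.variant_io import (
    CONSEQUENCE_CLASSES,
    MISSING,
    QualifyingFilter,
    VariantRecord,
    VcfFormatError,
    classify_consequence,
    is_qualifying,
    load_consequence_map,
    read_vcf,
)


def _record(consequence="stop_gain", ac=0, an=280_000, gene="G1"):
    return VariantRecord(
        chrom="chr1", pos=100, ref="C", alt="T", gene=gene,
        consequence=consequence, pop_allele_count=ac, pop_allele_number=an,
        genotypes={"A": 1},
    )


@pytest.mark.parametrize(
    "term,ref,alt,expected",
    [
        ("stop_gained", "C", "T", "stop_gain"),
        ("start_lost", "A", "G", "start_loss"),
        ("splice_donor_variant", "G", "A", "canonical_splice"),
        ("splice_acceptor_variant", "G", "A", "canonical_splice"),
        ("frameshift_variant", "A", "ATT", "frameshift_insertion"),
        ("frameshift_variant", "ATT", "A", "frameshift_deletion"),
        ("missense_variant", "C", "G", "other"),
        ("synonymous_variant", "C", "T", "other"),
        # extended splice region is not canonical splice disruption
        ("splice_region_variant", "C", "T", "other"),
        # compound VEP terms: first mappable term wins
        ("stop_gained&splice_region_variant", "C", "T", "stop_gain"),
        ("intron_variant&splice_donor_variant", "G", "T", "canonical_splice"),
    ],
)
def test_classify_consequence(term, ref, alt, expected):
    assert classify_consequence(term, ref, alt) == expected


def test_classify_empty_term_raises():
    with pytest.raises(ValueError):
        classify_consequence("")


def test_consequence_map_override(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text("# custom\nweird_term\tstop_gain\nstop_gained\tother\n")
    table = load_consequence_map(path)
    assert classify_consequence("weird_term", mapping=table) == "stop_gain"
    assert classify_consequence("stop_gained", mapping=table) == "other"


class TestQualifying:
    def test_boundary_inclusive(self):
        f = QualifyingFilter()
        assert is_qualifying(_record("stop_gain", ac=10), f)

    def test_boundary_exceeded(self):
        assert not is_qualifying(_record("stop_gain", ac=11), QualifyingFilter())

    def test_consequence_gate(self):
        assert not is_qualifying(_record("other", ac=0), QualifyingFilter())

    def test_frequency_scale_for_other_denominator(self):
        f = QualifyingFilter()
        # 2/140,000 = 4/280,000 <= 10/280,000
        assert is_qualifying(_record("start_loss", ac=2, an=140_000), f)
        # 6/140,000 = 12/280,000 > 10/280,000
        assert not is_qualifying(_record("start_loss", ac=6, an=140_000), f)

    def test_absent_from_reference_is_rare(self):
        assert is_qualifying(
            _record("stop_gain", ac=0),
            QualifyingFilter(max_pop_allele_count=0),
        )

    @settings(max_examples=200, derandomize=True)
    @given(
        ac=st.integers(0, 50),
        an=st.sampled_from([1_000, 140_000, 280_000, 500_000]),
        cls=st.sampled_from(CONSEQUENCE_CLASSES),
        cutoff=st.integers(0, 20),
    )
    def test_filter_monotonicity(self, ac, an, cls, cutoff):
        """Raising the AC cutoff never disqualifies; dropping a class
        never qualifies."""
        v = _record(cls, ac=ac, an=an)
        loose = QualifyingFilter(max_pop_allele_count=cutoff + 5)
        tight = QualifyingFilter(max_pop_allele_count=cutoff)
        assert not (is_qualifying(v, tight) and not is_qualifying(v, loose))
        narrowed = QualifyingFilter(
            allowed_consequences=frozenset({"stop_gain"}),
            max_pop_allele_count=cutoff,
        )
        assert not (is_qualifying(v, narrowed) and not is_qualifying(v, tight))


class TestReadVcf:
    def test_toy_decomposition_and_fields(self, toy_vcf):
        recs = list(read_vcf(toy_vcf, "info_tags"))
        assert len(recs) == 6  # 5 sites, one multi-allelic
        r1 = recs[0]
        assert (r1.gene, r1.consequence) == ("GENE1", "stop_gain")
        assert r1.genotypes == {"A": 1, "B": 2, "C": 0}
        assert (r1.pop_allele_count, r1.pop_allele_number) == (10, 280_000)

        # multi-allelic site: one record per ALT with its own AC and class
        alt1, alt2 = recs[3], recs[4]
        assert alt1.alt == "T" and alt1.consequence == "canonical_splice"
        assert alt1.pop_allele_count == 0
        assert alt1.genotypes == {"A": 1, "B": 0, "C": MISSING}
        assert alt2.alt == "TGG"
        assert alt2.consequence == "frameshift_insertion"
        assert alt2.pop_allele_count == 5
        assert alt2.genotypes == {"A": 1, "B": 1, "C": MISSING}

    def test_unknown_dialect(self, toy_vcf):
        with pytest.raises(VcfFormatError, match="dialect"):
            next(read_vcf(toy_vcf, "nonsense"))

    def test_missing_info_tag_is_hard_error(self, tmp_path, toy_vcf):
        text = toy_vcf.read_text().replace("GENE=GENE1;", "", 1)
        bad = tmp_path / "bad.vcf"
        bad.write_text(text)
        with pytest.raises(VcfFormatError, match="chr1:1000"):
            list(read_vcf(bad, "info_tags"))

    def test_vep_csq_dialect(self, tmp_path):
        vcf = tmp_path / "vep.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
            'annotations from Ensembl VEP. Format: '
            'Allele|Consequence|SYMBOL|gnomAD_AC|gnomAD_AN">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr1\t500\t.\tC\tT\t.\tPASS\t"
            "CSQ=T|stop_gained|NUMB|3|251000\tGT\t0/1\t0/0\n"
            "chr1\t900\t.\tA\tG\t.\tPASS\t"
            "CSQ=G|missense_variant|NUMBL||\tGT\t0/0\t1/1\n"
        )
        recs = list(read_vcf(vcf, "vep_csq"))
        assert [r.gene for r in recs] == ["NUMB", "NUMBL"]
        assert recs[0].consequence == "stop_gain"
        assert recs[0].pop_allele_count == 3
        assert recs[0].pop_allele_number == 251_000
        # empty gnomAD fields: absent from reference => AC=0 at default AN
        assert recs[1].pop_allele_count == 0
        assert recs[1].pop_allele_number == 280_000

    def test_snpeff_ann_dialect(self, tmp_path):
        vcf = tmp_path / "snpeff.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional '
            'annotations">\n'
            '##INFO=<ID=POP_AC,Number=A,Type=Integer,Description="AC">\n'
            '##INFO=<ID=POP_AN,Number=A,Type=Integer,Description="AN">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t700\t.\tG\tA\t.\tPASS\t"
            "ANN=A|splice_acceptor_variant|HIGH|LYST|ENSG1|x;POP_AC=1;POP_AN=280000"
            "\tGT\t0/1\n"
        )
        (rec,) = read_vcf(vcf, "snpeff_ann")
        assert rec.gene == "LYST"
        assert rec.consequence == "canonical_splice"
        assert rec.pop_allele_count == 1


def test_variant_record_invariants():
    with pytest.raises(ValueError):
        _record(ac=20, an=10)
    with pytest.raises(ValueError):
        VariantRecord("chr1", 0, "C", "T", "G", "stop_gain", 0, 1, {})
    with pytest.raises(ValueError):
        VariantRecord("chr1", 5, "C", "C", "G", "stop_gain", 0, 1, {})
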