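"""Gene collapsing to carrier status and pathway carrier counting."""

import numpy as np
import pytest

from pathburden.burden import (
    CarrierMatrix,
    CohortSpec,
    build_carrier_matrix,
    one_per_family,
    pathway_carrier_counts,
    read_manifest,
    validate_cohorts,
)
from pathburden.geneset_io import GeneSet, GeneSetCollection
from pathburden.variant_io import MISSING, QualifyingFilter, VariantRecord


def _var(gene, genotypes, consequence="stop_gain", ac=0, an=280_000, pos=100):
    return VariantRecord(
        chrom="chr1", pos=pos, ref="C", alt="T", gene=gene,
        consequence=consequence, pop_allele_count=ac,
        pop_allele_number=an, genotypes=genotypes,
    )


SAMPLES = ["A", "B", "C"]


def test_toy_collapsing():
    """het in G1 for A, hom in G2 for B, C reference everywhere."""
    variants = [
        _var("G1", {"A": 1, "B": 0, "C": 0}),
        _var("G2", {"A": 0, "B": 2, "C": 0}, pos=200),
    ]
    m = build_carrier_matrix(variants, QualifyingFilter(), SAMPLES)
    assert m.to_frame().values.tolist() == [[1, 0], [0, 1], [0, 0]]


def test_hom_binarized_to_one():
    m = build_carrier_matrix(
        [_var("G1", {"A": 2, "B": 0, "C": 0})], QualifyingFilter(), SAMPLES
    )
    assert m.dose("A", "G1") == 1


def test_missing_genotype_is_not_carrier():
    m = build_carrier_matrix(
        [_var("G1", {"A": MISSING, "B": 1, "C": 0})], QualifyingFilter(), SAMPLES
    )
    assert m.dose("A", "G1") == 0
    assert m.dose("B", "G1") == 1


def test_strict_missingness_mode_drops_samples():
    variants = [
        _var("G1", {"A": MISSING, "B": 1, "C": 0}),
        _var("G2", {"A": MISSING, "B": 0, "C": 1}, pos=200),
    ]
    m = build_carrier_matrix(variants, QualifyingFilter(), SAMPLES,
                             max_missing_fraction=0.1)
    assert "A" not in m.samples and set(m.samples) == {"B", "C"}


def test_no_qualifying_variants_all_zero_with_warning():
    with pytest.warns(UserWarning, match="no qualifying"):
        m = build_carrier_matrix(
            [_var("G1", {"A": 1, "B": 0, "C": 0}, consequence="other")],
            QualifyingFilter(), SAMPLES,
        )
    assert m.shape == (3, 0)


def test_unknown_sample_in_genotypes_errors():
    with pytest.raises(ValueError, match="absent"):
        build_carrier_matrix(
            [_var("G1", {"Z": 1})], QualifyingFilter(), SAMPLES
        )


def test_nonqualifying_variants_do_not_create_carriage():
    variants = [
        _var("G1", {"A": 1, "B": 0, "C": 0}),
        _var("G1", {"A": 0, "B": 1, "C": 0}, ac=5000, pos=200),  # too common
    ]
    m = build_carrier_matrix(variants, QualifyingFilter(), SAMPLES)
    assert m.dose("B", "G1") == 0


def test_tsv_round_trip(tmp_path):
    m = CarrierMatrix(SAMPLES, ["G1", "G2"],
                      np.array([[1, 0], [0, 1], [0, 0]]))
    path = tmp_path / "m.tsv"
    m.to_tsv(path)
    assert CarrierMatrix.from_tsv(path) == m


class TestPathwayCounts:
    matrix = CarrierMatrix(
        ["A", "B", "C", "D"],
        ["G1", "G2", "G3"],
        np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0], [0, 0, 1]]),
    )
    collection = GeneSetCollection((
        GeneSet("P1", "both G1 G2", frozenset({"G1", "G2"})),
        GeneSet("P2", "only G3", frozenset({"G3"})),
        GeneSet("P3", "absent genes", frozenset({"GX", "GY"})),
    ))
    cohorts = [
        CohortSpec("case", "case", ("A", "B")),
        CohortSpec("comp", "comparison", ("C", "D")),
    ]

    def _by_key(self, counts):
        return {(c.set_id, c.cohort_id): c for c in counts}

    def test_hand_tally(self):
        by = self._by_key(
            pathway_carrier_counts(self.matrix, self.collection, self.cohorts)
        )
        # A carries both G1 and G2 of P1 but counts once
        assert by[("P1", "case")].n_carriers == 2
        assert by[("P1", "comp")].n_carriers == 0
        assert by[("P2", "comp")].n_carriers == 1

    def test_disjoint_pathway_counts_zero(self):
        by = self._by_key(
            pathway_carrier_counts(self.matrix, self.collection, self.cohorts)
        )
        assert by[("P3", "case")].n_carriers == 0
        assert by[("P3", "comp")].n_carriers == 0

    def test_counts_sum_to_cohort_size(self):
        for c in pathway_carrier_counts(self.matrix, self.collection,
                                        self.cohorts):
            size = 2
            assert c.n_carriers + c.n_noncarriers == size

    def test_sample_order_invariance(self):
        perm = [3, 1, 0, 2]
        m2 = CarrierMatrix(
            [self.matrix.samples[i] for i in perm],
            self.matrix.genes,
            self.matrix.carriage[perm],
        )
        a = self._by_key(pathway_carrier_counts(
            self.matrix, self.collection, self.cohorts))
        b = self._by_key(pathway_carrier_counts(
            m2, self.collection, self.cohorts))
        assert {k: (v.n_carriers, v.n_noncarriers) for k, v in a.items()} == {
            k: (v.n_carriers, v.n_noncarriers) for k, v in b.items()
        }

    def test_superset_monotone(self):
        sub = GeneSetCollection((GeneSet("P", "p", frozenset({"G1"})),))
        sup = GeneSetCollection((GeneSet("P", "p", frozenset({"G1", "G2"})),))
        a = pathway_carrier_counts(self.matrix, sub, self.cohorts)
        b = pathway_carrier_counts(self.matrix, sup, self.cohorts)
        for x, y in zip(a, b):
            assert y.n_carriers >= x.n_carriers

    def test_cohort_sample_missing_from_matrix_errors(self):
        bad = [CohortSpec("case", "case", ("A", "ZZ")),
               CohortSpec("comp", "comparison", ("C",))]
        with pytest.raises(ValueError, match="absent"):
            pathway_carrier_counts(self.matrix, self.collection, bad)


class TestManifest:
    def test_read_and_roles(self, tmp_path):
        path = tmp_path / "manifest.tsv"
        path.write_text(
            "sample_id\tcohort_id\trole\n"
            "A\tmisc\tcase\nB\tmisc\tcase\nC\tobesity\tcomparison\n"
        )
        cohorts, df = read_manifest(path)
        assert [c.cohort_id for c in cohorts] == ["misc", "obesity"]
        assert cohorts[0].role == "case"

    def test_exactly_one_case_required(self):
        with pytest.raises(ValueError, match="case"):
            validate_cohorts([
                CohortSpec("x", "comparison", ("A",)),
                CohortSpec("y", "comparison", ("B",)),
            ])

    def test_one_per_family(self, tmp_path):
        path = tmp_path / "manifest.tsv"
        path.write_text(
            "sample_id\tcohort_id\trole\tfamily_id\n"
            "A\tm\tcase\tF1\nB\tm\tcase\tF1\nC\tc\tcomparison\tF2\n"
            "D\tc\tcomparison\t\n"
        )
        _, df = read_manifest(path)
        kept = one_per_family(df, seed=1)
        assert len(kept) == 3  # one of A/B, plus C, plus family-less D
        assert "D" in set(kept["sample_id"])
        # deterministic given the seed
        again = one_per_family(df, seed=1)
        assert list(kept["sample_id"]) == list(again["sample_id"])
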