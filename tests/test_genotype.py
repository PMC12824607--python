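"""Variant predicates, Boolean combinators, and the five genotype classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenogpc.cohort import Cohort, DiseaseRecord, Individual, Sex, VariantRecord
from phenogpc.genotype import (
    OMITTED,
    allele_count_classifier,
    biallelic_classifier,
    classifier_from_spec,
    classify_cohort,
    diagnosis_classifier,
    monoallelic_classifier,
    pred_and,
    pred_change_length,
    pred_consequence,
    pred_exon,
    pred_lof,
    pred_not,
    pred_or,
    pred_protein_region,
    pred_structural,
    predicate_from_spec,
    sex_classifier,
)

MISSENSE = VariantRecord(
    key="c.373G>C",
    gene="TBX5",
    consequences=frozenset({"missense_variant"}),
    protein_span=(125, 125),
    change_length=0,
)
STOP = VariantRecord(key="stop1", consequences=frozenset({"stop_gained"}))
FRAMESHIFT = VariantRecord(key="fs1", consequences=frozenset({"frameshift_variant"}))
SMALL_DEL = VariantRecord(key="del49", structural_kind="DEL", change_length=-49)
BIG_DEL = VariantRecord(key="del200", structural_kind="DEL", change_length=-200)
CHROM_DEL = VariantRecord(key="chrdel", structural_kind="DEL")  # imprecise


class TestPredicates:
    def test_consequence_match(self):
        assert pred_consequence("missense_variant")(MISSENSE)
        assert not pred_consequence("missense_variant")(STOP)

    def test_protein_region_overlap(self):
        hotspot = VariantRecord(key="v", protein_span=(845, 845))
        assert pred_protein_region(840, 850)(hotspot)
        assert not pred_protein_region(840, 850)(MISSENSE)
        with pytest.raises(ValueError):
            pred_protein_region(850, 840)

    def test_exon_membership(self):
        v = VariantRecord(key="v", affected_exons=frozenset({8}))
        assert pred_exon(8)(v) and not pred_exon(9)(v)

    def test_structural_size_threshold(self):
        big = pred_structural("DEL", min_size=50)
        assert not big(SMALL_DEL)  # 49 bp is below the 50 bp threshold
        assert big(BIG_DEL)
        assert big(CHROM_DEL)  # imprecise chromosomal events always qualify

    def test_point_mutation_conjunction(self):
        point = pred_and(
            pred_consequence("missense_variant"), pred_change_length("eq", 0)
        )
        assert point(MISSENSE)
        inframe_del = VariantRecord(
            key="v", consequences=frozenset({"missense_variant"}), change_length=-3
        )
        assert not point(inframe_del)

    def test_lof_disjunction(self):
        assert pred_lof()(FRAMESHIFT) and pred_lof()(STOP)
        assert not pred_lof()(MISSENSE)

    def test_descriptions_compose_with_parentheses(self):
        combined = pred_or(pred_consequence("a_label"), pred_exon(3))
        assert combined.description.startswith("(")
        assert "OR" in combined.description


@st.composite
def variant_records(draw):
    labels = ["missense_variant", "stop_gained", "frameshift_variant", "start_lost"]
    return VariantRecord(
        key=f"v{draw(st.integers(0, 10**6))}",
        consequences=frozenset(draw(st.sets(st.sampled_from(labels), max_size=3))),
        affected_exons=frozenset(draw(st.sets(st.integers(1, 20), max_size=3))),
        change_length=draw(st.one_of(st.none(), st.integers(-100, 100))),
    )


class TestBooleanAlgebra:
    @given(variant_records())
    @settings(max_examples=50, derandomize=True)
    def test_de_morgan_and_double_negation(self, record):
        p = pred_consequence("missense_variant")
        q = pred_change_length("eq", 0)
        assert pred_not(pred_and(p, q))(record) == pred_or(pred_not(p), pred_not(q))(record)
        assert pred_not(pred_or(p, q))(record) == pred_and(pred_not(p), pred_not(q))(record)
        assert pred_not(pred_not(p))(record) == p(record)

    def test_not_is_pointwise_complement(self):
        rng = np.random.default_rng(7)
        p = pred_exon(5)
        for _ in range(20):
            rec = VariantRecord(
                key="v",
                affected_exons=frozenset(
                    int(e) for e in rng.choice(20, size=rng.integers(0, 4), replace=False)
                ),
            )
            assert pred_not(p)(rec) == (not p(rec))


def _ind(ind_id, *variants, sex=Sex.UNKNOWN, diseases=(), genotype_unknown=False):
    return Individual(
        id=ind_id,
        sex=sex,
        variants=list(variants),
        diseases=[DiseaseRecord(disease_id=d) for d in diseases],
        genotype_unknown=genotype_unknown,
    )


class TestMonoallelic:
    def test_single_missense_allele_is_class_a(self):
        clf = monoallelic_classifier(pred_consequence("missense_variant"))
        assert clf.assign(_ind("P1", MISSENSE)) == "A"
        assert clf.assign(_ind("P2", STOP)) == "B"

    def test_hemizygous_male_is_classified(self):
        clf = monoallelic_classifier(pred_consequence("missense_variant"))
        hemi = _ind("P1", MISSENSE, sex=Sex.MALE)  # one allele, allele_count 1
        assert clf.assign(hemi) == "A"

    def test_compound_het_across_groups_is_omitted(self):
        clf = monoallelic_classifier(
            pred_consequence("missense_variant"), pred_structural("DEL")
        )
        assert clf.assign(_ind("P1", MISSENSE, BIG_DEL)) == OMITTED

    def test_homozygous_qualifying_allele_is_omitted(self):
        clf = monoallelic_classifier(pred_consequence("missense_variant"))
        hom = VariantRecord(
            key="v", consequences=frozenset({"missense_variant"}), allele_count=2
        )
        assert clf.assign(_ind("P1", hom)) == OMITTED

    def test_nonqualifying_individual_is_omitted_with_explicit_b(self):
        clf = monoallelic_classifier(
            pred_consequence("missense_variant"),
            pred_structural("DEL"),
        )
        assert clf.assign(_ind("P1", FRAMESHIFT)) == OMITTED

    def test_genotype_unknown_is_omitted(self):
        clf = monoallelic_classifier(pred_consequence("missense_variant"))
        assert clf.assign(_ind("P1", MISSENSE, genotype_unknown=True)) == OMITTED


class TestBiallelic:
    def test_two_stop_alleles_are_aa(self):
        clf = biallelic_classifier(pred_consequence("stop_gained"))
        hom = VariantRecord(
            key="v", consequences=frozenset({"stop_gained"}), allele_count=2
        )
        assert clf.assign(_ind("P1", hom)) == "AA"

    def test_compound_het_is_ab(self):
        clf = biallelic_classifier(pred_consequence("stop_gained"))
        assert clf.assign(_ind("P1", STOP, MISSENSE)) == "AB"

    def test_single_allele_is_omitted(self):
        clf = biallelic_classifier(pred_consequence("stop_gained"))
        assert clf.assign(_ind("P1", STOP)) == OMITTED

    def test_two_way_merge_partition(self):
        clf = biallelic_classifier(
            pred_consequence("stop_gained"), partitions=((2, 1), (0,))
        )
        assert clf.labels == ("AA/AB", "BB")
        assert clf.assign(_ind("P1", STOP, MISSENSE)) == "AA/AB"
        mm = VariantRecord(
            key="v", consequences=frozenset({"missense_variant"}), allele_count=2
        )
        assert clf.assign(_ind("P2", mm)) == "BB"

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            biallelic_classifier(
                pred_consequence("stop_gained"), partitions=((2,), (2, 0))
            )


class TestOtherClassifiers:
    def test_allele_count_doses(self):
        clf = allele_count_classifier(pred_consequence("missense_variant"))
        het = _ind("P1", MISSENSE)
        hom = _ind(
            "P2",
            VariantRecord(
                key="v", consequences=frozenset({"missense_variant"}), allele_count=2
            ),
        )
        assert clf.assign(het) == "1"
        assert clf.assign(hom) == "2"
        assert clf.assign(_ind("P3", STOP)) == OMITTED

    def test_sex_classifier(self):
        clf = sex_classifier()
        assert clf.assign(_ind("P1", sex=Sex.MALE)) == "MALE"
        assert clf.assign(_ind("P2", sex=Sex.FEMALE)) == "FEMALE"
        assert clf.assign(_ind("P3")) == OMITTED

    def test_diagnosis_classifier(self):
        clf = diagnosis_classifier(["OMIM:147920", "OMIM:300867"])
        assert clf.assign(_ind("P1", diseases=["OMIM:147920"])) == "OMIM:147920"
        assert clf.assign(_ind("P2", diseases=["OMIM:300867"])) == "OMIM:300867"
        assert clf.assign(_ind("P3", diseases=["OMIM:999999"])) == OMITTED
        both = _ind("P4", diseases=["OMIM:147920", "OMIM:300867"])
        assert clf.assign(both) == OMITTED
        with pytest.raises(ValueError):
            diagnosis_classifier(["OMIM:147920"])


class TestPartitionProperties:
    def _random_cohort(self, rng, n=30):
        inds = []
        for i in range(n):
            variants = []
            total = 0
            for j in range(int(rng.integers(0, 3))):
                dose = int(rng.integers(1, 3))
                if total + dose > 2:
                    continue
                total += dose
                variants.append(
                    VariantRecord(
                        key=f"v{i}-{j}",
                        consequences=frozenset(
                            {str(rng.choice(["missense_variant", "stop_gained"]))}
                        ),
                        allele_count=dose,
                    )
                )
            inds.append(Individual(id=f"P{i}", variants=variants))
        return Cohort(individuals=inds)

    def test_classes_partition_the_cohort(self):
        rng = np.random.default_rng(11)
        cohort = self._random_cohort(rng)
        for clf in (
            monoallelic_classifier(pred_consequence("missense_variant")),
            biallelic_classifier(pred_consequence("missense_variant")),
            allele_count_classifier(pred_consequence("missense_variant")),
        ):
            assignment = classify_cohort(cohort, clf)
            assert sum(assignment.counts.values()) == len(cohort)
            labelled = sum(
                n for lab, n in assignment.counts.items() if lab != OMITTED
            )
            assert labelled + assignment.n_omitted == len(cohort)

    def test_label_symmetry_under_predicate_swap(self):
        rng = np.random.default_rng(13)
        cohort = self._random_cohort(rng)
        a = pred_consequence("missense_variant")
        b = pred_consequence("stop_gained")
        fwd = classify_cohort(cohort, monoallelic_classifier(a, b))
        rev = classify_cohort(cohort, monoallelic_classifier(b, a))
        swap = {"A": "B", "B": "A", OMITTED: OMITTED}
        assert rev.by_individual == {
            i: swap[lab] for i, lab in fwd.by_individual.items()
        }


class TestSpecGrammar:
    def test_nested_boolean_spec(self):
        pred = predicate_from_spec(
            {
                "op": "and",
                "args": [
                    {"consequence": "missense_variant"},
                    {"change_length": {"eq": 0}},
                ],
            }
        )
        assert pred(MISSENSE)
        assert not pred(STOP)

    def test_classifier_spec_round_trip(self):
        clf = classifier_from_spec(
            {"type": "monoallelic", "a": {"consequence": "missense_variant"}}
        )
        assert clf.assign(_ind("P1", MISSENSE)) == "A"

    def test_unknown_spec_rejected(self):
        with pytest.raises(ValueError):
            predicate_from_spec({"bogus": 1})
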