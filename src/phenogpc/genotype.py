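"""Variant predicates and genotype classifiers.

A :class:`VariantPredicate` is a deterministic boolean function over one
allele's functional annotation; predicates compose with AND/OR/NOT.  A
:class:`GenotypeClassifier` uses predicates (or sex / diagnosis) to partition
a cohort into 2-3 genotype classes, omitting individuals that do not fit the
partition (e.g. compound heterozygotes in a mono-allelic analysis).
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .cohort import Cohort, Individual, Sex, VariantRecord

#: Sentinel label for individuals excluded from a partition.
OMITTED = "OMITTED"


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantPredicate:
    test: Callable[[VariantRecord], bool]
    description: str

    def __post_init__(self) -> None:
        if not self.description:
            raise ValueError("predicate description must be non-empty")

    def __call__(self, record: VariantRecord) -> bool:
        return bool(self.test(record))

    def __and__(self, other: "VariantPredicate") -> "VariantPredicate":
        return pred_and(self, other)

    def __or__(self, other: "VariantPredicate") -> "VariantPredicate":
        return pred_or(self, other)

    def __invert__(self) -> "VariantPredicate":
        return pred_not(self)


def pred_consequence(label: str) -> VariantPredicate:
    """True iff *label* (e.g. ``missense_variant``) is among the record's consequences."""
    if not label:
        raise ValueError("consequence label must be non-empty")
    return VariantPredicate(
        test=lambda r: label in r.consequences,
        description=f"consequence == {label}",
    )


def pred_exon(n: int) -> VariantPredicate:
    """True iff the variant affects 1-based exon *n*."""
    if n < 1:
        raise ValueError("exon numbers are 1-based")
    return VariantPredicate(
        test=lambda r: n in r.affected_exons, description=f"affects exon {n}"
    )


def pred_protein_region(start: int, end: int) -> VariantPredicate:
    """True iff the variant's protein span overlaps residues [start, end] (1-based)."""
    if start > end:
        raise ValueError(f"inverted protein region: {start} > {end}")
    return VariantPredicate(
        test=lambda r: r.protein_span is not None
        and r.protein_span[0] <= end
        and r.protein_span[1] >= start,
        description=f"overlaps protein residues {start}-{end}",
    )


def pred_variant_key(key: str) -> VariantPredicate:
    return VariantPredicate(test=lambda r: r.key == key, description=f"variant {key}")


_CMP = {
    "eq": operator.eq,
    "ne": operator.ne,
    "lt": operator.lt,
    "le": operator.le,
    "gt": operator.gt,
    "ge": operator.ge,
}


def pred_change_length(cmp: str, value: int) -> VariantPredicate:
    """Compare ``len(alt) - len(ref)``; records without a change length never match."""
    if cmp not in _CMP:
        raise ValueError(f"unknown comparison {cmp!r}; use one of {sorted(_CMP)}")
    op = _CMP[cmp]
    return VariantPredicate(
        test=lambda r: r.change_length is not None and op(r.change_length, value),
        description=f"change_length {cmp} {value}",
    )


def pred_structural(kind: str, min_size: int = 50) -> VariantPredicate:
    """Structural predicate: kind matches and the event is large or imprecise.

    An imprecise chromosomal event has no change length and always matches;
    a sequence-resolved event matches when ``|change_length| >= min_size``
    (default 50 bp, configurable).
    """
    def test(r: VariantRecord) -> bool:
        if r.structural_kind != kind:
            return False
        if r.change_length is None:
            return True  # imprecise chromosomal event
        return abs(r.change_length) >= min_size

    return VariantPredicate(
        test=test, description=f"structural {kind} (>= {min_size} bp or imprecise)"
    )


def pred_and(*preds: VariantPredicate) -> VariantPredicate:
    return VariantPredicate(
        test=lambda r: all(p(r) for p in preds),
        description="(" + " AND ".join(p.description for p in preds) + ")",
    )


def pred_or(*preds: VariantPredicate) -> VariantPredicate:
    return VariantPredicate(
        test=lambda r: any(p(r) for p in preds),
        description="(" + " OR ".join(p.description for p in preds) + ")",
    )


def pred_not(pred: VariantPredicate) -> VariantPredicate:
    return VariantPredicate(
        test=lambda r: not pred(r), description=f"(NOT {pred.description})"
    )


#: Canonical loss-of-function group: ablation, frameshift, premature stop, start loss.
LOF_CONSEQUENCES = (
    "transcript_ablation",
    "frameshift_variant",
    "stop_gained",
    "start_lost",
)


def pred_lof() -> VariantPredicate:
    return pred_or(*(pred_consequence(c) for c in LOF_CONSEQUENCES))


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeClassifier:
    """Total assignment of individuals to an ordered set of 2-3 class labels."""

    labels: tuple[str, ...]
    assign: Callable[[Individual], str]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) not in (2, 3):
            raise ValueError("classifiers define 2 or 3 classes")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("class labels must be distinct")


@dataclass
class ClassAssignment:
    """The realized partition of one cohort: individual id -> label or OMITTED."""

    labels: tuple[str, ...]
    by_individual: dict[str, str]
    description: str = ""

    @property
    def counts(self) -> dict[str, int]:
        out = {label: 0 for label in self.labels}
        out[OMITTED] = 0
        for lab in self.by_individual.values():
            out[lab] += 1
        return out

    @property
    def n_omitted(self) -> int:
        return self.counts[OMITTED]

    def members(self, label: str) -> list[str]:
        return [i for i, lab in self.by_individual.items() if lab == label]


def classify_cohort(cohort: Cohort, classifier: GenotypeClassifier) -> ClassAssignment:
    by_individual = {ind.id: classifier.assign(ind) for ind in cohort}
    for ind_id, lab in by_individual.items():
        if lab != OMITTED and lab not in classifier.labels:
            raise ValueError(f"classifier produced unknown label {lab!r} for {ind_id}")
    return ClassAssignment(
        labels=classifier.labels,
        by_individual=by_individual,
        description=classifier.description,
    )


def _qualifying_alleles(
    individual: Individual, pred_a: VariantPredicate, pred_b: VariantPredicate
) -> tuple[int, int]:
    """(a_dose, b_dose) over alleles matching A or B; A wins when both match."""
    a = b = 0
    for v in individual.variants:
        if pred_a(v):
            a += v.allele_count
        elif pred_b(v):
            b += v.allele_count
    return a, b


def monoallelic_classifier(
    pred_a: VariantPredicate,
    pred_b: VariantPredicate | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> GenotypeClassifier:
    """Partition by a single qualifying allele: A-matching vs B-matching.

    Suited to autosomal-dominant and X-linked analyses: a heterozygous or
    hemizygous allele counts once.  When *pred_b* is omitted it defaults to
    NOT A, so the classes are "has the A allele" vs "has some other allele".
    Individuals whose qualifying-allele total (over A u B) is not exactly one
    — none, homozygous, or compound heterozygous — are OMITTED.
    """
    if pred_b is None:
        pred_b = pred_not(pred_a)

    def assign(ind: Individual) -> str:
        if ind.genotype_unknown:
            return OMITTED
        a, b = _qualifying_alleles(ind, pred_a, pred_b)
        if a + b != 1:
            return OMITTED
        return labels[0] if a == 1 else labels[1]

    return GenotypeClassifier(
        labels=labels,
        assign=assign,
        description=f"mono-allelic: {labels[0]}={pred_a.description} "
        f"vs {labels[1]}={pred_b.description}",
    )


def biallelic_classifier(
    pred_a: VariantPredicate,
    pred_b: VariantPredicate | None = None,
    partitions: Sequence[Sequence[int]] = ((2,), (1,), (0,)),
    labels: Sequence[str] | None = None,
) -> GenotypeClassifier:
    """Partition individuals with exactly two qualifying alleles by A-allele count.

    Designed for autosomal-recessive conditions.  ``partitions`` groups the
    A-allele counts {2, 1, 0} (AA/AB/BB) into classes: the default is the
    three singleton classes; a 2-way merge such as ``((2, 1), (0,))`` tests
    "one or two A alleles" vs "no A allele".
    """
    if pred_b is None:
        pred_b = pred_not(pred_a)
    flat = [c for part in partitions for c in part]
    if sorted(flat) != [0, 1, 2] or len(partitions) not in (2, 3):
        raise ValueError(
            "partitions must group the A-allele counts {2,1,0} into 2 or 3 classes"
        )
    names = {2: "AA", 1: "AB", 0: "BB"}
    if labels is None:
        labels = tuple("/".join(names[c] for c in part) for part in partitions)
    label_of = {c: lab for part, lab in zip(partitions, labels) for c in part}

    def assign(ind: Individual) -> str:
        if ind.genotype_unknown:
            return OMITTED
        a, b = _qualifying_alleles(ind, pred_a, pred_b)
        if a + b != 2:
            return OMITTED
        return label_of[a]

    return GenotypeClassifier(
        labels=tuple(labels),
        assign=assign,
        description=f"bi-allelic: A={pred_a.description} vs B={pred_b.description}, "
        f"classes {list(labels)}",
    )


def allele_count_classifier(
    pred: VariantPredicate, counts: tuple[int, ...] = (1, 2)
) -> GenotypeClassifier:
    """Partition by the total dose of alleles matching *pred* (default 1 vs 2)."""
    if len(set(counts)) != len(counts):
        raise ValueError("allele counts must be distinct")
    labels = tuple(str(c) for c in counts)

    def assign(ind: Individual) -> str:
        if ind.genotype_unknown:
            return OMITTED
        dose = sum(v.allele_count for v in ind.variants if pred(v))
        return str(dose) if dose in counts else OMITTED

    return GenotypeClassifier(
        labels=labels,
        assign=assign,
        description=f"allele count {counts} of {pred.description}",
    )


def sex_classifier() -> GenotypeClassifier:
    """MALE vs FEMALE; unknown or unspecified sex is OMITTED."""
    def assign(ind: Individual) -> str:
        if ind.sex is Sex.MALE:
            return "MALE"
        if ind.sex is Sex.FEMALE:
            return "FEMALE"
        return OMITTED

    return GenotypeClassifier(
        labels=("MALE", "FEMALE"), assign=assign, description="sex"
    )


def diagnosis_classifier(disease_ids: Sequence[str]) -> GenotypeClassifier:
    """Partition by disease diagnosis; none-of or several-of the ids is OMITTED."""
    if not 2 <= len(disease_ids) <= 3:
        raise ValueError("diagnosis classifier takes 2 or 3 disease ids")
    ids = tuple(disease_ids)

    def assign(ind: Individual) -> str:
        have = {d.disease_id for d in ind.diseases} & set(ids)
        if len(have) != 1:
            return OMITTED
        return have.pop()

    return GenotypeClassifier(
        labels=ids,
        assign=assign,
        description=f"diagnosis in {list(ids)}",
    )


# ---------------------------------------------------------------------------
# JSON spec grammar for config files
# ---------------------------------------------------------------------------


def predicate_from_spec(spec: dict) -> VariantPredicate:
    """Build a predicate from the small config grammar, e.g.::

        {"op": "and", "args": [{"consequence": "missense_variant"},
                               {"change_length": {"eq": 0}}]}
    """
    if "op" in spec:
        op = spec["op"]
        args = [predicate_from_spec(a) for a in spec.get("args", [])]
        if op == "and":
            return pred_and(*args)
        if op == "or":
            return pred_or(*args)
        if op == "not":
            if len(args) != 1:
                raise ValueError("'not' takes exactly one argument")
            return pred_not(args[0])
        raise ValueError(f"unknown boolean op {op!r}")
    if "consequence" in spec:
        return pred_consequence(spec["consequence"])
    if "exon" in spec:
        return pred_exon(int(spec["exon"]))
    if "protein_region" in spec:
        start, end = spec["protein_region"]
        return pred_protein_region(int(start), int(end))
    if "key" in spec:
        return pred_variant_key(spec["key"])
    if "change_length" in spec:
        ((cmp, value),) = spec["change_length"].items()
        return pred_change_length(cmp, int(value))
    if "structural" in spec:
        s = spec["structural"]
        return pred_structural(s["kind"], int(s.get("min_size", 50)))
    if "lof" in spec:
        return pred_lof()
    raise ValueError(f"unrecognized predicate spec: {spec}")


def classifier_from_spec(spec: dict) -> GenotypeClassifier:
    """Build a classifier from config, e.g. ``{"type": "monoallelic", "a": {...}}``."""
    kind = spec.get("type")
    if kind == "monoallelic":
        return monoallelic_classifier(
            predicate_from_spec(spec["a"]),
            predicate_from_spec(spec["b"]) if "b" in spec else None,
            labels=tuple(spec.get("labels", ("A", "B"))),
        )
    if kind == "biallelic":
        kwargs = {}
        if "partitions" in spec:
            kwargs["partitions"] = tuple(tuple(p) for p in spec["partitions"])
        if "labels" in spec:
            kwargs["labels"] = tuple(spec["labels"])
        return biallelic_classifier(
            predicate_from_spec(spec["a"]),
            predicate_from_spec(spec["b"]) if "b" in spec else None,
            **kwargs,
        )
    if kind == "allele_count":
        return allele_count_classifier(
            predicate_from_spec(spec["pred"]),
            counts=tuple(spec.get("counts", (1, 2))),
        )
    if kind == "sex":
        return sex_classifier()
    if kind == "diagnosis":
        return diagnosis_classifier(spec["diseases"])
    raise ValueError(f"unknown classifier type {kind!r}")
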