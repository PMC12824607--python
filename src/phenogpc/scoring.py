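"""Phenotype severity scores: counting scorer, HPO-adapted de Vries score.

A scorer condenses one individual's phenotype into a number, or NaN when the
individual should be excluded from the comparison.  Scores from two genotype
classes are compared with a Mann-Whitney U test.  Both built-in scorers roll
annotations up the ontology: an annotation to a descendant counts toward the
score component (e.g. *Disproportionate short stature* counts for *Short
stature*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .cohort import Cohort, Individual
from .genotype import OMITTED, ClassAssignment
from .ontology import OntologyGraph, TermId, annotation_closures
from .stats import TestResult, mann_whitney_u

#: A scorer maps an individual to a float score or NaN (excluded).
Scorer = Callable[[Individual], float]


@dataclass(frozen=True)
class ScoreSpec:
    """Component terms of a counting score (one point per component hit)."""

    terms: tuple[TermId, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("score spec must name at least one term")


def counting_score(
    individual: Individual, graph: OntologyGraph, spec: ScoreSpec
) -> float:
    """Count score components with at least one observed annotation.

    A component term scores 1 when the individual is annotated to it or to
    any of its descendants; several hits on one component still score 1.
    The score is an integer in [0, len(spec.terms)].
    """
    for term in spec.terms:
        graph._check(term)
    obs, _, _ = annotation_closures(individual, graph)
    return float(sum(1 for term in spec.terms if term in obs))


@dataclass(frozen=True)
class DeVriesAnchors:
    """Anchor terms for the five de Vries components, editable configuration.

    Defaults use the standard HPO identifiers; toy analyses substitute their
    own ontology's terms.  Components and caps: D1 developmental delay /
    intellectual disability (2 if a severe/profound subtype, else 1 when
    present); D2 prenatal-onset growth retardation (2); D3 postnatal growth
    abnormalities (1 each for short/tall stature and micro/macrocephaly,
    capped at 2); D4 two or more distinct facial dysmorphisms (2); D5
    non-facial dysmorphisms and congenital anomalies (1 each, capped at 2).
    Maximum score 10.
    """

    developmental_delay: tuple[TermId, ...] = ("HP:0001263", "HP:0001249")
    severe_developmental_delay: tuple[TermId, ...] = ("HP:0010864", "HP:0002187")
    prenatal_growth_retardation: tuple[TermId, ...] = ("HP:0001511",)
    postnatal_growth: tuple[TermId, ...] = (
        "HP:0004322",  # short stature
        "HP:0000098",  # tall stature
        "HP:0000252",  # microcephaly
        "HP:0000256",  # macrocephaly
    )
    facial_dysmorphism: tuple[TermId, ...] = ("HP:0001999",)
    non_facial_anomaly: tuple[TermId, ...] = (
        "HP:0000598",  # abnormality of the ear
        "HP:0000478",  # abnormality of the eye
        "HP:0001627",  # abnormal heart morphology
        "HP:0000924",  # abnormality of the skeletal system
        "HP:0000119",  # abnormality of the genitourinary system
    )

    def all_terms(self) -> tuple[TermId, ...]:
        return (
            self.developmental_delay
            + self.severe_developmental_delay
            + self.prenatal_growth_retardation
            + self.postnatal_growth
            + self.facial_dysmorphism
            + self.non_facial_anomaly
        )


def devries_score(
    individual: Individual,
    graph: OntologyGraph,
    anchors: DeVriesAnchors = DeVriesAnchors(),
) -> float:
    """HPO-adapted de Vries severity score in [0, 10], or NaN when unevaluable.

    Every component is evaluated via the descendant closure of its anchor
    terms.  An individual with no known (observed or excluded) annotation
    touching any component is excluded with NaN rather than scored 0.
    """
    present = [t for t in anchors.all_terms() if t in graph]
    if not present:
        raise ValueError(
            "none of the de Vries anchor terms exist in the ontology; "
            "configure DeVriesAnchors for this ontology"
        )
    obs, exc, _ = annotation_closures(individual, graph)

    def hit(anchor: TermId) -> bool:
        return anchor in graph and anchor in obs

    def known(anchor: TermId) -> bool:
        if anchor not in graph:
            return False
        closure = graph.descendants(anchor, include_self=True)
        return bool(closure & obs) or bool(closure & exc)

    if not any(known(t) for t in present):
        return math.nan

    score = 0.0
    # D1: developmental delay / intellectual disability
    if any(hit(t) for t in anchors.severe_developmental_delay):
        score += 2
    elif any(hit(t) for t in anchors.developmental_delay):
        score += 1
    # D2: prenatal-onset growth retardation
    if any(hit(t) for t in anchors.prenatal_growth_retardation):
        score += 2
    # D3: postnatal growth abnormalities, capped at 2
    score += min(2, sum(1 for t in anchors.postnatal_growth if hit(t)))
    # D4: >= 2 distinct facial dysmorphism annotations
    facial_closure: set[TermId] = set()
    for t in anchors.facial_dysmorphism:
        if t in graph:
            facial_closure |= graph.descendants(t, include_self=True)
    distinct_facial = individual.observed_terms() & facial_closure
    if len(distinct_facial) >= 2:
        score += 2
    # D5: non-facial dysmorphisms / congenital anomalies, capped at 2
    score += min(2, sum(1 for t in anchors.non_facial_anomaly if hit(t)))
    return score


def make_counting_scorer(graph: OntologyGraph, spec: ScoreSpec) -> Scorer:
    return lambda ind: counting_score(ind, graph, spec)


def make_devries_scorer(
    graph: OntologyGraph, anchors: DeVriesAnchors = DeVriesAnchors()
) -> Scorer:
    return lambda ind: devries_score(ind, graph, anchors)


@dataclass
class ScoreAnalysisResult:
    test: TestResult
    scores: dict[str, dict[str, float]] = field(default_factory=dict)  # label -> id -> score


def score_analysis(
    cohort: Cohort,
    assignment: ClassAssignment,
    scorer: Scorer,
) -> ScoreAnalysisResult:
    """Mann-Whitney U comparison of scores between two genotype classes.

    NaN scores and OMITTED individuals are dropped; a class left empty after
    omission is a degenerate input.
    """
    labels = [lab for lab in assignment.labels if lab != OMITTED]
    if len(labels) != 2:
        raise ValueError("score analysis requires exactly 2 genotype classes")
    scores: dict[str, dict[str, float]] = {lab: {} for lab in labels}
    n_omitted = 0
    for ind in cohort:
        label = assignment.by_individual.get(ind.id, OMITTED)
        if label == OMITTED:
            n_omitted += 1
            continue
        value = scorer(ind)
        if math.isnan(value):
            n_omitted += 1
            continue
        scores[label][ind.id] = value
    samples = [list(scores[lab].values()) for lab in labels]
    if any(not s for s in samples):
        raise ValueError(
            "a genotype class has no scoreable individuals; cannot compare"
        )
    u, p = mann_whitney_u(samples[0], samples[1])
    n_used = sum(len(s) for s in samples)
    return ScoreAnalysisResult(
        test=TestResult(
            statistic=u, p_raw=p, n_used=n_used, n_omitted=len(cohort) - n_used
        ),
        scores=scores,
    )
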