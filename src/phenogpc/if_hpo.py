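"""Independent filtering of phenotype terms before exact testing (IF-HPO).

Testing every annotated HPO term in a cohort inflates the multiple-testing
burden; most of those tests are redundant (parent terms whose counts are
derived entirely from a child) or hopeless (too few informative individuals
to ever reach significance).  IF-HPO removes such terms by five rules that
depend only on the ontology structure and the contingency-table margins —
quantities independent of the test statistic under the null — so type I
error control is preserved while power for the remaining terms increases.

Rules, applied in order with first-match-wins reporting:

1. GENERAL_LEVEL — terms within ``general_depth`` child-edges of the
   phenotype root (and terms outside the root's subgraph) are too general to
   be of interest; a real signal will surface in a more specific descendant.
2. SAME_AS_CHILD — a term whose per-class (observed, known) counts equal
   those of one of its children adds no information beyond the child.
3. LOW_COVERAGE — terms reported in less than ``min_coverage_fraction`` of
   the cohort (default 0.4).
4. LOW_TOTAL — 2x2 tables with fewer than 7 informative individuals (3x2:
   fewer than 6) can never reach nominal significance.
5. EMPTY_CLASS — no observed-or-excluded status in some genotype class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .cohort import Cohort
from .genotype import OMITTED, ClassAssignment
from .ontology import OntologyGraph, TermId, annotation_closures


@dataclass(frozen=True)
class IfHpoConfig:
    general_depth: int = 3
    min_coverage_fraction: float = 0.4
    min_total_2x2: int = 7
    min_total_3x2: int = 6
    #: denominator for rule 3: the full classified cohort or only
    #: individuals with known status for the term
    coverage_denominator: str = "cohort"

    def __post_init__(self) -> None:
        if self.general_depth < 1:
            raise ValueError("general_depth must be >= 1")
        if not 0 < self.min_coverage_fraction <= 1:
            raise ValueError("min_coverage_fraction must be in (0, 1]")
        if self.coverage_denominator not in ("cohort", "known"):
            raise ValueError("coverage_denominator must be 'cohort' or 'known'")


class SkipRule(enum.Enum):
    GENERAL_LEVEL = "GENERAL_LEVEL"
    SAME_AS_CHILD = "SAME_AS_CHILD"
    LOW_COVERAGE = "LOW_COVERAGE"
    LOW_TOTAL = "LOW_TOTAL"
    EMPTY_CLASS = "EMPTY_CLASS"


@dataclass(frozen=True)
class SkipReason:
    rule: SkipRule
    detail: str = ""


@dataclass
class CohortStatuses:
    """Propagated per-individual closures for the classified cohort members."""

    observed: dict[str, frozenset[TermId]] = field(default_factory=dict)
    excluded: dict[str, frozenset[TermId]] = field(default_factory=dict)

    @classmethod
    def from_cohort(
        cls, cohort: Cohort, assignment: ClassAssignment, graph: OntologyGraph
    ) -> "CohortStatuses":
        out = cls()
        for ind in cohort:
            if assignment.by_individual.get(ind.id, OMITTED) == OMITTED:
                continue
            obs, exc, _ = annotation_closures(ind, graph)
            out.observed[ind.id] = obs
            out.excluded[ind.id] = exc
        return out


def term_counts(
    cohort: Cohort,
    assignment: ClassAssignment,
    graph: OntologyGraph,
    term: TermId,
    statuses: CohortStatuses | None = None,
) -> dict[str, tuple[int, int]]:
    """Per-class (n_observed, n_known) counts for one term after propagation.

    Individuals OMITTED by the classifier contribute to no class, and
    individuals with UNKNOWN status for the term contribute to neither the
    numerator nor the denominator of their class.
    """
    graph._check(term)
    if statuses is None:
        statuses = CohortStatuses.from_cohort(cohort, assignment, graph)
    counts = {label: [0, 0] for label in assignment.labels}
    for ind_id, obs in statuses.observed.items():
        label = assignment.by_individual[ind_id]
        if term in obs:
            counts[label][0] += 1
            counts[label][1] += 1
        elif term in statuses.excluded[ind_id]:
            counts[label][1] += 1
    return {label: (c[0], c[1]) for label, c in counts.items()}


def candidate_terms(statuses: CohortStatuses, graph: OntologyGraph) -> set[TermId]:
    """Terms carrying any annotation (direct or via closure) in the cohort."""
    cand: set[TermId] = set()
    for obs in statuses.observed.values():
        cand |= obs
    for exc in statuses.excluded.values():
        cand |= exc
    return cand & graph.phenotype_domain


def select_testable_terms(
    cohort: Cohort,
    assignment: ClassAssignment,
    graph: OntologyGraph,
    config: IfHpoConfig = IfHpoConfig(),
) -> tuple[set[TermId], dict[TermId, SkipReason]]:
    """Apply the five IF-HPO rules; returns (tested, skipped-with-reasons).

    The rules use only ontology structure and contingency margins, never the
    test statistic, so the filter is independent of the FET under the null.
    """
    present = [lab for lab, n in assignment.counts.items() if lab != OMITTED and n > 0]
    if len(present) < 2:
        raise ValueError(
            "IF-HPO requires at least 2 populated genotype classes, "
            f"got {present}"
        )
    statuses = CohortStatuses.from_cohort(cohort, assignment, graph)
    candidates = candidate_terms(statuses, graph)
    n_classified = len(statuses.observed)
    n_classes = len(assignment.labels)
    min_total = config.min_total_2x2 if n_classes == 2 else config.min_total_3x2
    general = graph.general_terms(config.general_depth)

    all_counts = {
        t: term_counts(cohort, assignment, graph, t, statuses) for t in candidates
    }
    tested: set[TermId] = set()
    skipped: dict[TermId, SkipReason] = {}
    for term in sorted(candidates):
        counts = all_counts[term]
        if term in general:
            skipped[term] = SkipReason(
                SkipRule.GENERAL_LEVEL,
                f"within {config.general_depth} levels of the root",
            )
            continue
        twin = next(
            (
                child
                for child in sorted(graph.children(term) & candidates)
                if all_counts[child] == counts
            ),
            None,
        )
        if twin is not None:
            skipped[term] = SkipReason(
                SkipRule.SAME_AS_CHILD, f"counts identical to child {twin}"
            )
            continue
        n_obs_total = sum(c[0] for c in counts.values())
        n_known_total = sum(c[1] for c in counts.values())
        denom = n_classified if config.coverage_denominator == "cohort" else n_known_total
        if denom == 0 or n_obs_total / denom < config.min_coverage_fraction:
            skipped[term] = SkipReason(
                SkipRule.LOW_COVERAGE,
                f"observed in {n_obs_total}/{denom} "
                f"(< {config.min_coverage_fraction:g})",
            )
            continue
        if n_known_total < min_total:
            skipped[term] = SkipReason(
                SkipRule.LOW_TOTAL, f"total known {n_known_total} < {min_total}"
            )
            continue
        if any(c[1] == 0 for c in counts.values()):
            empty = [lab for lab, c in counts.items() if c[1] == 0]
            skipped[term] = SkipReason(
                SkipRule.EMPTY_CLASS, f"no observations in class(es) {empty}"
            )
            continue
        tested.add(term)
    return tested, skipped


def skip_report(
    skipped: dict[TermId, SkipReason], graph: OntologyGraph
) -> pd.DataFrame:
    """Tabulate every untested term with its rule and detail, for audit."""
    rows = [
        {
            "term_id": term,
            "term_label": graph.label(term),
            "reason": reason.rule.value,
            "detail": reason.detail,
        }
        for term, reason in sorted(skipped.items())
    ]
    return pd.DataFrame(rows, columns=["term_id", "term_label", "reason", "detail"])
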