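"""Right-censored time-to-event extraction and genotype-specific survival.

Endpoints are disease onset, onset of a phenotype term (with ontology
roll-up: the youngest onset among the term's observed descendants), or
death.  Individuals without the event are right-censored at the age of last
encounter; individuals for whom neither an event age nor a censoring age is
known are omitted, per the global missing-data contract.  Kaplan-Meier
curves come from lifelines; the log-rank test from :mod:`phenogpc.stats`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import Cohort, Individual, VitalStatus
from .genotype import OMITTED, ClassAssignment
from .ontology import OntologyGraph, TermId
from .stats import TestResult, log_rank


class EndpointKind(enum.Enum):
    DISEASE_ONSET = "DISEASE_ONSET"
    TERM_ONSET = "TERM_ONSET"
    DEATH = "DEATH"


@dataclass(frozen=True)
class Endpoint:
    kind: EndpointKind
    term: TermId | None = None  # required for TERM_ONSET
    disease_id: str | None = None  # optional restriction for DISEASE_ONSET

    def __post_init__(self) -> None:
        if self.kind is EndpointKind.TERM_ONSET and self.term is None:
            raise ValueError("TERM_ONSET endpoint requires a term")


@dataclass(frozen=True)
class SurvivalRecord:
    time: float  # age in years
    event: bool  # True = event observed, False = right-censored

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be non-negative")


def endpoint_age(
    individual: Individual, graph: OntologyGraph, endpoint: Endpoint
) -> SurvivalRecord | None:
    """Extract one individual's (time, event) for the endpoint, or None (omitted).

    TERM_ONSET takes the minimum onset over observed annotations in the
    descendant closure of the endpoint term; annotated-but-undated events
    and individuals with no usable age are omitted rather than guessed.
    """
    if endpoint.kind is EndpointKind.DEATH:
        if individual.vital is VitalStatus.DECEASED:
            if individual.age_at_death is None:
                return None
            return SurvivalRecord(individual.age_at_death, True)
        if (
            individual.vital is VitalStatus.ALIVE
            and individual.age_last_encounter is not None
        ):
            return SurvivalRecord(individual.age_last_encounter, False)
        return None

    if endpoint.kind is EndpointKind.DISEASE_ONSET:
        diseases = [
            d
            for d in individual.diseases
            if endpoint.disease_id is None or d.disease_id == endpoint.disease_id
        ]
        if diseases:
            onsets = [d.onset for d in diseases if d.onset is not None]
            if onsets:
                return SurvivalRecord(min(onsets), True)
            return None  # diagnosed, onset unrecorded
        if individual.age_last_encounter is not None:
            return SurvivalRecord(individual.age_last_encounter, False)
        return None

    # TERM_ONSET
    closure = graph.descendants(endpoint.term, include_self=True)
    hits = [
        f for f in individual.features if not f.excluded and f.term in closure
    ]
    if hits:
        onsets = [f.onset for f in hits if f.onset is not None]
        if onsets:
            return SurvivalRecord(min(onsets), True)
        return None  # event observed but undated
    if individual.age_last_encounter is not None:
        return SurvivalRecord(individual.age_last_encounter, False)
    return None


@dataclass
class SurvivalAnalysisResult:
    test: TestResult
    curves: dict[str, pd.DataFrame]  # label -> KM table


def km_curve(records: list[SurvivalRecord], label: str = "") -> pd.DataFrame:
    """Kaplan-Meier product-limit curve as a tidy table."""
    kmf = KaplanMeierFitter(label=label or None)
    kmf.fit([r.time for r in records], [r.event for r in records])
    table = kmf.event_table
    surv = kmf.survival_function_
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
        }
    )


def survival_analysis(
    cohort: Cohort,
    assignment: ClassAssignment,
    endpoint: Endpoint,
    graph: OntologyGraph,
) -> SurvivalAnalysisResult:
    """Per-class KM curves plus a 2-class log-rank test for the endpoint."""
    labels = [lab for lab in assignment.labels if lab != OMITTED]
    if len(labels) != 2:
        raise ValueError("survival analysis requires exactly 2 genotype classes")
    per_class: dict[str, list[SurvivalRecord]] = {lab: [] for lab in labels}
    n_omitted = 0
    for ind in cohort:
        label = assignment.by_individual.get(ind.id, OMITTED)
        if label == OMITTED:
            n_omitted += 1
            continue
        rec = endpoint_age(ind, graph, endpoint)
        if rec is None:
            n_omitted += 1
            continue
        per_class[label].append(rec)
    if any(not recs for recs in per_class.values()):
        raise ValueError("a genotype class has no usable survival records")
    flat = [
        (r.time, r.event, lab) for lab, recs in per_class.items() for r in recs
    ]
    chi2, p = log_rank(flat)
    curves = {lab: km_curve(recs, lab) for lab, recs in per_class.items()}
    n_used = sum(len(r) for r in per_class.values())
    return SurvivalAnalysisResult(
        test=TestResult(
            statistic=chi2, p_raw=p, n_used=n_used, n_omitted=len(cohort) - n_used
        ),
        curves=curves,
    )


def curves_to_tsv(result: SurvivalAnalysisResult) -> pd.DataFrame:
    """Stack per-class KM curves into one exportable table."""
    frames = []
    for label, curve in result.curves.items():
        frame = curve.copy()
        frame.insert(0, "class", label)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
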