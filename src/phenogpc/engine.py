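"""End-to-end analysis orchestration and result tables.

``run_categorical`` is the workhorse: resolve the term scope (IF-HPO
filtering by default), build one r x 2 contingency table per testable term
from propagated statuses, apply the exact test, and correct across the
tested terms only.  Score, measurement, and survival runs are treated as
separate single hypotheses and receive no multiple-testing correction,
mirroring the convention that only the categorical family is corrected.
Sex and diagnosis analyses reuse the categorical machinery with the
corresponding classifier.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import Cohort
from .genotype import (
    OMITTED,
    ClassAssignment,
    GenotypeClassifier,
    classify_cohort,
    diagnosis_classifier,
    sex_classifier,
)
from .if_hpo import (
    CohortStatuses,
    IfHpoConfig,
    candidate_terms,
    select_testable_terms,
    skip_report,
    term_counts,
)
from .ontology import OntologyGraph, TermId
from .scoring import ScoreAnalysisResult, Scorer, score_analysis
from .stats import TestResult, adjust_pvalues, exact_rx2, fisher_exact_2x2, t_test
from .survival import Endpoint, SurvivalAnalysisResult, survival_analysis

#: Term-scope sentinels for categorical runs.
SCOPE_IF_HPO = "IF_HPO"
SCOPE_ALL = "ALL"


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    mtc_method: str = "fdr_bh"
    if_hpo: IfHpoConfig = field(default_factory=IfHpoConfig)
    #: SCOPE_IF_HPO, SCOPE_ALL, or an explicit tuple of terms
    term_scope: str | tuple[TermId, ...] = SCOPE_IF_HPO

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ResultTable:
    """Per-hypothesis results plus skip diagnostics and run metadata."""

    table: pd.DataFrame
    skipped: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def skipped_to_tsv(self, path) -> None:
        self.skipped.to_csv(path, sep="\t", index=False)

    def to_json(self) -> dict:
        return {
            "metadata": self.metadata,
            "results": self.table.to_dict(orient="records"),
            "skipped": self.skipped.to_dict(orient="records"),
        }


def _resolve_assignment(
    cohort: Cohort, classifier_or_assignment
) -> ClassAssignment:
    if isinstance(classifier_or_assignment, ClassAssignment):
        return classifier_or_assignment
    if isinstance(classifier_or_assignment, GenotypeClassifier):
        return classify_cohort(cohort, classifier_or_assignment)
    raise TypeError("expected a GenotypeClassifier or ClassAssignment")


_RESULT_COLUMNS = [
    "term_id",
    "term_label",
    "counts",
    "p_raw",
    "p_adjusted",
    "significant",
    "n_used",
    "n_omitted",
]


def run_categorical(
    cohort: Cohort,
    classifier,
    graph: OntologyGraph,
    config: AnalysisConfig = AnalysisConfig(),
) -> ResultTable:
    """Exact test of every in-scope term against the genotype partition.

    2-class partitions use the two-sided 2x2 Fisher test; 3-class partitions
    the Freeman-Halton 3x2 test.  Multiple-testing correction is applied
    across the tested terms only.  Zero testable terms is not an error: the
    result table is empty and the skip report is complete.
    """
    assignment = _resolve_assignment(cohort, classifier)
    statuses = CohortStatuses.from_cohort(cohort, assignment, graph)
    if config.term_scope == SCOPE_IF_HPO:
        tested, skipped = select_testable_terms(
            cohort, assignment, graph, config.if_hpo
        )
    elif config.term_scope == SCOPE_ALL:
        tested = candidate_terms(statuses, graph)
        skipped = {}
    else:
        for term in config.term_scope:
            graph._check(term)
        tested = set(config.term_scope)
        skipped = {}

    rows = []
    for term in sorted(tested):
        counts = term_counts(cohort, assignment, graph, term, statuses)
        table = [
            [counts[lab][0], counts[lab][1] - counts[lab][0]]
            for lab in assignment.labels
        ]
        if len(assignment.labels) == 2:
            p = fisher_exact_2x2(table)
        else:
            p = exact_rx2(table)
        n_used = sum(c[1] for c in counts.values())
        rows.append(
            {
                "term_id": term,
                "term_label": graph.label(term),
                "counts": "; ".join(
                    f"{lab}: {counts[lab][0]}/{counts[lab][1]}"
                    for lab in assignment.labels
                ),
                "p_raw": p,
                "n_used": n_used,
                "n_omitted": len(cohort) - n_used,
            }
        )
    df = pd.DataFrame(rows, columns=[c for c in _RESULT_COLUMNS if c not in ("p_adjusted", "significant")])
    if len(df):
        df["p_adjusted"] = adjust_pvalues(df["p_raw"].tolist(), config.mtc_method)
        df["significant"] = df["p_adjusted"] < config.alpha
        df = df.sort_values(
            ["p_adjusted", "p_raw", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    df = df[_RESULT_COLUMNS]
    return ResultTable(
        table=df,
        skipped=skip_report(skipped, graph),
        metadata=_metadata("categorical", assignment, config),
    )


def run_measurement(
    cohort: Cohort,
    classifier,
    assay_id: str,
    config: AnalysisConfig = AnalysisConfig(),
    equal_var: bool = True,
) -> TestResult:
    """Unpaired two-sided t test of one assay between two genotype classes.

    One test per call; no multiple-testing correction is applied.
    """
    assignment = _resolve_assignment(cohort, classifier)
    labels = list(assignment.labels)
    if len(labels) != 2:
        raise ValueError("measurement analysis requires exactly 2 classes")
    samples: dict[str, list[float]] = {lab: [] for lab in labels}
    for ind in cohort:
        label = assignment.by_individual.get(ind.id, OMITTED)
        if label == OMITTED:
            continue
        values = [m.value for m in ind.measurements if m.assay_id == assay_id]
        if values:
            samples[label].extend(values)
    if any(not v for v in samples.values()):
        raise ValueError(
            f"assay {assay_id!r} has no measurements in class(es) "
            f"{[lab for lab, v in samples.items() if not v]}"
        )
    if any(len(v) < 2 for v in samples.values()):
        raise ValueError(
            f"assay {assay_id!r} needs at least 2 measurements per class"
        )
    t, p = t_test(samples[labels[0]], samples[labels[1]], equal_var=equal_var)
    n_used = sum(len(v) for v in samples.values())
    return TestResult(
        statistic=t, p_raw=p, n_used=n_used, n_omitted=len(cohort) - n_used
    )


def run_score(
    cohort: Cohort,
    classifier,
    scorer: Scorer,
) -> ScoreAnalysisResult:
    """Mann-Whitney U comparison of a phenotype severity score (no MTC)."""
    assignment = _resolve_assignment(cohort, classifier)
    return score_analysis(cohort, assignment, scorer)


def run_survival(
    cohort: Cohort,
    classifier,
    endpoint: Endpoint,
    graph: OntologyGraph,
) -> SurvivalAnalysisResult:
    """Log-rank comparison of a time-to-event endpoint (no MTC)."""
    assignment = _resolve_assignment(cohort, classifier)
    return survival_analysis(cohort, assignment, endpoint, graph)


def run_sex(
    cohort: Cohort,
    graph: OntologyGraph,
    config: AnalysisConfig = AnalysisConfig(),
) -> ResultTable:
    """Categorical analysis of phenotypic features between males and females."""
    return run_categorical(cohort, sex_classifier(), graph, config)


def run_diagnosis(
    cohort: Cohort,
    disease_ids,
    graph: OntologyGraph,
    config: AnalysisConfig = AnalysisConfig(),
) -> ResultTable:
    """Categorical analysis of phenotypic features between disease diagnoses."""
    return run_categorical(
        cohort, diagnosis_classifier(disease_ids), graph, config
    )


def _metadata(kind: str, assignment: ClassAssignment, config: AnalysisConfig) -> dict:
    return {
        "analysis": kind,
        "classifier": assignment.description,
        "class_counts": assignment.counts,
        "alpha": config.alpha,
        "mtc_method": config.mtc_method,
        "term_scope": config.term_scope
        if isinstance(config.term_scope, str)
        else list(config.term_scope),
        "config_hash": config.hash(),
        "version": __version__,
    }


def write_run_manifest(out_dir, metadata: dict, inputs: dict) -> Path:
    """Write a machine-readable record of one run's inputs and configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(
            {"inputs": inputs, "metadata": metadata}, fh, indent=2, sort_keys=True
        )
        fh.write("\n")
    return path
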