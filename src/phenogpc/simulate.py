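"""Hermetic synthetic fixtures: toy ontologies and cohorts with planted effects.

The generator emulates the structure of real case-level inputs — a rooted
multi-parent phenotype DAG, phenopacket JSON records with observed/excluded
leaf annotations, onsets, measurements and causal variants, plus the variant
annotation sidecar — at toy scale, so every analysis path can be exercised
without downloads.  Penetrance is specified at leaf terms; ancestors acquire
status only through true-path propagation, matching real annotation
practice.  Everything is driven by one integer seed and the same
configuration always produces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import (
    Cohort,
    DiseaseRecord,
    Individual,
    MeasurementRecord,
    PhenotypicFeatureRecord,
    Sex,
    VariantRecord,
    VitalStatus,
    write_phenopacket,
)
from .genotype import GenotypeClassifier, monoallelic_classifier, pred_consequence
from .ontology import OntologyGraph, TermId, build_ontology

ROOT = "HP:0000118"

#: Consequence assigned to the planted causal variant of each genotype class.
CLASS_CONSEQUENCES = ("missense_variant", "stop_gained")


def make_toy_ontology(
    branches: int,
    depth: int,
    seed: int = 0,
    fanout: int = 2,
    multiparent_fraction: float = 0.0,
) -> OntologyGraph:
    """Build a rooted DAG: *branches* subtrees of *depth* levels, each node
    with *fanout* children, plus a seeded fraction of multi-parent nodes."""
    if branches < 1 or depth < 2:
        raise ValueError("need branches >= 1 and depth >= 2")
    rng = np.random.default_rng(seed)
    counter = 0

    def new_term() -> TermId:
        nonlocal counter
        counter += 1
        return f"HP:{5000000 + counter:07d}"

    edges: list[tuple[TermId, TermId]] = []
    labels = {ROOT: "Phenotypic abnormality"}
    by_level: dict[int, list[TermId]] = {0: [ROOT]}
    for _ in range(branches):
        top = new_term()
        edges.append((top, ROOT))
        by_level.setdefault(1, []).append(top)
        frontier = [top]
        for level in range(2, depth + 1):
            nxt = []
            for parent in frontier:
                for _ in range(fanout):
                    child = new_term()
                    edges.append((child, parent))
                    nxt.append(child)
            by_level.setdefault(level, []).extend(nxt)
            frontier = nxt
    # extra is_a parents one level up, keeping the graph acyclic
    if multiparent_fraction > 0:
        for level in range(3, depth + 1):
            for term in by_level.get(level, []):
                if rng.random() < multiparent_fraction:
                    candidates = [
                        p
                        for p in by_level[level - 1]
                        if (term, p) not in edges
                    ]
                    if candidates:
                        extra = candidates[int(rng.integers(len(candidates)))]
                        edges.append((term, extra))
    for term in {t for e in edges for t in e}:
        labels.setdefault(term, f"Toy term {term.split(':')[1]}")
    return build_ontology(ROOT, edges, labels=labels)


def ontology_to_edge_list(graph: OntologyGraph) -> dict:
    """Serialize to the edge-list JSON dialect consumed by ``load_ontology``."""
    return {
        "root": graph.root,
        "terms": [
            {"id": t, "label": graph.label(t)} for t in sorted(graph.terms)
        ],
        "edges": sorted(
            [child, parent] for child, parent in graph.graph.edges
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort."""

    seed: int = 0
    n_individuals: int = 50
    genotype_split: tuple[float, ...] = (0.5, 0.5)
    #: assign exact class counts (n * split, randomly permuted) instead of
    #: drawing each individual's class independently
    balanced_classes: bool = False
    #: planted signal: leaf term -> per-class penetrance
    penetrance: dict[TermId, tuple[float, ...]] = field(default_factory=dict)
    #: number of null leaf terms annotated with a class-independent penetrance
    n_nuisance_terms: int | None = None
    nuisance_penetrance_range: tuple[float, float] = (0.05, 0.35)
    #: probability an absent feature is explicitly recorded as excluded
    exclusion_recording_prob: float = 0.5
    #: probability a feature's status goes entirely unrecorded
    status_missingness_prob: float = 0.1
    #: optional time-to-event endpoint: term plus per-class onset distribution,
    #: each ("exponential", rate) or ("weibull", shape, scale); onsets in years
    onset_term: TermId | None = None
    onset_dist: tuple[tuple, ...] = ()
    censoring_prob: float = 0.3
    #: optional measurement: (assay_id, unit, per-class (mean, sd))
    measurement: tuple | None = None
    disease_ids: tuple[str, ...] = ("MONDO:0000001",)

    def __post_init__(self) -> None:
        if abs(sum(self.genotype_split) - 1.0) > 1e-9:
            raise ValueError("genotype_split must sum to 1")
        for p in (
            self.exclusion_recording_prob,
            self.status_missingness_prob,
            self.censoring_prob,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside every generated cohort."""

    class_of: dict[str, int]
    signal_terms: dict[TermId, tuple[float, ...]]
    nuisance_terms: dict[TermId, float]

    def to_json(self) -> dict:
        return {
            "class_of": self.class_of,
            "signal_terms": {t: list(p) for t, p in self.signal_terms.items()},
            "nuisance_terms": self.nuisance_terms,
        }


def planted_classifier() -> GenotypeClassifier:
    """The classifier that recovers the generator's two genotype classes."""
    return monoallelic_classifier(
        pred_consequence(CLASS_CONSEQUENCES[0]),
        pred_consequence(CLASS_CONSEQUENCES[1]),
        labels=("class0", "class1"),
    )


def _draw_onset(rng: np.random.Generator, dist: tuple) -> float:
    kind = dist[0]
    if kind == "exponential":
        return float(rng.exponential(1.0 / dist[1]))
    if kind == "weibull":
        shape, scale = dist[1], dist[2]
        return float(scale * rng.weibull(shape))
    raise ValueError(f"unknown onset distribution {dist!r}")


def simulate_cohort(
    graph: OntologyGraph, config: SimConfig, out_dir=None
) -> tuple[Cohort, PlantedTruth]:
    """Generate a cohort with planted genotype-phenotype effects.

    Each individual draws a genotype class from ``genotype_split`` and
    receives a fabricated heterozygous causal variant whose consequence
    identifies the class, so :func:`planted_classifier` reproduces the
    planted labels exactly.  Each penetrance-bearing leaf term is observed
    with the class's penetrance; unobserved features are explicitly excluded
    with ``exclusion_recording_prob`` and silently absent otherwise, and any
    feature's status is dropped entirely with ``status_missingness_prob``.
    When *out_dir* is given, phenopacket JSONs, the sidecar TSV, the
    ontology, and the planted truth are written there.
    """
    for term in config.penetrance:
        if term not in graph:
            raise ValueError(f"penetrance refers to unknown term {term}")
    n_classes = len(config.genotype_split)
    if n_classes != 2:
        raise ValueError("the generator plants exactly 2 genotype classes")
    rng = np.random.default_rng(config.seed)

    leaves = sorted(
        t
        for t in graph.phenotype_domain
        if t != graph.root and not graph.children(t)
    )
    free_leaves = [t for t in leaves if t not in config.penetrance]
    if config.n_nuisance_terms is None:
        nuisance = list(free_leaves)
    else:
        if config.n_nuisance_terms > len(free_leaves):
            raise ValueError("not enough leaf terms for the requested nuisance count")
        idx = rng.choice(len(free_leaves), size=config.n_nuisance_terms, replace=False)
        nuisance = [free_leaves[i] for i in sorted(idx)]
    lo, hi = config.nuisance_penetrance_range
    nuisance_pen = {t: float(rng.uniform(lo, hi)) for t in nuisance}

    term_pen: dict[TermId, tuple[float, ...]] = dict(config.penetrance)
    term_pen.update({t: (p,) * n_classes for t, p in nuisance_pen.items()})
    ordered_terms = sorted(term_pen)

    if config.balanced_classes:
        n0 = round(config.n_individuals * config.genotype_split[0])
        fixed = np.array([0] * n0 + [1] * (config.n_individuals - n0))
        class_draw = rng.permutation(fixed)
    else:
        class_draw = rng.choice(
            n_classes, size=config.n_individuals, p=config.genotype_split
        )

    individuals = []
    class_of: dict[str, int] = {}
    width = len(str(config.n_individuals))
    for i in range(config.n_individuals):
        ind_id = f"sim-{i + 1:0{width}d}"
        cls = int(class_draw[i])
        class_of[ind_id] = cls
        sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE

        features: list[PhenotypicFeatureRecord] = []
        for term in ordered_terms:
            pen = term_pen[term][cls]
            observed = rng.random() < pen
            if rng.random() < config.status_missingness_prob:
                continue
            if observed:
                features.append(PhenotypicFeatureRecord(term=term))
            elif rng.random() < config.exclusion_recording_prob:
                features.append(PhenotypicFeatureRecord(term=term, excluded=True))

        age_last = round(float(rng.uniform(1.0, 40.0)), 2)
        if config.onset_term is not None:
            event_time = round(_draw_onset(rng, config.onset_dist[cls]), 3)
            if rng.random() < config.censoring_prob:
                age_last = round(event_time * float(rng.uniform(0.0, 1.0)), 3)
            else:
                features.append(
                    PhenotypicFeatureRecord(term=config.onset_term, onset=event_time)
                )
                age_last = round(event_time + 1.0, 3)

        measurements = []
        if config.measurement is not None:
            assay_id, unit, params = config.measurement
            mean, sd = params[cls]
            measurements.append(
                MeasurementRecord(
                    assay_id=assay_id,
                    value=round(float(rng.normal(mean, sd)), 4),
                    unit=unit,
                )
            )

        variants = [
            VariantRecord(
                key=f"var_class{cls}",
                gene="GENE1",
                consequences=frozenset({CLASS_CONSEQUENCES[cls]}),
                allele_count=1,
            )
        ]
        disease = config.disease_ids[min(cls, len(config.disease_ids) - 1)]
        individuals.append(
            Individual(
                id=ind_id,
                sex=sex,
                age_last_encounter=age_last,
                vital=VitalStatus.ALIVE,
                features=features,
                measurements=measurements,
                diseases=[DiseaseRecord(disease_id=disease, label=disease)],
                variants=variants,
            )
        )

    cohort = Cohort(individuals=individuals, provenance=["simulate_cohort"])
    truth = PlantedTruth(
        class_of=class_of,
        signal_terms=dict(config.penetrance),
        nuisance_terms=nuisance_pen,
    )
    if out_dir is not None:
        write_fixture(cohort, truth, graph, out_dir)
    return cohort, truth


def sidecar_rows() -> list[dict]:
    """Sidecar annotation rows for the generator's fabricated variants."""
    return [
        {
            "key": f"var_class{cls}",
            "gene": "GENE1",
            "transcript": "NM_000001.1",
            "consequences": consequence,
            "exons": str(cls + 1),
            "protein_start": str(100 * (cls + 1)),
            "protein_end": str(100 * (cls + 1)),
            "change_length": "0" if consequence == "missense_variant" else "0",
            "structural_kind": "",
        }
        for cls, consequence in enumerate(CLASS_CONSEQUENCES)
    ]


def write_fixture(
    cohort: Cohort, truth: PlantedTruth, graph: OntologyGraph, out_dir
) -> None:
    """Write phenopackets/, annotations.tsv, ontology.json, truth.json."""
    out = Path(out_dir)
    pp_dir = out / "phenopackets"
    pp_dir.mkdir(parents=True, exist_ok=True)
    for ind in cohort:
        doc = write_phenopacket(ind)
        with open(pp_dir / f"{ind.id}.json", "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    header = [
        "key",
        "gene",
        "transcript",
        "consequences",
        "exons",
        "protein_start",
        "protein_end",
        "change_length",
        "structural_kind",
    ]
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in sidecar_rows():
            fh.write("\t".join(row[c] for c in header) + "\n")
    with open(out / "ontology.json", "w") as fh:
        json.dump(ontology_to_edge_list(graph), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")
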