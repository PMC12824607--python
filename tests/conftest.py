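"""Shared fixtures: toy ontologies and cohort builders."""

from __future__ import annotations

import pytest

from phenogpc.cohort import Individual, PhenotypicFeatureRecord
from phenogpc.ontology import build_ontology

ROOT = "HP:0000118"
EYE = "HP:0000478"
LENS = "HP:0000517"
CATARACT = "HP:0000518"
ZONULAR = "HP:0010920"
NUCLEAR = "HP:0100018"


@pytest.fixture
def chain_graph():
    """Six-term chain: root -> Eye -> Lens -> Cataract -> Zonular -> Nuclear."""
    return build_ontology(
        ROOT,
        [
            (EYE, ROOT),
            (LENS, EYE),
            (CATARACT, LENS),
            (ZONULAR, CATARACT),
            (NUCLEAR, ZONULAR),
        ],
        labels={
            ROOT: "Phenotypic abnormality",
            EYE: "Abnormality of the eye",
            LENS: "Abnormality of the lens",
            CATARACT: "Cataract",
            ZONULAR: "Zonular cataract",
            NUCLEAR: "Nuclear cataract",
        },
    )


@pytest.fixture
def diamond_graph():
    """Root -> A -> {B, C} -> D: D has two parents sharing a grandparent."""
    return build_ontology(
        ROOT,
        [
            ("HP:0000001", ROOT),
            ("HP:0000002", "HP:0000001"),
            ("HP:0000003", "HP:0000001"),
            ("HP:0000004", "HP:0000002"),
            ("HP:0000004", "HP:0000003"),
        ],
    )


def make_individual(
    ind_id="P1", observed=(), excluded=(), onsets=None, **kwargs
) -> Individual:
    onsets = onsets or {}
    features = [
        PhenotypicFeatureRecord(term=t, onset=onsets.get(t)) for t in observed
    ]
    features += [
        PhenotypicFeatureRecord(term=t, excluded=True) for t in excluded
    ]
    return Individual(id=ind_id, features=features, **kwargs)


@pytest.fixture
def individual_factory():
    return make_individual
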