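"""Phenotype ontology: a multi-parent is_a DAG with true-path-rule propagation.

Phenotype terms (e.g. HPO terms such as ``HP:0000486`` *Strabismus*) form a
directed acyclic graph in which an edge ``child is_a parent`` means every
individual with the child manifestation also has the parent manifestation.
Annotation therefore propagates: an *observed* term implies all of its
ancestors are observed, and an *excluded* term implies all of its descendants
are excluded (the "true path rule").  This module loads such ontologies from
OBO-graph JSON or a simple edge-list dialect, answers ancestor/descendant
queries, identifies "general-level" terms near the root, and resolves the
observed/excluded/unknown status of any term for one individual.
"""

from __future__ import annotations

import enum
import json
import logging
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import Individual

logger = logging.getLogger(__name__)

#: A term identifier is a CURIE string, e.g. ``HP:0001250``.
TermId = str

_CURIE_RE = re.compile(r"^[^\s:]+:[^\s:]+$")


class OntologyError(Exception):
    """Structural or configuration problem with an ontology file."""


class TermNotFoundError(KeyError):
    """A queried term is not present in the ontology."""

    def __init__(self, term: TermId):
        super().__init__(term)
        self.term = term

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return f"term not found in ontology: {self.term}"


class TermStatus(enum.Enum):
    """Status of one (individual, term) pair after propagation."""

    OBSERVED = "OBSERVED"
    EXCLUDED = "EXCLUDED"
    UNKNOWN = "UNKNOWN"


def validate_curie(curie: str) -> TermId:
    """Check that *curie* is a non-empty ``PREFIX:LOCAL`` identifier."""
    if not isinstance(curie, str) or not _CURIE_RE.match(curie):
        raise OntologyError(f"not a valid CURIE term identifier: {curie!r}")
    return curie


def _iri_to_curie(node_id: str) -> str:
    """Normalize an OBO-style IRI (``.../HP_0000118``) to a CURIE; CURIEs pass through."""
    if node_id.startswith(("http://", "https://")):
        frag = node_id.rsplit("/", 1)[-1].rsplit("#", 1)[-1]
        if "_" in frag:
            prefix, local = frag.split("_", 1)
            return f"{prefix}:{local}"
        return frag
    return node_id


@dataclass
class OntologyGraph:
    """A rooted is_a DAG of phenotype terms.

    Edges are stored child -> parent in a :class:`networkx.DiGraph`, so a
    term's ancestors are the nodes reachable *from* it and its descendants
    are the nodes that reach it.
    """

    graph: nx.DiGraph
    root: TermId
    labels: dict[TermId, str] = field(default_factory=dict)

    # -- lazy caches (per-instance, keyed by term) ---------------------------
    _anc_cache: dict[TermId, frozenset[TermId]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _desc_cache: dict[TermId, frozenset[TermId]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _phenotype_domain: frozenset[TermId] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.root not in self.graph:
            raise OntologyError(f"root term {self.root} is not in the graph")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(
                f"ontology contains a cycle involving {cycle[0][0]}"
            )
        if self.graph.out_degree(self.root) > 0:
            raise OntologyError(
                f"root term {self.root} has a parent inside the graph"
            )

    # -- basic queries -------------------------------------------------------

    def __contains__(self, term: TermId) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def terms(self) -> frozenset[TermId]:
        return frozenset(self.graph.nodes)

    def label(self, term: TermId) -> str:
        return self.labels.get(term, term)

    def parents(self, term: TermId) -> set[TermId]:
        self._check(term)
        return set(self.graph.successors(term))

    def children(self, term: TermId) -> set[TermId]:
        self._check(term)
        return set(self.graph.predecessors(term))

    def _check(self, term: TermId) -> None:
        if term not in self.graph:
            raise TermNotFoundError(term)

    # -- closures ------------------------------------------------------------

    def ancestors(self, term: TermId, include_self: bool = False) -> set[TermId]:
        """All terms reachable from *term* via is_a edges (transitive parents)."""
        self._check(term)
        if term not in self._anc_cache:
            self._anc_cache[term] = frozenset(nx.descendants(self.graph, term))
        out = set(self._anc_cache[term])
        if include_self:
            out.add(term)
        return out

    def descendants(self, term: TermId, include_self: bool = False) -> set[TermId]:
        """All terms from which *term* is reachable (transitive children)."""
        self._check(term)
        if term not in self._desc_cache:
            self._desc_cache[term] = frozenset(nx.ancestors(self.graph, term))
        out = set(self._desc_cache[term])
        if include_self:
            out.add(term)
        return out

    @property
    def phenotype_domain(self) -> frozenset[TermId]:
        """The root plus all of its descendants — the only terms ever tested."""
        if self._phenotype_domain is None:
            self._phenotype_domain = frozenset(
                self.descendants(self.root, include_self=True)
            )
        return self._phenotype_domain

    def general_terms(self, depth: int) -> set[TermId]:
        """Terms within *depth* child-edges of the root, plus out-of-domain terms.

        "Depth" is the shortest-path distance from the root over child edges;
        multi-parent terms take the minimum over paths.  Terms that are not
        descendants of the root (e.g. clinical-modifier branches) are always
        included — they are never candidates for testing.
        """
        if depth < 1:
            raise ValueError("depth must be >= 1")
        dist = nx.single_source_shortest_path_length(
            self.graph.reverse(copy=False), self.root, cutoff=depth
        )
        general = set(dist)  # includes the root (distance 0)
        general |= self.terms - self.phenotype_domain
        return general


def load_ontology(source, fmt: str | None = None) -> OntologyGraph:
    """Load an ontology from OBO-graph JSON or the edge-list JSON dialect.

    Only ``is_a`` edges are consumed; other edge types are dropped with a
    warning.  The format is auto-detected when *fmt* is None.
    """
    with open(source) as fh:
        doc = json.load(fh)
    if fmt is None:
        fmt = "obo-graph-json" if "graphs" in doc else "edge-list-json"
    if fmt == "obo-graph-json":
        return _from_obograph(doc)
    if fmt == "edge-list-json":
        return _from_edge_list(doc)
    raise OntologyError(f"unknown ontology format: {fmt}")


def build_ontology(
    root: TermId,
    edges: Iterable[tuple[TermId, TermId]],
    labels: Mapping[TermId, str] | None = None,
    extra_terms: Iterable[TermId] = (),
) -> OntologyGraph:
    """Construct an :class:`OntologyGraph` from (child, parent) pairs."""
    g = nx.DiGraph()
    g.add_node(validate_curie(root))
    for term in extra_terms:
        g.add_node(validate_curie(term))
    for child, parent in edges:
        g.add_edge(validate_curie(child), validate_curie(parent))
    return OntologyGraph(graph=g, root=root, labels=dict(labels or {}))


def _from_edge_list(doc: dict) -> OntologyGraph:
    try:
        root = doc["root"]
        terms = doc.get("terms", [])
        edges = doc["edges"]
    except KeyError as exc:
        raise OntologyError(f"edge-list ontology missing key: {exc}") from exc
    labels = {t["id"]: t.get("label", t["id"]) for t in terms}
    return build_ontology(
        root,
        [(c, p) for c, p in edges],
        labels=labels,
        extra_terms=list(labels),
    )


_OBO_ROOT_CANDIDATES = ("HP:0000118",)


def _from_obograph(doc: dict, root: TermId | None = None) -> OntologyGraph:
    try:
        g0 = doc["graphs"][0]
    except (KeyError, IndexError) as exc:
        raise OntologyError("OBO-graph JSON has no graphs[0]") from exc
    labels: dict[TermId, str] = {}
    terms: list[TermId] = []
    for node in g0.get("nodes", []):
        curie = _iri_to_curie(node["id"])
        terms.append(curie)
        if node.get("lbl"):
            labels[curie] = node["lbl"]
    edges = []
    for edge in g0.get("edges", []):
        pred = edge.get("pred", "")
        if pred not in ("is_a", "subClassOf", "rdfs:subClassOf"):
            logger.warning("dropping non-is_a edge with pred=%r", pred)
            continue
        edges.append((_iri_to_curie(edge["sub"]), _iri_to_curie(edge["obj"])))
    if root is None:
        root = doc.get("root")
    if root is None:
        present = set(terms) | {t for e in edges for t in e}
        for cand in _OBO_ROOT_CANDIDATES:
            if cand in present:
                root = cand
                break
    if root is None:
        raise OntologyError(
            "could not resolve the phenotype root term in the OBO graph"
        )
    return build_ontology(root, edges, labels=labels, extra_terms=terms)


# ---------------------------------------------------------------------------
# Annotation propagation
# ---------------------------------------------------------------------------


def annotation_closures(
    individual: "Individual", graph: OntologyGraph
) -> tuple[frozenset[TermId], frozenset[TermId], frozenset[TermId]]:
    """Propagate one individual's annotations per the true path rule.

    Returns ``(observed, excluded, conflicts)`` where *observed* is the
    ancestor-closure of the observed features clipped to the phenotype
    domain, *excluded* is the descendant-closure of the excluded features,
    and *conflicts* holds terms claimed by both closures.  Conflicting terms
    are removed from both sets, so their status resolves to UNKNOWN.
    """
    obs: set[TermId] = set()
    exc: set[TermId] = set()
    for feature in individual.features:
        term = feature.term
        if term not in graph:
            raise TermNotFoundError(term)
        if feature.excluded:
            exc |= graph.descendants(term, include_self=True)
        else:
            obs |= graph.ancestors(term, include_self=True)
    obs &= graph.phenotype_domain
    conflicts = obs & exc
    if conflicts:
        logger.warning(
            "individual %s: %d term(s) both observed-by-ancestry and "
            "excluded-by-descent resolve to UNKNOWN",
            individual.id,
            len(conflicts),
        )
    return (
        frozenset(obs - conflicts),
        frozenset(exc - conflicts),
        frozenset(conflicts),
    )


def term_status(
    individual: "Individual", graph: OntologyGraph, term: TermId
) -> TermStatus:
    """Resolve the observed/excluded/unknown status of *term* for one individual."""
    graph._check(term)
    obs, exc, _ = annotation_closures(individual, graph)
    if term in obs:
        return TermStatus.OBSERVED
    if term in exc:
        return TermStatus.EXCLUDED
    return TermStatus.UNKNOWN
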