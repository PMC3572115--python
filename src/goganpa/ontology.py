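"""Gene Ontology DAG and annotation handling.

Parses OBO 1.2 ontology documents and GAF-style annotation files, filters
annotation records by evidence code, namespace and qualifier, and propagates
direct annotations up the ontology (true-path rule) so that term-specificity
measures can be computed on ancestor-closed gene counts.

Evidence-code policy: records with evidence ``ND`` (no biological data
available) are always dropped; exclusion of electronically inferred
annotations (``IEA``) is the caller's switch — a network built without IEA
is the curated-only variant, a network built with IEA the high-coverage one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

#: namespaces as they appear in OBO documents, mapped to the short labels
#: used throughout this package.
NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
#: GAF column-9 aspect letters.
ASPECT_CODES = {"P": "BP", "F": "MF", "C": "CC"}

#: evidence code that is unconditionally excluded.
ALWAYS_EXCLUDED_EVIDENCE = frozenset({"ND"})


class OboParseError(ValueError):
    """Raised for a malformed OBO stanza; message names the offending line."""


class OntologyValidationError(ValueError):
    """Raised when the parsed ontology violates a structural invariant."""


@dataclass(frozen=True)
class Term:
    id: str
    name: str
    namespace: str  # BP / MF / CC
    obsolete: bool = False


@dataclass
class OntologyDAG:
    """GO terms plus directed child->parent edges (``is_a``, ``part_of``).

    Obsolete terms are recorded in :attr:`terms` but carry no edges and are
    invisible to traversal. The graph restricted to any namespace is acyclic
    (validated at construction).
    """

    terms: dict[str, Term]
    graph: nx.DiGraph  # nodes: non-obsolete term ids; edges child -> parent
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False
    )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All ancestors of ``term_id`` *including the term itself*."""
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        if term_id not in self.graph:
            raise KeyError(f"term {term_id!r} not in ontology (or obsolete)")
        # edges point child -> parent, so graph-descendants are ancestors
        anc = frozenset(nx.descendants(self.graph, term_id)) | {term_id}
        self._ancestor_cache[term_id] = anc
        return anc

    def namespace_of(self, term_id: str) -> str:
        return self.terms[term_id].namespace

    def traversable_terms(self, namespace: str | None = None) -> set[str]:
        if namespace is None:
            return set(self.graph.nodes)
        return {
            t for t in self.graph.nodes if self.terms[t].namespace == namespace
        }

    def roots(self, namespace: str | None = None) -> set[str]:
        nodes = self.traversable_terms(namespace)
        return {t for t in nodes if self.graph.out_degree(t) == 0}

    def validate(self) -> None:
        for ns in {t.namespace for t in self.terms.values() if not t.obsolete}:
            sub = self.graph.subgraph(self.traversable_terms(ns))
            if not nx.is_directed_acyclic_graph(sub):
                cycle = nx.find_cycle(sub)
                raise OntologyValidationError(
                    f"cycle in namespace {ns}: {cycle}"
                )


def parse_obo(obo_text: str, include_part_of: bool = True) -> OntologyDAG:
    """Parse an OBO 1.2 document into an :class:`OntologyDAG`.

    ``is_a`` edges are always kept; ``part_of`` relationship edges are kept
    only when ``include_part_of`` is true. Obsolete terms are flagged and
    excluded from traversal. Edges pointing at unknown or obsolete terms are
    dropped with a logged count.
    """
    stanzas: list[tuple[int, dict]] = []
    current: dict | None = None
    current_line = 0
    in_term = False

    for lineno, raw in enumerate(obo_text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip() if not raw.startswith("!") else ""
        if not line:
            continue
        if line.startswith("["):
            if current is not None and in_term:
                stanzas.append((current_line, current))
            in_term = line == "[Term]"
            current = {} if in_term else None
            current_line = lineno
            continue
        if current is None:
            continue  # header or non-Term stanza content
        if ":" not in line:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {raw!r}")
        tag, value = (s.strip() for s in line.split(":", 1))
        if tag in ("is_a",):
            current.setdefault("is_a", []).append(value.split()[0])
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(f"line {lineno}: malformed relationship {raw!r}")
            current.setdefault("relationship", []).append((parts[0], parts[1]))
        else:
            current.setdefault(tag, value)
    if current is not None and in_term:
        stanzas.append((current_line, current))

    terms: dict[str, Term] = {}
    for lineno, st in stanzas:
        if "id" not in st:
            raise OboParseError(f"line {lineno}: [Term] stanza without id")
        ns_raw = st.get("namespace", "biological_process")
        ns = NAMESPACE_CODES.get(ns_raw, ns_raw)
        terms[st["id"]] = Term(
            id=st["id"],
            name=st.get("name", st["id"]),
            namespace=ns,
            obsolete=st.get("is_obsolete", "false").lower() == "true",
        )

    graph = nx.DiGraph()
    graph.add_nodes_from(t.id for t in terms.values() if not t.obsolete)
    n_dropped_edges = 0
    for _, st in stanzas:
        child = st["id"]
        if terms[child].obsolete:
            continue
        parents = [(p, "is_a") for p in st.get("is_a", [])]
        if include_part_of:
            parents += [
                (p, rel)
                for rel, p in st.get("relationship", [])
                if rel == "part_of"
            ]
        for parent, rel in parents:
            if parent not in terms or terms[parent].obsolete:
                n_dropped_edges += 1
                continue
            graph.add_edge(child, parent, relation=rel)
    if n_dropped_edges:
        logger.warning(
            "dropped %d edges to unknown/obsolete terms", n_dropped_edges
        )

    dag = OntologyDAG(terms=terms, graph=graph)
    dag.validate()
    return dag


@dataclass(frozen=True)
class AnnotationRecord:
    gene: str
    term: str
    evidence: str
    qualifiers: tuple[str, ...] = ()

    @property
    def negated(self) -> bool:
        return "NOT" in self.qualifiers


@dataclass
class AnnotationSet:
    """Gene -> term-set maps, in a direct and an ancestor-propagated view."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]] | None = None
    report: dict[str, int] = field(default_factory=dict)
    _term_index: dict[str, frozenset[str]] | None = field(
        default=None, repr=False
    )

    @property
    def genes(self) -> set[str]:
        return set(self.direct)

    def annotated_genes(self, term: str) -> frozenset[str]:
        """Genes reaching ``term`` on the propagated view."""
        if self.propagated is None:
            raise ValueError("annotation set has not been propagated")
        if self._term_index is None:
            index: dict[str, set[str]] = {}
            for gene, ts in self.propagated.items():
                for t in ts:
                    index.setdefault(t, set()).add(gene)
            self._term_index = {t: frozenset(gs) for t, gs in index.items()}
        return self._term_index.get(term, frozenset())

    @property
    def term_index(self) -> dict[str, frozenset[str]]:
        self.annotated_genes("")  # force build
        assert self._term_index is not None
        return self._term_index


def filter_records(
    records: list[AnnotationRecord],
    dag: OntologyDAG,
    exclude_evidence: frozenset[str] | set[str] = frozenset(),
    namespace: str | None = "BP",
    normalize_case: bool = False,
) -> AnnotationSet:
    """Apply evidence/namespace/qualifier filters and build the direct view.

    ``ND`` is always excluded on top of ``exclude_evidence``. Records whose
    term is obsolete or absent from the DAG are skipped and counted in the
    returned set's ``report``. Gene ids are matched exactly and
    case-sensitively unless ``normalize_case`` upper-cases them.
    """
    excluded = ALWAYS_EXCLUDED_EVIDENCE | set(exclude_evidence)
    direct: dict[str, set[str]] = {}
    report = {
        "n_input": len(records),
        "n_excluded_evidence": 0,
        "n_excluded_not": 0,
        "n_excluded_namespace": 0,
        "n_unknown_term": 0,
        "n_kept": 0,
    }
    for rec in records:
        if rec.negated:
            report["n_excluded_not"] += 1
            continue
        if rec.evidence in excluded:
            report["n_excluded_evidence"] += 1
            continue
        if rec.term not in dag:
            report["n_unknown_term"] += 1
            continue
        if namespace is not None and dag.namespace_of(rec.term) != namespace:
            report["n_excluded_namespace"] += 1
            continue
        gene = rec.gene.upper() if normalize_case else rec.gene
        direct.setdefault(gene, set()).add(rec.term)
        report["n_kept"] += 1
    if report["n_unknown_term"]:
        logger.warning(
            "skipped %d records with unknown/obsolete terms",
            report["n_unknown_term"],
        )
    return AnnotationSet(
        direct={g: frozenset(ts) for g, ts in direct.items()}, report=report
    )


def _parse_gaf_line(fields: list[str]) -> AnnotationRecord:
    # GAF 2.x columns (1-based): 2 gene, 4 qualifier, 5 GO id, 7 evidence,
    # 9 aspect letter
    quals = tuple(q for q in fields[3].split("|") if q)
    return AnnotationRecord(
        gene=fields[1], term=fields[4], evidence=fields[6], qualifiers=quals
    )


def read_annotation_records(gaf_text: str) -> list[AnnotationRecord]:
    """Read GAF 2.x lines, or the simplified 3-column dialect
    ``gene<TAB>term<TAB>evidence`` used for fixtures."""
    records: list[AnnotationRecord] = []
    for lineno, raw in enumerate(gaf_text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("!") or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) >= 9:
            records.append(_parse_gaf_line(fields))
        elif len(fields) == 3:
            records.append(
                AnnotationRecord(
                    gene=fields[0], term=fields[1], evidence=fields[2]
                )
            )
        else:
            raise ValueError(
                f"line {lineno}: expected GAF (>=9 columns) or 3-column "
                f"annotation line, got {len(fields)} columns"
            )
    return records


def parse_annotations(
    gaf_text: str,
    dag: OntologyDAG,
    exclude_evidence: frozenset[str] | set[str] = frozenset(),
    namespace: str | None = "BP",
    normalize_case: bool = False,
) -> AnnotationSet:
    """Parse + filter an annotation document into a direct-view set.

    GAF aspect letters (P/F/C) are ignored in favour of the namespace looked
    up in the DAG, which is authoritative.
    """
    records = read_annotation_records(gaf_text)
    return filter_records(
        records, dag, exclude_evidence, namespace, normalize_case
    )


def propagate(dag: OntologyDAG, anns: AnnotationSet) -> AnnotationSet:
    """True-path propagation: each gene inherits every ancestor of each of
    its directly annotated terms."""
    propagated = {
        gene: frozenset().union(*(dag.ancestors(t) for t in ts))
        if ts
        else frozenset()
        for gene, ts in anns.direct.items()
    }
    return AnnotationSet(
        direct=anns.direct, propagated=propagated, report=dict(anns.report)
    )
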