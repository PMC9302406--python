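"""Gene Ontology handling: OBO parsing, ancestor propagation, information content.

Terms live in three namespaces (molecular_function, biological_process,
cellular_component).  Annotation sets are propagated by closing each
protein's terms under is_a and part_of ancestry within the namespace
(regulates relations are not followed; namespace roots are dropped as
uninformative).  Per-term information content, used by the Smin metric, is
the negative log2 frequency of the term among proteins annotated in its
namespace, computed from the reference annotation corpus itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import pandas as pd

from .errors import DegenerateInputError, InputError

logger = logging.getLogger(__name__)

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")
NAMESPACE_ALIASES = {
    "mf": "molecular_function",
    "bp": "biological_process",
    "cc": "cellular_component",
}

#: Relations followed during propagation (the common evaluation convention).
PROPAGATED_RELATIONS = ("is_a", "part_of")

EXPERIMENTAL_EVIDENCE = {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"}


def resolve_namespace(name: str) -> str:
    ns = NAMESPACE_ALIASES.get(name.lower(), name)
    if ns not in NAMESPACES:
        raise InputError(f"unknown GO namespace {name!r}")
    return ns


class Ontology:
    """Directed acyclic term hierarchy with alt-id resolution.

    Wraps the child->parent multigraph produced by the OBO reader; only
    is_a and part_of edges are traversed.
    """

    def __init__(self, graph: nx.MultiDiGraph, alt_ids: dict[str, str],
                 replaced_by: dict[str, str]):
        self.graph = graph
        self.alt_ids = alt_ids
        self.replaced_by = replaced_by
        self.roots = {
            n for n in graph
            if not any(k in PROPAGATED_RELATIONS for _, _, k in graph.out_edges(n, keys=True))
        }
        self._ancestors = lru_cache(maxsize=None)(self._ancestors_uncached)

    def __contains__(self, term: str) -> bool:
        return term in self.graph or term in self.alt_ids or term in self.replaced_by

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def canonical(self, term: str) -> str | None:
        """Resolve alt_ids and obsolete replacements; None if unresolvable."""
        if term in self.graph:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        if term in self.replaced_by:
            replacement = self.replaced_by[term]
            return self.canonical(replacement) if replacement != term else None
        return None

    def namespace(self, term: str) -> str:
        t = self.canonical(term)
        if t is None:
            raise InputError(f"term {term} not in ontology")
        return self.graph.nodes[t].get("namespace", NAMESPACES[0])

    def name(self, term: str) -> str:
        t = self.canonical(term)
        return self.graph.nodes[t].get("name", t) if t else term

    def _ancestors_uncached(self, term: str) -> frozenset:
        ns = self.namespace(term)
        seen: set[str] = set()
        stack = [self.canonical(term)]
        while stack:
            node = stack.pop()
            for _, parent, key in self.graph.out_edges(node, keys=True):
                if key in PROPAGATED_RELATIONS and parent not in seen:
                    if self.graph.nodes[parent].get("namespace", ns) == ns:
                        seen.add(parent)
                        stack.append(parent)
        return frozenset(seen)

    def ancestors(self, term: str) -> frozenset:
        """All is_a/part_of ancestors in the term's namespace (roots included)."""
        t = self.canonical(term)
        if t is None:
            raise InputError(f"term {term} not in ontology")
        return self._ancestors(t)


def load_ontology(obo_source) -> Ontology:
    """Parse an OBO 1.2/1.4 file (path, URL or handle) into an Ontology.

    Obsolete terms are dropped; their replaced_by targets are kept as a
    redirection map.  A cycle in is_a/part_of relations is a fatal error.
    """
    import obonet

    graph = obonet.read_obo(obo_source, ignore_obsolete=False)
    replaced_by: dict[str, str] = {}
    obsolete = []
    for node, data in graph.nodes(data=True):
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.append(node)
            repl = data.get("replaced_by")
            if repl:
                replaced_by[node] = repl[0] if isinstance(repl, list) else repl
    graph.remove_nodes_from(obsolete)
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    hierarchy = nx.DiGraph(
        (u, v) for u, v, k in graph.edges(keys=True) if k in PROPAGATED_RELATIONS
    )
    if not nx.is_directed_acyclic_graph(hierarchy):
        cycle = nx.find_cycle(hierarchy)
        raise InputError(f"ontology contains a cycle: {' -> '.join(u for u, _ in cycle)}")
    return Ontology(graph, alt_ids, replaced_by)


@dataclass
class AnnotationSet:
    """protein id -> set of GO term ids, with optional per-term evidence codes."""

    annotations: dict[str, set[str]] = field(default_factory=dict)
    evidence: dict[str, dict[str, str]] = field(default_factory=dict)
    propagated: bool = False

    def __len__(self) -> int:
        return len(self.annotations)

    def proteins(self) -> list[str]:
        return sorted(self.annotations)

    def terms_of(self, protein_id: str) -> set[str]:
        return self.annotations.get(protein_id, set())

    def filter_evidence(self, mode: str = "all") -> "AnnotationSet":
        """mode: 'all' (keep everything, the default — including IEA improves
        prediction accuracy), 'experimental', or 'no-iea'."""
        if mode == "all":
            return self
        kept: dict[str, set[str]] = {}
        ev: dict[str, dict[str, str]] = {}
        for pid, terms in self.annotations.items():
            codes = self.evidence.get(pid, {})
            for t in terms:
                code = codes.get(t, "")
                if mode == "experimental" and code not in EXPERIMENTAL_EVIDENCE:
                    continue
                if mode == "no-iea" and code == "IEA":
                    continue
                kept.setdefault(pid, set()).add(t)
                ev.setdefault(pid, {})[t] = code
        return AnnotationSet(kept, ev, self.propagated)


def load_annotations_tsv(path, ontology: Ontology | None = None,
                         evidence_filter: str = "all") -> AnnotationSet:
    """Read a merged annotation table: protein_id, go_id[, evidence[, source]].

    A header line is detected and skipped.  With an ontology, alt_ids are
    canonicalized and unresolvable terms dropped with a warning count.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="!", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: need at least protein_id and go_id columns")
    if str(df.iloc[0, 1]).lower() in ("go_id", "goid", "term"):
        df = df.iloc[1:]
    annotations: dict[str, set[str]] = {}
    evidence: dict[str, dict[str, str]] = {}
    n_dropped = 0
    for row in df.itertuples(index=False):
        pid, term = str(row[0]), str(row[1])
        code = str(row[2]) if len(row) > 2 and pd.notna(row[2]) else ""
        if ontology is not None:
            canon = ontology.canonical(term)
            if canon is None:
                n_dropped += 1
                continue
            term = canon
        annotations.setdefault(pid, set()).add(term)
        evidence.setdefault(pid, {})[term] = code
    if n_dropped:
        logger.warning("%s: dropped %d annotations with unresolvable terms", path, n_dropped)
    return AnnotationSet(annotations, evidence).filter_evidence(evidence_filter)


def load_gaf(path, ontology: Ontology | None = None,
             evidence_filter: str = "all") -> AnnotationSet:
    """Read a GAF 2.x association file (columns 2, 5, 7: object id, GO id,
    evidence)."""
    annotations: dict[str, set[str]] = {}
    evidence: dict[str, dict[str, str]] = {}
    n_dropped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                raise InputError(f"{path}: GAF line with fewer than 7 columns")
            pid, term, code = cols[1], cols[4], cols[6]
            if ontology is not None:
                canon = ontology.canonical(term)
                if canon is None:
                    n_dropped += 1
                    continue
                term = canon
            annotations.setdefault(pid, set()).add(term)
            evidence.setdefault(pid, {})[term] = code
    if n_dropped:
        logger.warning("%s: dropped %d annotations with unresolvable terms", path, n_dropped)
    return AnnotationSet(annotations, evidence).filter_evidence(evidence_filter)


def propagate(direct: AnnotationSet, ont: Ontology) -> AnnotationSet:
    """Close each protein's term set under ancestry; namespace roots excluded.

    Unresolvable terms are skipped with a warning.  Idempotent.
    """
    out: dict[str, set[str]] = {}
    n_skipped = 0
    for pid, terms in direct.annotations.items():
        closed: set[str] = set()
        for t in terms:
            canon = ont.canonical(t)
            if canon is None:
                n_skipped += 1
                continue
            closed.add(canon)
            closed |= ont.ancestors(canon)
        out[pid] = closed - ont.roots
    if n_skipped:
        logger.warning("propagate: skipped %d unresolvable terms", n_skipped)
    return AnnotationSet(out, dict(direct.evidence), propagated=True)


class InformationContent:
    """Per-term ic in bits with an add-one guard for unseen terms."""

    def __init__(self, values: dict[str, float], guard: float):
        self.values = values
        self.guard = guard

    def __getitem__(self, term: str) -> float:
        return self.values.get(term, self.guard)

    def get(self, term: str, default: float | None = None) -> float:
        return self.values.get(term, self.guard if default is None else default)

    def __contains__(self, term: str) -> bool:
        return term in self.values


def information_content(annotations: AnnotationSet, ont: Ontology) -> InformationContent:
    """ic(t) = -log2(freq of t among proteins annotated in t's namespace).

    Requires a propagated annotation set so ancestor counts dominate
    descendant counts (making ic monotone along edges).  Terms absent from
    the corpus fall back to -log2(1/(n+1)) with n the corpus size.
    """
    if len(annotations) == 0:
        raise DegenerateInputError("information content needs a nonempty corpus")
    if not annotations.propagated:
        raise InputError("information_content requires a propagated annotation set")
    term_counts: dict[str, int] = {}
    ns_totals: dict[str, int] = {ns: 0 for ns in NAMESPACES}
    for pid, terms in annotations.annotations.items():
        seen_ns = set()
        for t in terms:
            term_counts[t] = term_counts.get(t, 0) + 1
            seen_ns.add(ont.namespace(t))
        for ns in seen_ns:
            ns_totals[ns] += 1
    values = {}
    for t, c in term_counts.items():
        denom = ns_totals[ont.namespace(t)]
        values[t] = -math.log2(c / denom) if denom else 0.0
    n = len(annotations)
    return InformationContent(values, guard=-math.log2(1.0 / (n + 1)))
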