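"""OBO parsing, ontology graph structure and true-path annotation propagation.

The graph stores directed child-to-parent edges of kind ``is_a`` or
``part_of``. After restriction to a single namespace the graph must be
acyclic with exactly one root, and every term must reach the root. Term
depth is the *longest* path to the root, which guarantees children are
processed strictly before their parents in the elim traversal.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

from .errors import DataValidationError, MalformedOntologyError

__all__ = ["OntologyGraph", "AnnotationMap", "parse_obo", "propagate", "write_obo"]

FOLLOWED_RELATIONS = ("is_a", "part_of")


@dataclass
class OntologyGraph:
    """A single-namespace GO-style DAG (edges point child -> parent)."""

    graph: nx.DiGraph
    namespace: str | None = None

    def __post_init__(self) -> None:
        if len(self.graph) == 0:
            raise MalformedOntologyError("ontology has no terms")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise MalformedOntologyError("ontology graph contains a cycle")
        roots = [t for t in self.graph if self.graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise MalformedOntologyError(
                f"expected exactly one root, found {len(roots)}: {sorted(roots)[:5]}"
            )
        self._root = roots[0]
        for term in self.graph:
            if term != self._root and not nx.has_path(self.graph, term, self._root):
                raise MalformedOntologyError(f"term {term} cannot reach the root")

    @property
    def root(self) -> str:
        return self._root

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by following child->parent edges (term excluded)."""
        return nx.descendants(self.graph, term)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def depths(self) -> dict[str, int]:
        """Longest-path distance from each term up to the root (root = 0)."""
        depth: dict[str, int] = {}
        for term in nx.topological_sort(self.graph.reverse(copy=False)):
            parents = self.parents(term)
            depth[term] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth


def _stanza_lines(stream: IO[str]) -> Iterable[list[str]]:
    current: list[str] | None = None
    for raw in stream:
        line = raw.split("!", 1)[0].strip() if not raw.startswith("!") else ""
        if raw.strip() == "[Term]":
            if current is not None:
                yield current
            current = []
        elif raw.strip().startswith("[") and raw.strip().endswith("]"):
            if current is not None:
                yield current
            current = None  # non-Term stanza (e.g. [Typedef])
        elif current is not None and line:
            current.append(line)
    if current is not None:
        yield current


def parse_obo(source, namespace: str | None = "biological_process") -> OntologyGraph:
    """Parse an OBO 1.2-dialect file into an :class:`OntologyGraph`.

    Reads ``id``, ``name``, ``namespace``, ``is_a``, ``relationship:
    part_of`` and ``is_obsolete``; obsolete terms are dropped. When
    ``namespace`` is given, terms of other namespaces (and edges into
    them) are discarded; pass ``None`` to keep everything.
    """
    import os

    close = False
    if isinstance(source, (str, bytes, os.PathLike)):
        stream = open(source, "r", encoding="utf-8")
        close = True
    else:
        stream = source
    terms: dict[str, dict] = {}
    edges: list[tuple[str, str, str]] = []
    try:
        for stanza in _stanza_lines(stream):
            fields: dict[str, list[str]] = {}
            for line in stanza:
                if ":" not in line:
                    continue
                key, value = line.split(":", 1)
                fields.setdefault(key.strip(), []).append(value.strip())
            if "id" not in fields:
                raise MalformedOntologyError("[Term] stanza without an id")
            term_id = fields["id"][0]
            if fields.get("is_obsolete", ["false"])[0].lower() == "true":
                continue
            terms[term_id] = {
                "name": fields.get("name", [term_id])[0],
                "namespace": fields.get("namespace", [None])[0],
            }
            for target in fields.get("is_a", []):
                edges.append((term_id, target.split()[0], "is_a"))
            for rel in fields.get("relationship", []):
                parts = rel.split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    edges.append((term_id, parts[1], "part_of"))
    finally:
        if close:
            stream.close()
    if namespace is not None:
        terms = {
            t: meta
            for t, meta in terms.items()
            if meta["namespace"] in (None, namespace)
        }
    g = nx.DiGraph()
    for term, meta in terms.items():
        g.add_node(term, **meta)
    for child, parent, kind in edges:
        if child in terms and parent in terms:
            g.add_edge(child, parent, relation=kind)
    return OntologyGraph(graph=g, namespace=namespace)


def write_obo(graph: OntologyGraph, path) -> None:
    """Minimal OBO writer; inverse of :func:`parse_obo` for our dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in graph.terms:
            meta = graph.graph.nodes[term]
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {meta.get('name', term)}\n")
            if meta.get("namespace"):
                fh.write(f"namespace: {meta['namespace']}\n")
            for parent in sorted(graph.parents(term)):
                kind = graph.graph.edges[term, parent].get("relation", "is_a")
                if kind == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {kind} {parent}\n")
            fh.write("\n")


@dataclass
class AnnotationMap:
    """Direct and true-path-propagated gene annotations.

    ``n_universe`` counts the genes carrying at least one propagated
    annotation; by construction the root term is annotated by all of them.
    """

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    genes_by_term: dict[str, set[str]]

    @property
    def n_universe(self) -> int:
        return len(self.propagated)

    @property
    def universe(self) -> set[str]:
        return set(self.propagated)

    def count(self, term: str) -> int:
        return len(self.genes_by_term.get(term, ()))


def propagate(
    graph: OntologyGraph,
    direct: Mapping[str, Iterable[str]],
    on_unknown: str = "error",
) -> AnnotationMap:
    """Close direct annotations under ancestry (is_a and part_of).

    ``on_unknown`` controls annotations to term ids absent from the
    graph: ``"error"`` raises, ``"skip"`` drops them silently (the count
    is available on the returned map as ``dropped_unknown``).
    """
    if on_unknown not in ("error", "skip"):
        raise DataValidationError(f"unknown on_unknown policy {on_unknown!r}")
    anc_cache: dict[str, set[str]] = {}
    direct_clean: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    genes_by_term: dict[str, set[str]] = {}
    dropped = 0
    for gene, terms in direct.items():
        keep: set[str] = set()
        for term in terms:
            if term not in graph.graph:
                if on_unknown == "error":
                    raise DataValidationError(
                        f"gene {gene!r} annotated to unknown term {term!r}"
                    )
                dropped += 1
                continue
            keep.add(term)
        if not keep:
            continue
        closure: set[str] = set()
        for term in keep:
            if term not in anc_cache:
                anc_cache[term] = graph.ancestors(term) | {term}
            closure |= anc_cache[term]
        direct_clean[gene] = keep
        propagated[gene] = closure
        for term in closure:
            genes_by_term.setdefault(term, set()).add(gene)
    amap = AnnotationMap(
        direct=direct_clean, propagated=propagated, genes_by_term=genes_by_term
    )
    amap.dropped_unknown = dropped  # type: ignore[attr-defined]
    return amap
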