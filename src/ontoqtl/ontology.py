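"""Ontology parsing, descendant closures, and anchored pruning.

The refinement cascade works on the Gene Ontology DAG: after per-contrast
enrichment, the enriched term set is pruned to the subgraph *subtended by*
an anchor term (every term from which the anchor is reachable via
child->parent edges — i.e. the anchor's descendants), and candidate genes
are then restricted to those transitively annotated to a more specific
focus term. The default anchors mirror the flowering-time use case
(GO:0003006, developmental process involved in reproduction, then
GO:0010228, vegetative to reproductive phase transition of meristem) but
are ordinary parameters, so the cascade applies to any trait.

Graphs are ``networkx.MultiDiGraph`` objects with edges pointing child ->
parent, as produced by :mod:`obonet`. Only ``is_a`` edges are followed by
default; ``part_of`` can be included with a flag.
"""

from __future__ import annotations

import networkx as nx

DEFAULT_ANCHOR = "GO:0003006"
DEFAULT_FOCUS = "GO:0010228"


def parse_obo(path, include_part_of: bool = False) -> nx.MultiDiGraph:
    """Load an OBO 1.2/1.4 ontology into a child->parent multigraph.

    Obsolete terms are excluded; edge types other than ``is_a`` (and
    ``part_of`` when requested) are dropped. A cyclic graph or an edge to
    an undeclared term is fatal.
    """
    import obonet

    raw = obonet.read_obo(str(path), ignore_obsolete=True)
    keep = {"is_a", "part_of"} if include_part_of else {"is_a"}
    graph = nx.MultiDiGraph()
    for node, data in raw.nodes(data=True):
        graph.add_node(node, **data)
    dangling = set()
    for child, parent, key in raw.edges(keys=True):
        if key not in keep:
            continue
        if "name" not in raw.nodes[parent]:
            dangling.add(parent)
            continue
        graph.add_edge(child, parent, key=key)
    if dangling:
        raise ValueError(
            f"edges reference undeclared term(s): {sorted(dangling)}"
        )
    if not nx.is_directed_acyclic_graph(graph):
        cycle = [u for u, _, _ in nx.find_cycle(graph)]
        raise ValueError(f"ontology contains a cycle: {cycle}")
    return graph


def _require_term(graph: nx.MultiDiGraph, term: str, what: str) -> None:
    if term not in graph:
        raise KeyError(f"{what} term {term!r} not in ontology")


def descendants(graph: nx.MultiDiGraph, anchor: str) -> set[str]:
    """Terms subtended by ``anchor``: every term from which the anchor is
    reachable via child->parent edges, the anchor included."""
    _require_term(graph, anchor, "anchor")
    return nx.ancestors(graph, anchor) | {anchor}


def ancestors(graph: nx.MultiDiGraph, term: str) -> set[str]:
    """Terms reachable upward from ``term`` (term excluded)."""
    _require_term(graph, term, "query")
    return nx.descendants(graph, term)


def prune_enriched(enriched_terms, graph: nx.MultiDiGraph, anchor: str) -> list[str]:
    """Retain enriched terms lying in the anchored subgraph, preserving
    the input order."""
    sub = descendants(graph, anchor)
    return [t for t in enriched_terms if t in sub]


def genes_for_term(annotations, graph: nx.MultiDiGraph, focus: str) -> set[str]:
    """Genes transitively annotated to ``focus``: annotated directly to the
    focus term or to any term it subtends.

    ``annotations`` maps gene id -> set of term ids; direct (unpropagated)
    annotations are sufficient.
    """
    _require_term(graph, focus, "focus")
    sub = descendants(graph, focus)
    return {g for g, terms in annotations.items() if terms & sub}


def read_annotations(path) -> dict[str, set[str]]:
    """Read a two-column (gene, term) TSV into a gene -> terms mapping."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            ann.setdefault(gene, set()).add(term)
    return ann


def write_annotations(annotations, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
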