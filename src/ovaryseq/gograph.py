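"""Enrichment graph construction and export (Cytoscape-ready).

Builds the is_a graph over scored GO terms with node size encoding the
gene count and node color encoding the enrichment score (positive = the
premature pole, negative = mature). Two visibility rules zero a node's
display size without touching its stored score or count: GO level < 2
(level = shortest is_a path from the namespace root, root = 0) and fewer
than 150 carrying genes (both cutoffs strict, both configurable). Branches
whose subtree contains no "significant" node — |score| >= sig_threshold,
default 1.0, i.e. a two-fold frequency ratio — are pruned entirely.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .config import OntologyError


def term_levels(dag: nx.DiGraph) -> dict[str, int]:
    """Shortest is_a distance from each term up to its namespace root.

    Roots (terms with no parent) are level 0. Edges point child -> parent,
    so the level is the shortest directed path length to a root.
    """
    roots = [t for t in dag.nodes if dag.out_degree(t) == 0]
    rev = nx.reverse_view(dag)  # parent -> child
    levels: dict[str, int] = {}
    for root in roots:
        for term, dist in nx.single_source_shortest_path_length(rev, root).items():
            if term not in levels or dist < levels[term]:
                levels[term] = dist
    missing = set(dag.nodes) - levels.keys()
    if missing:
        raise OntologyError(
            f"term(s) cannot reach any namespace root: {sorted(missing)[:3]}"
        )
    return levels


def term_level(dag: nx.DiGraph, term: str) -> int:
    if term not in dag:
        raise OntologyError(f"term {term} not in ontology")
    return term_levels(dag)[term]


def build_enrichment_graph(
    dag: nx.DiGraph,
    results: pd.DataFrame,
    min_level: int = 2,
    min_genes: int = 150,
    sig_threshold: float = 1.0,
) -> nx.DiGraph:
    """Assemble the displayable enrichment graph from per-term scores.

    Nodes start from every scored term (nonzero count in at least one DE
    set); a node's gene count is the number of genes across both sets
    carrying the term (the sets are disjoint, so counts add). Subtrees with
    no significant descendant-or-self are pruned; survivors get
    ``display_size`` proportional to the gene count, zeroed by the level
    and size visibility rules. Edges are the is_a pairs between retained
    terms.
    """
    levels = term_levels(dag)
    info = {
        row.term_id: (int(row.n_pre) + int(row.n_mat), float(row.score))
        for row in results.itertuples()
    }
    sub = dag.subgraph(info.keys())
    significant = {t for t, (_, score) in info.items() if abs(score) >= sig_threshold}
    keep: set[str] = set()
    for t in significant:
        keep.add(t)
        keep |= nx.descendants(sub, t)  # is_a ancestors of a significant term

    graph = nx.DiGraph()
    for term in sorted(keep):
        n_genes, score = info[term]
        level = levels[term]
        visible = level >= min_level and n_genes >= min_genes
        graph.add_node(
            term,
            name=str(dag.nodes[term].get("name", term)),
            namespace=str(dag.nodes[term].get("namespace", "")),
            level=level,
            n_genes=n_genes,
            score=score,
            display_size=float(n_genes) if visible else 0.0,
            visible=visible,
        )
    for child, parent in sub.edges:
        if child in keep and parent in keep:
            graph.add_edge(child, parent)
    return graph


# ------------------------------------------------------------------ export


def export_graph(graph: nx.DiGraph, out_prefix: str | Path) -> dict[str, Path]:
    """Write GraphML plus a Cytoscape SIF/node-attribute pair.

    Returns the written paths. Re-reading either representation reproduces
    the graph (see ``read_graphml`` / ``read_sif``).
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": prefix.with_suffix(".graphml"),
        "sif": prefix.with_suffix(".sif"),
        "nodes": prefix.with_suffix(".nodes.tsv"),
    }
    nx.write_graphml(graph, paths["graphml"], named_key_ids=True)
    with open(paths["sif"], "w") as fh:
        for child, parent in sorted(graph.edges):
            fh.write(f"{child}\tis_a\t{parent}\n")
    cols = ["term_id", "name", "namespace", "level", "n_genes", "score",
            "display_size", "visible"]
    with open(paths["nodes"], "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for term in sorted(graph.nodes):
            d = graph.nodes[term]
            fh.write(
                f"{term}\t{d['name']}\t{d['namespace']}\t{d['level']}\t"
                f"{d['n_genes']}\t{d['score']!r}\t{d['display_size']!r}\t"
                f"{d['visible']}\n"
            )
    return paths


def read_graphml(path: str | Path) -> nx.DiGraph:
    graph = nx.read_graphml(path)
    return nx.DiGraph(graph)


def read_sif(sif_path: str | Path, nodes_path: str | Path) -> nx.DiGraph:
    """Rebuild the enrichment graph from a SIF + node-attribute TSV pair."""
    graph = nx.DiGraph()
    with open(nodes_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            graph.add_node(
                vals["term_id"],
                name=vals["name"],
                namespace=vals["namespace"],
                level=int(vals["level"]),
                n_genes=int(vals["n_genes"]),
                score=float(vals["score"]),
                display_size=float(vals["display_size"]),
                visible=vals["visible"] == "True",
            )
    with open(sif_path) as fh:
        for line in fh:
            if line.strip():
                child, _, parent = line.rstrip("\n").split("\t")
                graph.add_edge(child, parent)
    return graph
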