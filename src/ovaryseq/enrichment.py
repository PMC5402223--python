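"""GO-term enrichment between the premature-up and mature-up gene sets.

The per-term score is

    Enrich(GO) = log2( ((N_pre(GO) + c) / (N_total(pre) + c))
                     / ((N_mat(GO) + c) / (N_total(mat) + c)) )

with pseudo-count c = 0.05 added symmetrically to all four quantities, so
the score is finite for any counts and exactly antisymmetric under swapping
the two gene sets. N_X(GO) is the number of set-X genes carrying the term
after is_a propagation; N_total(X) is the number of set-X genes with at
least one GO mapping. Positive scores mean the term is relatively more
frequent among premature-up genes.

Only is_a edges are honored; other OBO relations (part_of, ...) and
obsolete terms are ignored on load.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .config import InputError, OntologyError

logger = logging.getLogger(__name__)

_NS_SHORT = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}


def load_obo(path: str | Path) -> nx.DiGraph:
    """Read an OBO ontology keeping only is_a edges (child -> parent).

    Node attributes: ``name`` and ``namespace`` (BP/CC/MF). Obsolete terms
    are skipped by the reader.
    """
    multi = obonet.read_obo(str(path))
    dag = nx.DiGraph()
    for term, data in multi.nodes(data=True):
        ns = data.get("namespace", "")
        dag.add_node(
            term,
            name=data.get("name", term),
            namespace=_NS_SHORT.get(ns, ns),
        )
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    return dag


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["gene_id", "go_id"]:
        raise InputError(
            f"annotation table must have columns gene_id, go_id; got {list(df.columns)}"
        )
    annotations: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["go_id"]):
        annotations.setdefault(gene, set()).add(term)
    return annotations


def _check_acyclic(dag: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(dag):
        member = nx.find_cycle(dag)[0][0]
        raise OntologyError(f"ontology contains an is_a cycle through {member}")


def term_closure(dag: nx.DiGraph) -> dict[str, frozenset[str]]:
    """Each term's is_a ancestors-plus-self, memoized over the whole DAG."""
    _check_acyclic(dag)
    closure: dict[str, frozenset[str]] = {}
    for term in nx.topological_sort(nx.reverse_view(dag)):
        anc = {term}
        for parent in dag.successors(term):
            anc |= closure[parent]
        closure[term] = frozenset(anc)
    return closure


def propagate_annotations(
    dag: nx.DiGraph, annotations: dict[str, set[str]]
) -> dict[str, frozenset[str]]:
    """Close each gene's annotation set over is_a ancestors.

    The result is a superset of the direct annotation and a fixed point:
    propagating again changes nothing. Terms absent from the DAG are an
    input error.
    """
    closure = term_closure(dag)
    out: dict[str, frozenset[str]] = {}
    for gene, terms in annotations.items():
        unknown = terms - closure.keys()
        if unknown:
            raise InputError(
                f"gene {gene}: annotation term(s) not in ontology: {sorted(unknown)[:3]}"
            )
        closed: set[str] = set()
        for term in terms:
            closed |= closure[term]
        out[gene] = frozenset(closed)
    return out


def term_counts(
    gene_set: set[str], propagated: dict[str, frozenset[str]]
) -> tuple[dict[str, int], int]:
    """Per-term gene counts within a gene set, and the annotated-gene total.

    Genes without any GO mapping are dropped from the total (and logged).
    """
    counts: dict[str, int] = {}
    total = 0
    dropped = 0
    for gene in gene_set:
        terms = propagated.get(gene)
        if not terms:
            dropped += 1
            continue
        total += 1
        for term in terms:
            counts[term] = counts.get(term, 0) + 1
    if dropped:
        logger.info("term_counts: dropped %d gene(s) without GO annotation", dropped)
    return counts, total


def enrichment_score(
    n_pre: int,
    n_total_pre: int,
    n_mat: int,
    n_total_mat: int,
    pseudo: float = 0.05,
    placement: str = "all",
) -> float:
    """The log2 frequency-ratio enrichment score with pseudo-count.

    ``placement='all'`` (default) adds the pseudo-count to all four
    quantities; ``'counts_only'`` adds it to the two numerator counts only.
    """
    if pseudo <= 0:
        if 0 in (n_pre, n_mat) or 0 in (n_total_pre, n_total_mat):
            raise InputError("pseudo-count must be > 0 when any count is zero")
        pseudo = 0.0
    if min(n_pre, n_total_pre, n_mat, n_total_mat) < 0:
        raise InputError("counts must be non-negative")
    c_tot = pseudo if placement == "all" else 0.0
    freq_pre = (n_pre + pseudo) / (n_total_pre + c_tot)
    freq_mat = (n_mat + pseudo) / (n_total_mat + c_tot)
    return math.log2(freq_pre / freq_mat)


def compute_enrichment(
    dag: nx.DiGraph,
    annotations: dict[str, set[str]],
    premature_up_genes: set[str],
    mature_up_genes: set[str],
    pseudo: float = 0.05,
    placement: str = "all",
    propagate: bool = True,
) -> pd.DataFrame:
    """Score every GO term observed in either DE gene set.

    Columns: term_id, name, namespace, n_pre, n_total_pre, n_mat,
    n_total_mat, score — sorted by namespace, then score descending. Terms
    with zero count in both sets are not reported.
    """
    if not premature_up_genes and not mature_up_genes:
        logger.warning("compute_enrichment: both gene sets are empty")
    if propagate:
        closed = propagate_annotations(dag, annotations)
    else:
        closed = {g: frozenset(t) for g, t in annotations.items()}
    counts_pre, total_pre = term_counts(set(premature_up_genes), closed)
    counts_mat, total_mat = term_counts(set(mature_up_genes), closed)
    rows = []
    for term in sorted(counts_pre.keys() | counts_mat.keys()):
        n_pre = counts_pre.get(term, 0)
        n_mat = counts_mat.get(term, 0)
        data = dag.nodes[term] if term in dag else {}
        rows.append(
            (
                term,
                data.get("name", term),
                data.get("namespace", ""),
                n_pre,
                total_pre,
                n_mat,
                total_mat,
                enrichment_score(n_pre, total_pre, n_mat, total_mat, pseudo, placement),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "name", "namespace",
            "n_pre", "n_total_pre", "n_mat", "n_total_mat", "score",
        ],
    )
    return df.sort_values(
        ["namespace", "score"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)


def read_enrichment(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"term_id": str})


def write_enrichment(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
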