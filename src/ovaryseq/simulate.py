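"""Synthetic-data generation with known ground truth.

Emulates the study design the pipeline targets: two conditions (premature
and mature ovary), each with replicate libraries of negative-binomial gene
counts carrying planted fold changes; a three-namespace GO DAG (BP/CC/MF)
with term-frequency skews planted between the two DE gene sets; and
101-base single-end reads with planted PCR-duplicate clusters plus
near-miss decoys sitting exactly at the similarity boundary.

Counts use the NB2 mean-dispersion model (var = mu + d*mu^2), sampled as a
gamma-Poisson mixture so the d -> 0 limit is exactly Poisson. Fold changes
are planted symmetrically on the FPKM scale (x sqrt(fold) in the up
condition, / sqrt(fold) in the other) so that the expected FPKM ratio
equals ``true_fold`` and per-condition totals stay balanced.

All generators are deterministic given ``config.seed``; each draws from its
own child stream so outputs do not depend on call order.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig
from .dedup import ReadRecord, write_fastq
from .quant import (
    CLASS_MAT_UP,
    CLASS_NEITHER,
    CLASS_PRE_UP,
    GeneModel,
    MATURE,
    PREMATURE,
    models_to_frame,
    write_counts,
    write_models,
)

_NAMESPACES = ("BP", "CC", "MF")
_NS_LONG = {
    "BP": "biological_process",
    "CC": "cellular_component",
    "MF": "molecular_function",
}
_BASES = np.array(list("ACGT"))

# child-stream ids, one per generator, so outputs are call-order independent
_STREAM_MODELS = 0
_STREAM_CLASSES = 1
_STREAM_COUNTS = 2
_STREAM_DAG = 3
_STREAM_READS = 4
_STREAM_QPCR = 5


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _check(config: SimulationConfig) -> None:
    errs = config.validate()
    if errs:
        raise ConfigurationError(errs)


def gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n_genes + 1)]


# ------------------------------------------------------------- gene models


def generate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Gene identifiers with transcript lengths uniform in length_range."""
    _check(config)
    rng = _rng(config, _STREAM_MODELS)
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    return [GeneModel(g, int(L)) for g, L in zip(gene_ids(config.n_genes), lengths)]


# ------------------------------------------------------ counts with truth


def assign_classes(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic per-gene true DE class (shared by counts and GO gens)."""
    _check(config)
    rng = _rng(config, _STREAM_CLASSES)
    n = config.n_genes
    n_pre = round(config.frac_pre_up * n)
    n_mat = round(config.frac_mat_up * n)
    labels = np.array(
        [CLASS_PRE_UP] * n_pre
        + [CLASS_MAT_UP] * n_mat
        + [CLASS_NEITHER] * (n - n_pre - n_mat),
        dtype=object,
    )
    rng.shuffle(labels)
    return pd.DataFrame({"gene_id": gene_ids(n), "true_class": labels})


def generate_counts(
    models: list[GeneModel], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count table plus the per-gene truth table.

    Per-gene expected counts scale with baseline abundance x length, so the
    planted effect lives on the length-normalized (FPKM) scale and survives
    quantification. Pre-up genes have expected premature/mature FPKM ratio
    ``true_fold``; mat-up genes ``1/true_fold``.
    """
    if not models:
        raise ConfigurationError(["models: must be nonempty"])
    _check(config)
    truth = assign_classes(config)
    rng = _rng(config, _STREAM_COUNTS)
    n = len(models)
    lengths = np.array([m.length for m in models], dtype=float)
    abundance = rng.lognormal(0.0, config.abundance_sigma, n) if config.abundance_sigma > 0 else np.ones(n)

    boost = math.sqrt(config.true_fold)
    mult = {PREMATURE: np.ones(n), MATURE: np.ones(n)}
    is_pre = (truth["true_class"] == CLASS_PRE_UP).to_numpy()
    is_mat = (truth["true_class"] == CLASS_MAT_UP).to_numpy()
    mult[PREMATURE][is_pre] *= boost
    mult[MATURE][is_pre] /= boost
    mult[PREMATURE][is_mat] /= boost
    mult[MATURE][is_mat] *= boost

    s_base = float(np.sum(abundance * lengths))
    rows = []
    ids = [m.gene_id for m in models]
    d = config.dispersion
    for condition in (PREMATURE, MATURE):
        mu = config.library_size * abundance * mult[condition] * lengths / s_base
        for rep in range(1, config.n_replicates + 1):
            mu_rep = mu
            if config.between_rep_sigma > 0:
                mu_rep = mu * np.exp(rng.normal(0.0, config.between_rep_sigma, n))
            lam = rng.gamma(1.0 / d, mu_rep * d)
            counts = rng.poisson(lam)
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": ids,
                        "condition": condition,
                        "replicate": rep,
                        "count": counts,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True), truth


# --------------------------------------------------------- GO DAG + skews


def generate_go_dag(
    config: SimulationConfig,
) -> tuple[nx.DiGraph, dict[str, set[str]], list[tuple[str, str]]]:
    """Random three-namespace is_a DAG, gene annotations, and planted truth.

    Returns ``(dag, annotations, truth)`` where ``dag`` is a DiGraph with
    child -> parent is_a edges and node attributes ``name``/``namespace``,
    ``annotations`` maps gene_id to its set of directly annotated terms,
    and ``truth`` lists ``(term_id, "pre"|"mat")`` for each planted term,
    giving the direction its enrichment score should take.
    """
    _check(config)
    rng = _rng(config, _STREAM_DAG)
    dag = nx.DiGraph()
    ids = [f"GO:{i:07d}" for i in range(1, config.n_go_terms + 1)]
    planted = config.planted_terms or []
    planted_ids = {p.term_id for p in planted}
    levels: dict[str, int] = {}
    by_ns: dict[str, list[str]] = {ns: [] for ns in _NAMESPACES}
    for i, term in enumerate(ids):
        if i < 3:
            ns = _NAMESPACES[i]
            dag.add_node(term, name=f"{ns.lower()} root", namespace=ns)
            levels[term] = 0
        else:
            ns = _NAMESPACES[rng.integers(0, 3)]
            # planted terms stay childless so is_a propagation cannot
            # dilute their planted frequency skew
            candidates = [
                t
                for t in by_ns[ns]
                if levels[t] < config.dag_depth and t not in planted_ids
            ]
            n_parents = min(len(candidates), 1 + int(rng.random() < 0.3))
            parents = rng.choice(len(candidates), size=n_parents, replace=False)
            dag.add_node(term, name=f"synthetic term {i + 1} ({ns})", namespace=ns)
            for j in parents:
                dag.add_edge(term, candidates[j])
            levels[term] = min(levels[candidates[j]] for j in parents) + 1
        by_ns[ns].append(term)

    roots = set(ids[:3])
    for p in planted:
        if p.term_id not in dag or p.term_id in roots:
            raise ConfigurationError(
                [f"planted_terms[{p.term_id}]: not a generated non-root term"]
            )

    truth_df = assign_classes(config)
    classes = dict(zip(truth_df["gene_id"], truth_df["true_class"]))
    base_pool = [t for t in ids if t not in roots and t not in planted_ids]

    annotations: dict[str, set[str]] = {}
    p0 = config.annotation_prob
    for gene in gene_ids(config.n_genes):
        if rng.random() >= 0.95:  # a few genes stay unannotated
            continue
        k = 1 + rng.poisson(2)
        k = min(k, len(base_pool))
        terms = {base_pool[j] for j in rng.choice(len(base_pool), size=k, replace=False)}
        for p in planted:
            cls = classes[gene]
            in_target = (p.target == "pre" and cls == CLASS_PRE_UP) or (
                p.target == "mat" and cls == CLASS_MAT_UP
            )
            prob = min(1.0, p.skew * p0) if in_target else p0
            if rng.random() < prob:
                terms.add(p.term_id)
        annotations[gene] = terms
    truth = [(p.term_id, p.target) for p in planted]
    return dag, annotations, truth


def write_obo(dag: nx.DiGraph, path: str | Path) -> None:
    """Emit a minimal OBO file (id/name/namespace/is_a stanza lines only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: synthetic-go\n")
        for term in sorted(dag.nodes):
            data = dag.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            fh.write(f"namespace: {_NS_LONG[data['namespace']]}\n")
            for parent in sorted(dag.successors(term)):
                fh.write(f"is_a: {parent} ! {dag.nodes[parent].get('name', parent)}\n")


def write_annotations(annotations: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgo_id\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


# --------------------------------------------- reads with planted duplicates


def max_duplicate_mismatches(length: int, sim_threshold: float = 0.90) -> int:
    """Largest mismatch count that still gives similarity strictly above the bar."""
    mm = int(length * (1.0 - sim_threshold))
    while mm > 0 and (length - mm) / length <= sim_threshold:
        mm -= 1
    while (length - (mm + 1)) / length > sim_threshold:
        mm += 1
    return mm


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, n_mut: int, start: int) -> str:
    """Mutate exactly n_mut distinct positions at or after ``start``."""
    positions = start + rng.choice(len(seq) - start, size=n_mut, replace=False)
    chars = list(seq)
    for pos in positions:
        old = "ACGT".index(chars[pos])
        chars[pos] = "ACGT"[(old + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


def generate_reads_with_duplicates(
    config: SimulationConfig,
) -> tuple[list[ReadRecord], dict[str, str], set[str]]:
    """Reads plus planted PCR duplicates and boundary decoys.

    Returns ``(reads, dup_truth, decoys)``: ``dup_truth`` maps each planted
    duplicate's id to its original's id (duplicates share the 10-base prefix
    and stay strictly above 90% similarity); ``decoys`` are ids of reads
    sharing an original's prefix but mutated to similarity <= 90%, which the
    strict predicate must keep. Originals precede their copies in output
    order, so the keep-first policy removes exactly the planted duplicates.
    """
    _check(config)
    rng = _rng(config, _STREAM_READS)
    L, prefix = config.read_length, 10
    mm_max = max_duplicate_mismatches(L, 0.90)
    qual = "I" * L
    originals = [
        ReadRecord(f"read_{i:06d}", _random_seq(rng, L), qual)
        for i in range(1, config.n_reads + 1)
    ]
    extras: list[ReadRecord] = []
    dup_truth: dict[str, str] = {}
    decoys: set[str] = set()
    can_decoy = (L - prefix) >= (mm_max + 1)
    for orig in originals:
        if rng.random() < config.dup_rate:
            n_mut = min(int(rng.binomial(L - prefix, config.mutation_rate)), mm_max)
            dup_id = f"{orig.read_id}_dup"
            extras.append(ReadRecord(dup_id, _mutate(rng, orig.sequence, n_mut, prefix), qual))
            dup_truth[dup_id] = orig.read_id
        if can_decoy and rng.random() < config.decoy_rate:
            decoy_id = f"{orig.read_id}_decoy"
            extras.append(
                ReadRecord(decoy_id, _mutate(rng, orig.sequence, mm_max + 1, prefix), qual)
            )
            decoys.add(decoy_id)
    order = rng.permutation(len(extras))
    reads = originals + [extras[i] for i in order]
    return reads, dup_truth, decoys


# --------------------------------------------------------------- qPCR table


def generate_qpcr_table(config: SimulationConfig, n_per_class: int = 4) -> pd.DataFrame:
    """Synthetic Ct pairs consistent with the planted fold changes.

    For a gene with planted premature/mature fold f, the mature Ct exceeds
    the premature Ct by log2(f) cycles (ideal per-cycle doubling), so the
    deltaCt pipeline recovers f. Purely synthetic stand-in for a qPCR run.
    """
    _check(config)
    rng = _rng(config, _STREAM_QPCR)
    truth = assign_classes(config)
    rows = []
    fold_of = {
        CLASS_PRE_UP: config.true_fold,
        CLASS_MAT_UP: 1.0 / config.true_fold,
        CLASS_NEITHER: 1.0,
    }
    for cls, fold in fold_of.items():
        genes = truth.loc[truth["true_class"] == cls, "gene_id"].head(n_per_class)
        for gene in genes:
            ct_pre = float(rng.uniform(18.0, 30.0))
            rows.append((gene, ct_pre, ct_pre + math.log2(fold)))
    return pd.DataFrame(rows, columns=["gene_id", "ct_premature", "ct_mature"])


# -------------------------------------------------------------- file bundle


def simulate_all(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input plus truth tables.

    Returns a dict of paths: reads.fastq, counts.tsv, models.tsv, go.obo,
    annotations.tsv, qpcr_ct.tsv, truth_classes.tsv, truth_duplicates.tsv,
    truth_go.tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for name in (
        "reads.fastq", "counts.tsv", "models.tsv", "go.obo", "annotations.tsv",
        "qpcr_ct.tsv", "truth_classes.tsv", "truth_duplicates.tsv", "truth_go.tsv",
    )}
    models = generate_gene_models(config)
    counts, truth = generate_counts(models, config)
    dag, annotations, go_truth = generate_go_dag(config)
    reads, dup_truth, decoys = generate_reads_with_duplicates(config)
    qpcr = generate_qpcr_table(config)

    write_models(models_to_frame(models), paths["models.tsv"])
    write_counts(counts, paths["counts.tsv"])
    truth.to_csv(paths["truth_classes.tsv"], sep="\t", index=False)
    write_obo(dag, paths["go.obo"])
    write_annotations(annotations, paths["annotations.tsv"])
    write_fastq(reads, paths["reads.fastq"])
    with open(paths["truth_duplicates.tsv"], "w") as fh:
        fh.write("duplicate_id\toriginal_id\n")
        for dup in sorted(dup_truth):
            fh.write(f"{dup}\t{dup_truth[dup]}\n")
        for decoy in sorted(decoys):
            fh.write(f"{decoy}\t-\n")
    with open(paths["truth_go.tsv"], "w") as fh:
        fh.write("term_id\ttarget\n")
        for term, target in go_truth:
            fh.write(f"{term}\t{target}\n")
    qpcr.to_csv(paths["qpcr_ct.tsv"], sep="\t", index=False)
    return paths
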