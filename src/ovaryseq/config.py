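"""Configuration objects, validation, and the package's exception hierarchy.

Defaults are the workflow's canonical constants: a 10-base duplicate
prefix, a strict 90% whole-read similarity threshold, FPKM > 1 for
"expressed", FPKM ratio thresholds 1.5 / 0.67 for differential-expression
classes, a 0.05 pseudo-count in the enrichment score, and the graph
visibility cutoffs (GO level >= 2, >= 150 genes per term).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Optional

import yaml


class OvaryseqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OvaryseqError):
    """Invalid configuration; carries the full list of field errors."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class InputError(OvaryseqError):
    """Malformed or inconsistent input data."""


class ParseError(InputError):
    """Unparseable input file; message names the offending record."""


class EmptyLibraryError(InputError):
    """A replicate with zero total mapped reads cannot be normalized."""


class OntologyError(OvaryseqError):
    """Structurally invalid ontology (cycle, unreachable root, ...)."""


@dataclass
class PlantedTerm:
    """A GO term planted with a frequency skew between the two DE gene sets.

    ``target`` is the gene set ("pre" or "mat") in which the term is
    over-represented by factor ``skew`` relative to the opposite set.
    """

    term_id: str
    target: str  # "pre" | "mat"
    skew: float = 2.0


@dataclass
class SimulationConfig:
    """Ground-truth generator settings for the synthetic study.

    The defaults emulate the study design: two conditions (premature and
    mature ovary) x two replicate libraries of negative-binomial counts,
    ~10% of genes planted up in each condition at a two-fold expression
    ratio, a three-namespace GO DAG with planted term-frequency skews,
    and 101-base single-end reads carrying planted PCR-duplicate clusters.
    """

    n_genes: int = 2000
    length_range: tuple[int, int] = (500, 5000)
    n_replicates: int = 2
    library_size: int = 200_000
    dispersion: float = 0.1  # NB2: var = mu + dispersion * mu^2
    abundance_sigma: float = 1.0  # lognormal spread of baseline abundance
    between_rep_sigma: float = 0.0  # biological replicate variance (log scale)
    frac_pre_up: float = 0.1
    frac_mat_up: float = 0.1
    true_fold: float = 2.0
    n_go_terms: int = 60
    dag_depth: int = 4
    annotation_prob: float = 0.3  # base chance a gene carries a planted term
    planted_terms: Optional[list[PlantedTerm]] = None
    dup_rate: float = 0.2
    decoy_rate: float = 0.1
    n_reads: int = 200
    read_length: int = 101
    mutation_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.planted_terms is None:
            # the last two generated terms; the generator keeps planted
            # terms childless so propagation cannot dilute the planted skew
            self.planted_terms = [
                PlantedTerm(f"GO:{self.n_go_terms - 1:07d}", "pre", 2.0),
                PlantedTerm(f"GO:{self.n_go_terms:07d}", "mat", 2.0),
            ]
        else:
            self.planted_terms = [
                p if isinstance(p, PlantedTerm) else PlantedTerm(*p)
                for p in self.planted_terms
            ]

    def validate(self) -> list[str]:
        errs = []
        if self.n_genes < 1:
            errs.append("n_genes: must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            errs.append("length_range: require 1 <= lower <= upper")
        if self.n_replicates < 1:
            errs.append("n_replicates: must be >= 1")
        if self.library_size < 1:
            errs.append("library_size: must be >= 1")
        if self.dispersion <= 0:
            errs.append("dispersion: must be > 0")
        if not 0.0 <= self.frac_pre_up <= 1.0:
            errs.append("frac_pre_up: must be in [0, 1]")
        if not 0.0 <= self.frac_mat_up <= 1.0:
            errs.append("frac_mat_up: must be in [0, 1]")
        if self.frac_pre_up + self.frac_mat_up > 1.0:
            errs.append("frac_pre_up + frac_mat_up: must be <= 1")
        if self.true_fold <= 1.5:
            errs.append("true_fold: must be > 1.5 (the up-classification cutoff)")
        if self.n_go_terms < 3:
            errs.append("n_go_terms: must be >= 3 (one root per namespace)")
        if self.dag_depth < 1:
            errs.append("dag_depth: must be >= 1")
        if not 0.0 <= self.dup_rate <= 1.0:
            errs.append("dup_rate: must be in [0, 1]")
        if not 0.0 <= self.decoy_rate <= 1.0:
            errs.append("decoy_rate: must be in [0, 1]")
        if self.read_length <= 10:
            errs.append("read_length: must be > 10 (the duplicate prefix length)")
        if not 0.0 <= self.mutation_rate <= 1.0:
            errs.append("mutation_rate: must be in [0, 1]")
        if not 0.0 <= self.annotation_prob <= 1.0:
            errs.append("annotation_prob: must be in [0, 1]")
        for p in self.planted_terms:
            if p.target not in ("pre", "mat"):
                errs.append(f"planted_terms[{p.term_id}].target: must be 'pre' or 'mat'")
            if p.skew <= 0:
                errs.append(f"planted_terms[{p.term_id}].skew: must be > 0")
        return errs


@dataclass
class DedupParams:
    """Constants of the PCR-duplicate predicate (10-base prefix, >90%)."""

    prefix_len: int = 10
    sim_threshold: float = 0.90

    def validate(self) -> list[str]:
        errs = []
        if self.prefix_len < 1:
            errs.append("prefix_len: must be >= 1")
        if not 0.0 < self.sim_threshold < 1.0:
            errs.append("sim_threshold: must be in (0, 1)")
        return errs


@dataclass
class PipelineConfig:
    """Full pipeline settings; defaults equal the workflow's canonical constants."""

    # stage toggles
    run_simulate: bool = True
    run_dedup: bool = True
    run_quant: bool = True
    run_enrichment: bool = True
    run_graph: bool = True
    run_qpcr: bool = True

    # input paths (used when run_simulate is off, or to override)
    fastq_path: Optional[str] = None
    counts_path: Optional[str] = None
    models_path: Optional[str] = None
    obo_path: Optional[str] = None
    annotations_path: Optional[str] = None
    qpcr_path: Optional[str] = None

    # dedup
    dedup: DedupParams = field(default_factory=DedupParams)
    # quantification / classification
    expressed_threshold: float = 1.0
    up_ratio: float = 1.5
    down_ratio: float = 0.67
    replicate_mode: str = "average_fpkm"  # | "pool_counts"
    universe: str = "union"  # | "intersection" | "all"
    # enrichment
    pseudo_count: float = 0.05
    pseudo_placement: str = "all"  # | "counts_only"
    propagate: bool = True
    # graph export
    min_level: int = 2
    min_genes: int = 150
    sig_threshold: float = 1.0
    # qPCR
    efficiency: float = 2.0
    ct_cap: float = 44.0

    out_dir: str = "ovaryseq_out"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> list[str]:
        errs = []
        errs += [f"dedup.{e}" for e in self.dedup.validate()]
        if self.expressed_threshold < 0:
            errs.append("expressed_threshold: must be >= 0")
        if self.up_ratio <= 1.0:
            errs.append("up_ratio: must be > 1")
        if not 0.0 < self.down_ratio < 1.0:
            errs.append("down_ratio: must be in (0, 1)")
        if self.down_ratio >= self.up_ratio:
            errs.append("down_ratio: must be below up_ratio")
        if self.replicate_mode not in ("average_fpkm", "pool_counts"):
            errs.append("replicate_mode: must be 'average_fpkm' or 'pool_counts'")
        if self.universe not in ("union", "intersection", "all"):
            errs.append("universe: must be 'union', 'intersection' or 'all'")
        if self.pseudo_count <= 0:
            errs.append("pseudo_count: must be > 0")
        if self.pseudo_placement not in ("all", "counts_only"):
            errs.append("pseudo_placement: must be 'all' or 'counts_only'")
        if self.min_level < 0:
            errs.append("min_level: must be >= 0")
        if self.min_genes < 0:
            errs.append("min_genes: must be >= 0")
        if self.sig_threshold < 0:
            errs.append("sig_threshold: must be >= 0")
        if self.efficiency <= 1.0:
            errs.append("efficiency: must be > 1 (amplification factor per cycle)")
        if self.ct_cap <= 0:
            errs.append("ct_cap: must be > 0")
        errs += [f"sim.{e}" for e in self.sim.validate()]
        return errs


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Return the config if valid, else raise with the full error list."""
    errs = config.validate()
    if errs:
        raise ConfigurationError(errs)
    return config


_NESTED = {"dedup": DedupParams, "sim": SimulationConfig}


def config_from_dict(data: dict) -> PipelineConfig:
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError([f"{k}: unknown field" for k in sorted(unknown)])
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            sub_known = {f.name for f in fields(_NESTED[key])}
            bad = set(value) - sub_known
            if bad:
                raise ConfigurationError(
                    [f"{key}.{k}: unknown field" for k in sorted(bad)]
                )
            if key == "sim" and "length_range" in value:
                value = dict(value)
                value["length_range"] = tuple(value["length_range"])
            kwargs[key] = _NESTED[key](**value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config file; omitted fields take the canonical defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(["config root: expected a mapping"])
    return config_from_dict(data)


def config_to_dict(config: PipelineConfig) -> dict:
    return asdict(config)
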