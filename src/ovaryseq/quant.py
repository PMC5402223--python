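"""FPKM quantification and ratio-threshold differential-expression classes.

FPKM for gene g in one replicate is ``count_g * 1e9 / (length_g * T)`` with
T the replicate's total mapped-read count (the sum of its per-gene counts).
Per-condition values are the arithmetic mean over replicates (optionally,
counts can be pooled before normalization). A gene is "expressed" in a
condition when its averaged FPKM is strictly greater than 1. Genes expressed
in at least one condition are classified by the premature/mature FPKM ratio:
strictly above 1.5 is premature-up, strictly below 0.67 is mature-up,
anything else (including both boundaries) is neither. The thresholds are
taken literally as printed, so the band is asymmetric: 0.67 is not 1/1.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import EmptyLibraryError, InputError

PREMATURE = "premature"
MATURE = "mature"
CONDITIONS = (PREMATURE, MATURE)

CLASS_PRE_UP = "premature_up"
CLASS_MAT_UP = "mature_up"
CLASS_NEITHER = "neither"


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcript length, the FPKM denominator."""

    gene_id: str
    length: int

    def __post_init__(self):
        if self.length < 1:
            raise InputError(f"gene {self.gene_id}: length must be >= 1")


def models_to_frame(models: Iterable[GeneModel]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(m.gene_id, m.length) for m in models], columns=["gene_id", "length"]
    )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise InputError(f"duplicate gene_id in models: {dup}")
    return df


def read_models(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "length": int})
    if list(df.columns) != ["gene_id", "length"]:
        raise InputError(
            f"gene model table must have columns gene_id, length; got {list(df.columns)}"
        )
    return df


def write_models(models: pd.DataFrame, path: str | Path) -> None:
    models.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "condition": str, "replicate": int, "count": int},
    )
    expected = ["gene_id", "condition", "replicate", "count"]
    if list(df.columns) != expected:
        raise InputError(f"count table must have columns {expected}; got {list(df.columns)}")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def compute_fpkm(
    counts: pd.DataFrame,
    models: pd.DataFrame,
    condition: str,
    replicate: int,
) -> pd.Series:
    """Per-gene FPKM for one replicate of one condition.

    Genes present in the models but absent from the replicate's rows get
    count 0. Counts for gene ids not present in the models are an error.
    """
    sub = counts[(counts["condition"] == condition) & (counts["replicate"] == replicate)]
    if sub.empty:
        raise InputError(f"no counts for condition={condition!r} replicate={replicate}")
    unknown = set(sub["gene_id"]) - set(models["gene_id"])
    if unknown:
        raise InputError(f"count table contains unknown gene_id(s): {sorted(unknown)[:3]}")
    if (sub["count"] < 0).any():
        raise InputError("negative counts are not allowed")
    total = float(sub["count"].sum())
    if total == 0:
        raise EmptyLibraryError(
            f"condition={condition!r} replicate={replicate}: zero total mapped reads"
        )
    per_gene = sub.set_index("gene_id")["count"]
    counts_vec = per_gene.reindex(models["gene_id"], fill_value=0).astype(float)
    lengths = models.set_index("gene_id")["length"].reindex(models["gene_id"])
    fpkm = counts_vec * 1e9 / (lengths * total)
    fpkm.name = f"{condition}_{replicate}"
    return fpkm


def average_replicates(per_replicate: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of per-replicate FPKM columns (genes as the index).

    All replicate columns must cover the same genes with no missing values.
    """
    if per_replicate.isna().any().any():
        missing = per_replicate.index[per_replicate.isna().any(axis=1)][0]
        raise InputError(f"replicate FPKM tables are not congruent: gene {missing} missing")
    return per_replicate.mean(axis=1)


def fpkm_table(
    counts: pd.DataFrame,
    models: pd.DataFrame,
    replicate_mode: str = "average_fpkm",
) -> pd.DataFrame:
    """Replicate-collapsed FPKM per condition (columns) and gene (index).

    ``average_fpkm`` computes FPKM per replicate and averages; the
    ``pool_counts`` alternative sums counts across replicates first and
    normalizes once.
    """
    out = {}
    for condition in sorted(counts["condition"].unique()):
        reps = sorted(counts.loc[counts["condition"] == condition, "replicate"].unique())
        if replicate_mode == "average_fpkm":
            cols = pd.DataFrame(
                {r: compute_fpkm(counts, models, condition, r) for r in reps}
            )
            out[condition] = average_replicates(cols)
        elif replicate_mode == "pool_counts":
            pooled = (
                counts[counts["condition"] == condition]
                .groupby("gene_id", as_index=False)["count"]
                .sum()
            )
            pooled["condition"] = condition
            pooled["replicate"] = 0
            out[condition] = compute_fpkm(
                pooled[["gene_id", "condition", "replicate", "count"]],
                models,
                condition,
                0,
            )
        else:
            raise InputError(f"unknown replicate_mode: {replicate_mode!r}")
    return pd.DataFrame(out)


def filter_expressed(fpkm: pd.DataFrame, threshold: float = 1.0) -> dict[str, set[str]]:
    """Genes with averaged FPKM strictly above the threshold, per condition.

    A gene at exactly FPKM = 1.0 is *not* expressed under the strict rule.
    """
    return {
        condition: set(fpkm.index[fpkm[condition] > threshold])
        for condition in fpkm.columns
    }


def classify_de(
    fpkm_pre: float,
    fpkm_mat: float,
    up_ratio: float = 1.5,
    down_ratio: float = 0.67,
) -> tuple[float, str]:
    """Classify one gene by its premature/mature FPKM ratio.

    Returns ``(ratio, label)``. A zero mature FPKM with positive premature
    FPKM gives an infinite ratio and the premature-up class; both zero is a
    precondition violation (such genes are outside the classification
    universe).
    """
    if fpkm_pre < 0 or fpkm_mat < 0:
        raise InputError("FPKM values must be non-negative")
    if fpkm_pre == 0 and fpkm_mat == 0:
        raise InputError("gene with zero FPKM in both conditions is not classifiable")
    ratio = math.inf if fpkm_mat == 0 else fpkm_pre / fpkm_mat
    if ratio > up_ratio:
        label = CLASS_PRE_UP
    elif ratio < down_ratio:
        label = CLASS_MAT_UP
    else:
        label = CLASS_NEITHER
    return ratio, label


def classification_universe(
    fpkm: pd.DataFrame,
    expressed_threshold: float = 1.0,
    universe: str = "union",
) -> list[str]:
    """The gene set entering ratio classification.

    Default is the union of the two conditions' expressed sets; the
    intersection and the all-genes alternatives are selectable.
    """
    expressed = filter_expressed(fpkm, expressed_threshold)
    pre_set = expressed.get(PREMATURE, set())
    mat_set = expressed.get(MATURE, set())
    if universe == "union":
        genes = pre_set | mat_set
    elif universe == "intersection":
        genes = pre_set & mat_set
    elif universe == "all":
        genes = {g for g in fpkm.index if fpkm.loc[g].sum() > 0}
    else:
        raise InputError(f"unknown universe: {universe!r}")
    return sorted(genes)


def classify_table(
    fpkm: pd.DataFrame,
    expressed_threshold: float = 1.0,
    up_ratio: float = 1.5,
    down_ratio: float = 0.67,
    universe: str = "union",
) -> pd.DataFrame:
    """Per-gene DE classification over the chosen universe.

    Columns: gene_id, fpkm_pre, fpkm_mat, ratio, de_class. The three class
    labels partition the universe.
    """
    for condition in (PREMATURE, MATURE):
        if condition not in fpkm.columns:
            raise InputError(f"FPKM table lacks condition column {condition!r}")
    genes = classification_universe(fpkm, expressed_threshold, universe)
    rows = []
    for g in genes:
        pre, mat = float(fpkm.at[g, PREMATURE]), float(fpkm.at[g, MATURE])
        ratio, label = classify_de(pre, mat, up_ratio, down_ratio)
        rows.append((g, pre, mat, ratio, label))
    return pd.DataFrame(
        rows, columns=["gene_id", "fpkm_pre", "fpkm_mat", "ratio", "de_class"]
    )


def read_fpkm(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_fpkm(fpkm: pd.DataFrame, path: str | Path) -> None:
    fpkm.rename_axis("gene_id").to_csv(path, sep="\t")


def read_classes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def write_classes(classes: pd.DataFrame, path: str | Path) -> None:
    classes.to_csv(path, sep="\t", index=False)
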