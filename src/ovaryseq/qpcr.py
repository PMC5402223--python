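"""Relative qPCR quantification by the deltaCt method.

Ct is the cycle at which the PCR product becomes detectable; deltaCt is
``ct_mature - ct_premature``, so a gene expressed more highly in the
premature ovary (detected earlier there) has positive deltaCt. Assuming
ideal per-cycle doubling, the premature/mature fold change is
``2 ** deltaCt``; the amplification efficiency is exposed as a parameter
but defaults to 2.0, as no calibration is modelled. Reactions whose Ct
reaches the cycle cap (44 by default) never crossed the detection
threshold and are excluded as non-detects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import InputError


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired Ct values for one gene in the two ovary conditions."""

    gene_id: str
    ct_premature: float
    ct_mature: float


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    delta_ct: float
    fold_change: float


def delta_ct(m: QpcrMeasurement, ct_cap: float = 44.0) -> float:
    """deltaCt = ct_mature - ct_premature; positive = higher in premature."""
    for label, ct in (("ct_premature", m.ct_premature), ("ct_mature", m.ct_mature)):
        if not 0.0 < ct < ct_cap:
            raise InputError(
                f"gene {m.gene_id}: {label}={ct} outside (0, {ct_cap}) — non-detect"
            )
    return m.ct_mature - m.ct_premature


def fold_change(delta: float, efficiency: float = 2.0) -> float:
    """Expression fold change implied by a Ct difference.

    ``efficiency ** delta``: strictly positive, strictly increasing, and
    reciprocal under sign flip.
    """
    if efficiency <= 1.0:
        raise InputError("efficiency must be > 1 (amplification per cycle)")
    return efficiency ** delta


def quantify(m: QpcrMeasurement, efficiency: float = 2.0, ct_cap: float = 44.0) -> FoldChangeResult:
    d = delta_ct(m, ct_cap)
    return FoldChangeResult(m.gene_id, d, fold_change(d, efficiency))


def quantify_table(
    table: pd.DataFrame, efficiency: float = 2.0, ct_cap: float = 44.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene deltaCt and fold change; non-detect rows are split out.

    Returns ``(results, excluded)``; ``results`` adds delta_ct and
    fold_change columns, ``excluded`` holds rows with any Ct outside
    (0, ct_cap).
    """
    expected = ["gene_id", "ct_premature", "ct_mature"]
    if list(table.columns) != expected:
        raise InputError(f"qPCR table must have columns {expected}; got {list(table.columns)}")
    ok_rows, bad_rows = [], []
    for row in table.itertuples(index=False):
        m = QpcrMeasurement(str(row.gene_id), float(row.ct_premature), float(row.ct_mature))
        try:
            r = quantify(m, efficiency, ct_cap)
        except InputError:
            bad_rows.append(row)
            continue
        ok_rows.append((m.gene_id, m.ct_premature, m.ct_mature, r.delta_ct, r.fold_change))
    results = pd.DataFrame(
        ok_rows,
        columns=["gene_id", "ct_premature", "ct_mature", "delta_ct", "fold_change"],
    )
    excluded = pd.DataFrame(bad_rows, columns=expected)
    return results, excluded


def read_ct_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
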