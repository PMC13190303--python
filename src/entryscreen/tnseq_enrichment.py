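"""The Tn-Seq enrichment statistic.

Per condition, raw barcode counts are normalized to

    log2((count / column_total) * 1e6 + 1)

(log2-CPM with the +1 inside the logarithm, so zero counts map to exactly
zero). For each phage condition an ordinary least-squares line is fit with
the no-phage condition as the independent variable; each barcode's residual
is its deviation from expectation under no selection. Residuals are
averaged per gene to give log2 enrichment scores — a descriptive ranking,
not a significance test.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from entryscreen.io import MISSING_GENE
from entryscreen.tables import BarcodePool, CountTable


@dataclasses.dataclass
class RegressionFit:
    """OLS fit of phage-condition on control-condition normalized counts."""

    slope: float
    intercept: float
    residuals: np.ndarray


def log2_cpm(count_column: Sequence[int] | np.ndarray, column_total: int | None = None) -> np.ndarray:
    """Normalize one count column to log2(CPM + 1).

    ``column_total`` defaults to the column sum; passing it explicitly lets
    callers normalize a slice against the full-condition total.
    """
    counts = np.asarray(count_column, dtype=np.float64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if column_total is None:
        column_total = counts.sum()
    if column_total <= 0:
        raise ValueError("empty condition: column total must be > 0")
    return np.log2(counts / float(column_total) * 1e6 + 1.0)


def fit_control_regression(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """OLS with intercept of phage (y) on no-phage control (x) values.

    Residual_i = y_i - (slope * x_i + intercept). Requires n >= 3 and a
    non-constant control column.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must share barcode ordering and length")
    if x.size < 3:
        raise ValueError("need at least 3 barcodes for regression")
    if np.var(x) == 0:  # exact-constant or underflowing spread
        raise ValueError("degenerate design: control values are constant")
    fit = stats.linregress(x, y)
    residuals = y - (fit.slope * x + fit.intercept)
    return RegressionFit(slope=float(fit.slope), intercept=float(fit.intercept), residuals=residuals)


def gene_enrichment(
    fit: RegressionFit,
    pool: BarcodePool,
    barcodes: Sequence[str],
) -> pd.DataFrame:
    """Average per-barcode residuals into per-gene enrichment scores.

    Intergenic barcodes (gene_id ``"-"``) are excluded. Output columns:
    gene_id, n_barcodes, score, rank; sorted by score descending with ties
    broken by gene_id ascending.
    """
    if len(barcodes) != fit.residuals.size:
        raise ValueError("one residual per barcode required")
    gene_of = pool.gene_of()
    missing = [bc for bc in barcodes if bc not in gene_of]
    if missing:
        raise ValueError(f"barcodes absent from pool: {missing[:3]}")
    df = pd.DataFrame(
        {
            "gene_id": [gene_of[bc] for bc in barcodes],
            "residual": fit.residuals,
        }
    )
    df = df[df["gene_id"] != MISSING_GENE]
    scores = (
        df.groupby("gene_id")["residual"]
        .agg(n_barcodes="size", score="mean")
        .reset_index()
    )
    scores = scores.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    scores["rank"] = np.arange(1, len(scores) + 1)
    scores["n_barcodes"] = scores["n_barcodes"].astype(int)
    return scores[["gene_id", "n_barcodes", "score", "rank"]]


def run_screen(
    count_table: CountTable,
    pool: BarcodePool,
    control_condition: str,
    phage_conditions: Sequence[str],
    min_total: int = 0,
) -> dict[str, pd.DataFrame]:
    """Run the full enrichment screen: one regression per phage condition.

    ``min_total`` optionally drops barcodes whose summed raw count across
    the control and the given phage condition falls below the threshold
    (off by default: zero-count barcodes sit near the origin and are
    retained).

    Returns ``{phage_condition: gene score table}``.
    """
    x_raw = count_table.column(control_condition)
    results: dict[str, pd.DataFrame] = {}
    for phage in phage_conditions:
        y_raw = count_table.column(phage)
        keep = (x_raw + y_raw) >= min_total
        barcodes = [bc for bc, k in zip(count_table.barcodes, keep) if k]
        x = log2_cpm(x_raw[keep], int(x_raw.sum()))
        y = log2_cpm(y_raw[keep], int(y_raw.sum()))
        fit = fit_control_regression(x, y)
        results[phage] = gene_enrichment(fit, pool, barcodes)
    return results
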