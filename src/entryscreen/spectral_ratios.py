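"""Pull-down enrichment quantification from spectral-count tables.

Spectral counts are a semi-quantitative abundance proxy; enrichment of a
protein in a bait pull-down relative to a control is expressed as a
pseudocounted log2 ratio. Ratios are reported only for proteins abundant
enough to quantify — by default those with at least ``min_count`` spectral
counts in at least one sample. Two pseudocount profiles are conventional:
1 for proximity-labelling (TurboID-style) tables and 0.5 for crosslinking
pull-down tables; both are plain parameters here.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class SpectralCountTable:
    """Protein × sample non-negative integer spectral counts.

    ``proteins`` is an ordered list of ``(protein_id, origin)`` pairs with
    origin one of host/phage/construct (an input annotation, never
    inferred).
    """

    proteins: list[tuple[str, str]]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.proteins), len(self.samples)):
            raise ValueError("count matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("spectral counts must be non-negative")
        ids = [pid for pid, _ in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValueError("protein ids must be unique")

    def sample_column(self, sample: str) -> np.ndarray:
        try:
            j = self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "origin", [o for _, o in self.proteins])
        df.insert(0, "protein_id", [p for p, _ in self.proteins])
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpectralCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "origin": str})
        if "protein_id" not in df.columns:
            raise ValueError(f"{path}: missing required column 'protein_id'")
        if "origin" not in df.columns:
            df.insert(1, "origin", "host")
        samples = [c for c in df.columns if c not in ("protein_id", "origin")]
        return cls(
            proteins=list(zip(df["protein_id"], df["origin"])),
            samples=samples,
            counts=df[samples].to_numpy(),
        )


@dataclasses.dataclass(frozen=True)
class RatioConfig:
    """Pseudocount and abundance-filter settings for ratio reporting."""

    pseudocount: float = 1.0
    min_count: int = 50

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")


TURBOID_PROFILE = RatioConfig(pseudocount=1.0, min_count=50)
CROSSLINK_PROFILE = RatioConfig(pseudocount=0.5, min_count=50)


def filter_min_counts(table: SpectralCountTable, min_count: int) -> SpectralCountTable:
    """Retain proteins with >= ``min_count`` spectral counts in at least one
    sample; row order preserved. Idempotent, never alters retained counts."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if len(table.proteins) == 0:
        return SpectralCountTable(list(table.proteins), list(table.samples), table.counts.copy())
    keep = table.counts.max(axis=1) >= min_count
    return SpectralCountTable(
        proteins=[p for p, k in zip(table.proteins, keep) if k],
        samples=list(table.samples),
        counts=table.counts[keep],
    )


def log2_ratio(count_a: float, count_b: float, pseudocount: float) -> float:
    """log2((count_a + pseudocount) / (count_b + pseudocount)).

    The pseudocount keeps the ratio finite at zero counts; equal counts
    give exactly 0.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return math.log2((count_a + pseudocount) / (count_b + pseudocount))


def enrichment_table(
    table: SpectralCountTable,
    numerator_sample: str,
    denominator_sample: str,
    config: RatioConfig = TURBOID_PROFILE,
) -> pd.DataFrame:
    """Filtered, sorted per-protein log2 enrichment ratios.

    Applies the min-count filter, then computes the pseudocounted log2
    ratio of numerator over denominator per retained protein. Sorted by
    ratio descending, ties by protein_id ascending. Swapping numerator and
    denominator negates every ratio exactly.
    """
    filtered = filter_min_counts(table, config.min_count)
    num = filtered.sample_column(numerator_sample).astype(np.float64)
    den = filtered.sample_column(denominator_sample).astype(np.float64)
    ratios = np.log2(num + config.pseudocount) - np.log2(den + config.pseudocount)
    df = filtered.to_frame()
    df["log2_ratio"] = ratios
    df = df.sort_values(
        ["log2_ratio", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
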