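"""Core tabular containers: the barcode pool mapping and the count table."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from entryscreen.io import MISSING_GENE, read_tsv_table


@dataclasses.dataclass
class BarcodePool:
    """Barcode → insertion position → gene assignment for a transposon library.

    ``table`` has columns ``barcode``, ``position`` (0-based genome
    coordinate), ``gene_id`` (``"-"`` for intergenic insertions) and
    ``abundance`` (pre-selection clone abundance, arbitrary units).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"barcode", "position", "gene_id", "abundance"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"BarcodePool table missing columns {sorted(missing)}")
        if self.table["barcode"].duplicated().any():
            dup = self.table.loc[self.table["barcode"].duplicated(), "barcode"].iloc[0]
            raise ValueError(f"duplicate barcode {dup!r} in pool")

    @property
    def barcodes(self) -> list[str]:
        return self.table["barcode"].tolist()

    def gene_of(self) -> dict[str, str]:
        return dict(zip(self.table["barcode"], self.table["gene_id"]))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodePool":
        df = read_tsv_table(
            path,
            {"barcode": str, "position": int, "gene_id": str, "abundance": float},
        )
        return cls(df)


@dataclasses.dataclass
class CountTable:
    """Barcode × condition integer read counts.

    Column totals are the per-condition denominators of log2-CPM
    normalization and always equal exact column sums.
    """

    barcodes: list[str]
    conditions: list[str]
    counts: np.ndarray  # shape (n_barcodes, n_conditions), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.barcodes), len(self.conditions)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.conditions)} conditions"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts in CountTable")

    @property
    def totals(self) -> dict[str, int]:
        sums = self.counts.sum(axis=0)
        return {c: int(s) for c, s in zip(self.conditions, sums)}

    def column(self, condition: str) -> np.ndarray:
        try:
            j = self.conditions.index(condition)
        except ValueError:
            raise KeyError(f"unknown condition {condition!r}") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.conditions)
        df.insert(0, "barcode", self.barcodes)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
        if "barcode" not in df.columns:
            raise ValueError(f"{path}: missing required column 'barcode'")
        conditions = [c for c in df.columns if c != "barcode"]
        counts = df[conditions].to_numpy()
        if not np.issubdtype(counts.dtype, np.integer):
            bad = np.argwhere(df[conditions].isna().to_numpy())
            line = bad[0][0] + 2 if len(bad) else "?"
            raise ValueError(f"{path} line {line}: non-integer count cell")
        return cls(df["barcode"].tolist(), conditions, counts)


MISSING = MISSING_GENE
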