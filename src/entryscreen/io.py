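"""Format readers/writers and run-configuration echo.

The single tabular dialect is TSV: tab-delimited, one header row, UTF-8,
"." decimal separator. Sequence I/O goes through Biopython so wrapped and
unwrapped FASTA both parse.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import logging
from pathlib import Path
from typing import Any, Callable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("entryscreen")

MISSING_GENE = "-"


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Residues are uppercased; duplicate ids are a hard error.
    """
    records: dict[str, str] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    recs = [SeqRecord(Seq(s.upper()), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as handle:
        SeqIO.write(recs, handle, "fasta")


def read_tsv_table(
    path: str | Path,
    schema: Mapping[str, Callable[[str], Any]],
) -> pd.DataFrame:
    """Read a TSV with a typed schema, reporting line numbers on errors.

    ``schema`` maps required column names to converters. The cell value
    ``"-"`` in a ``gene_id`` column is kept verbatim (missing-gene marker);
    conversion failures raise with the 1-based file line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in schema:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col, conv in schema.items():
        if conv is str:
            continue
        converted = []
        for i, cell in enumerate(df[col]):
            try:
                converted.append(conv(cell))
            except (ValueError, TypeError) as exc:
                # +2: header line plus 1-based numbering
                raise ValueError(f"{path} line {i + 2}: cannot parse {col}={cell!r}") from exc
        df[col] = converted
    return df


def _nonneg_int(cell: str) -> int:
    value = int(cell)
    if value < 0:
        raise ValueError(f"negative count {value}")
    return value


@dataclasses.dataclass
class RunConfig:
    """Fully resolved parameters of one pipeline stage.

    Every run writes this echo alongside its outputs; re-running a
    deterministic stage from the echo reproduces its outputs byte-identically.
    """

    command: str
    seed: int | None = None
    paths: dict[str, str] = dataclasses.field(default_factory=dict)
    parameters: dict[str, Any] = dataclasses.field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def log_stage(stage: str, **info: Any) -> None:
    """Log input sizes, attrition and parameter echo at a stage boundary."""
    detail = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("%s: %s", stage, detail)
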