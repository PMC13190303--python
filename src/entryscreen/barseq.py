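"""Barcode extraction and counting for BarSeq amplicon reads.

Reads carry a transposon barcode between two fixed primer-derived flanks.
Extraction anchors on the pre-flank (allowing a small substitution budget),
takes the next ``barcode_length`` bases, and verifies the start of the
post-flank. Counting is closed-pool: only barcodes of the characterized
library are counted; everything else is discarded and reported.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from entryscreen.io import _open_text
from entryscreen.synthetic_data import ReadStructure
from entryscreen.tables import BarcodePool, CountTable

POST_ANCHOR_LENGTH = 8


@dataclasses.dataclass(frozen=True)
class BarcodeHit:
    """A barcode located in one read.

    ``flank_mismatches`` is the total substitution count across the
    pre-flank and the verified post-flank anchor; it never exceeds the
    configured ``max_flank_mismatch``.
    """

    read_id: str
    barcode: str
    flank_mismatches: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_barcode(
    read_sequence: str,
    read_structure: ReadStructure,
    max_flank_mismatch: int = 0,
    read_id: str = "",
) -> BarcodeHit | None:
    """Locate the barcode in one read, or return ``None``.

    The pre-flank may sit at any offset; among placements whose combined
    pre-flank + post-anchor mismatches fit the budget, the one with the
    fewest mismatches wins, ties going to the smallest offset. The
    post-flank anchor is its first ``min(len(post_flank), 8)`` bases.
    """
    pre = read_structure.pre_flank
    bl = read_structure.barcode_length
    anchor = read_structure.post_flank[: min(len(read_structure.post_flank), POST_ANCHOR_LENGTH)]
    seq = read_sequence.upper()
    min_len = len(pre) + bl + len(anchor)
    best: tuple[int, int] | None = None  # (mismatches, offset)
    for offset in range(len(seq) - min_len + 1):
        mm = _hamming(seq[offset : offset + len(pre)], pre)
        if mm > max_flank_mismatch:
            continue
        post_start = offset + len(pre) + bl
        mm += _hamming(seq[post_start : post_start + len(anchor)], anchor)
        if mm > max_flank_mismatch:
            continue
        if best is None or mm < best[0]:
            best = (mm, offset)
            if mm == 0:
                break
    if best is None:
        return None
    mm, offset = best
    barcode = seq[offset + len(pre) : offset + len(pre) + bl]
    return BarcodeHit(read_id=read_id, barcode=barcode, flank_mismatches=mm)


def _iter_fastq(path: str | Path) -> Iterable[tuple[str, str]]:
    try:
        handle = _open_text(path)
    except OSError as exc:
        raise OSError(f"cannot read FASTQ file {path}: {exc}") from exc
    with handle:
        while True:
            header = handle.readline()
            if not header:
                return
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record in {path}")
            yield header[1:].strip().split()[0], seq.strip()


def _distance1_index(barcodes: Sequence[str]) -> dict[str, str | None]:
    """Map every Hamming-distance-1 variant to its unique known barcode.

    Variants reachable from more than one known barcode map to ``None``
    (ambiguous). Exact barcodes are excluded — exact matching takes
    priority during counting.
    """
    index: dict[str, str | None] = {}
    known = set(barcodes)
    for bc in barcodes:
        for i in range(len(bc)):
            for base in "ACGT":
                if base == bc[i]:
                    continue
                variant = bc[:i] + base + bc[i + 1 :]
                if variant in known:
                    continue
                if variant in index and index[variant] != bc:
                    index[variant] = None
                else:
                    index[variant] = bc
    return index


def count_barcodes(
    fastq_paths: Mapping[str, str | Path | Sequence[str | Path]],
    known_pool: BarcodePool,
    read_structure: ReadStructure,
    policy: str = "exact",
    max_flank_mismatch: int = 0,
) -> tuple[CountTable, dict]:
    """Count known-pool barcodes per condition from FASTQ files.

    ``fastq_paths`` maps condition name to one path or a list of paths.
    Policy ``"exact"`` counts exact barcode matches only; ``"correct1"``
    additionally assigns an observed barcode to a known barcode iff exactly
    one known barcode lies within Hamming distance 1 (ambiguous and
    unmatched barcodes are discarded). The report tallies, per condition,
    total / extracted / assigned / discarded / unextracted reads; always
    assigned + discarded + unextracted == total.
    """
    if policy not in {"exact", "correct1"}:
        raise ValueError(f"unknown policy {policy!r}")
    barcodes = known_pool.barcodes
    bc_index = {bc: i for i, bc in enumerate(barcodes)}
    near = _distance1_index(barcodes) if policy == "correct1" else {}

    conditions = list(fastq_paths)
    counts = np.zeros((len(barcodes), len(conditions)), dtype=np.int64)
    report: dict = {"policy": policy, "conditions": {}}
    for j, cond in enumerate(conditions):
        paths = fastq_paths[cond]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        total = extracted = assigned = discarded = 0
        for path in paths:
            for read_id, seq in _iter_fastq(path):
                total += 1
                hit = extract_barcode(seq, read_structure, max_flank_mismatch, read_id)
                if hit is None:
                    continue
                extracted += 1
                i = bc_index.get(hit.barcode)
                if i is None and policy == "correct1":
                    target = near.get(hit.barcode)
                    i = bc_index[target] if target is not None else None
                if i is None:
                    discarded += 1
                else:
                    counts[i, j] += 1
                    assigned += 1
        report["conditions"][cond] = {
            "total_reads": total,
            "extracted": extracted,
            "assigned": assigned,
            "discarded": discarded,
            "unextracted": total - extracted,
        }
    return CountTable(list(barcodes), conditions, counts), report
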