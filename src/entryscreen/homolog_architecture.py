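"""Homolog-family architecture analytics.

Covers family-level sequence analysis around a reference protein: greedy
dereplication of near-identical homologs, pairwise identity/coverage from a
fixed-scoring global alignment, per-position identity profiles in reference
coordinates with a rolling mean, homolog region lengths from an alignment,
transmembrane-segment summaries, a hydropathy sliding-window TM predictor,
greedy most-common-domain-hit coverage, and identity-based clade grouping.

All protein coordinates are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GAP = "-"


# ---------------------------------------------------------------------------
# Pairwise identity


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Global-alignment identity and coverage between two protein sequences.

    Scoring is fixed: match +1, mismatch 0, linear gap penalty -1 per gap
    column. Among all optimal-score alignments the one with the most
    identical columns defines the reported values (this choice is unique:
    given the optimal score and the match count, the gap count and aligned
    column count are determined). Returns

    * identity — identical columns / total alignment columns (double-gap
      columns cannot occur);
    * coverage — columns where both sequences have a residue, divided by
      the shorter sequence's length.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    la, lb = len(seq_a), len(seq_b)
    # Lexicographic (score, matches) maximization folded into one integer:
    # combined = score * K + matches with K > max possible matches.
    K = la + lb + 1
    b_arr = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    idx = np.arange(lb + 1, dtype=np.int64)
    prev = -K * idx  # row 0: leading gaps in a
    for i in range(1, la + 1):
        reward = np.where(b_arr == ord(seq_a[i - 1]), K + 1, 0)
        cand = np.maximum(prev[:-1] + reward, prev[1:] - K)
        vals = np.empty(lb + 1, dtype=np.int64)
        vals[0] = -K * i
        vals[1:] = cand
        # resolve the within-row left-gap recursion via a running max
        prev = np.maximum.accumulate(vals + K * idx) - K * idx
    combined = int(prev[-1])
    matches = combined % K
    score = (combined - matches) // K
    gaps = matches - score
    pairs = (la + lb - gaps) // 2
    columns = pairs + gaps
    return matches / columns, pairs / min(la, lb)


def identity_matrix(
    sequences: Mapping[str, str],
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """All-vs-all identity matrix (symmetric, unit diagonal).

    ``region=(start, end)`` restricts the comparison to those 1-based
    inclusive residue positions of each sequence, for regional identity
    comparisons; sequences shorter than ``start`` contribute empty slices
    and raise.
    """
    ids = list(sequences)
    seqs = {}
    for name, seq in sequences.items():
        if region is not None:
            start, end = region
            seq = seq[start - 1 : end]
            if not seq:
                raise ValueError(f"sequence {name!r} has no residues in region {region}")
        seqs[name] = seq
    n = len(ids)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, _ = pairwise_identity(seqs[ids[i]], seqs[ids[j]])
            values[i, j] = values[j, i] = ident
    return pd.DataFrame(values, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Dereplication


def dereplicate(
    sequences: Mapping[str, str],
    id_threshold: float = 0.95,
    cov_threshold: float = 0.90,
) -> tuple[list[str], dict[str, str]]:
    """Greedy dereplication of near-identical sequences.

    Sequences are scanned longest first (ties by id ascending); each joins
    the first existing representative it matches at identity >=
    ``id_threshold`` and coverage >= ``cov_threshold``, else becomes a new
    representative. Defaults collapse homologs at 95% identity / 90%
    coverage. Returns ``(representative ids, member -> representative)``.
    """
    for name, thr in (("id_threshold", id_threshold), ("cov_threshold", cov_threshold)):
        if not 0.0 < thr <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1]")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    representatives: list[str] = []
    membership: dict[str, str] = {}
    for name in order:
        assigned = None
        for rep in representatives:
            ident, cov = pairwise_identity(sequences[name], sequences[rep])
            if ident >= id_threshold and cov >= cov_threshold:
                assigned = rep
                break
        if assigned is None:
            representatives.append(name)
            assigned = name
        membership[name] = assigned
    return representatives, membership


# ---------------------------------------------------------------------------
# Aligned family


@dataclasses.dataclass
class AlignedFamily:
    """An MSA numbered relative to the reference sequence's residues.

    ``rows`` maps sequence id to its gapped row; all rows share one length
    and the reference row must be among them. ``column_to_refpos`` maps
    alignment column (0-based) to 1-based reference residue position, for
    the reference's non-gap columns only.
    """

    reference_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if self.reference_id not in self.rows:
            raise ValueError(f"reference {self.reference_id!r} missing from rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        ref_row = self.rows[self.reference_id]
        self.refpos_to_column: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(ref_row):
            if ch != GAP:
                pos += 1
                self.refpos_to_column[pos] = col
        if pos == 0:
            raise ValueError("reference row contains no residues")
        self.reference_length = pos

    @property
    def column_to_refpos(self) -> dict[int, int]:
        return {col: pos for pos, col in self.refpos_to_column.items()}

    @classmethod
    def from_fasta_rows(cls, rows: Mapping[str, str], reference_id: str) -> "AlignedFamily":
        return cls(reference_id=reference_id, rows={k: v.upper() for k, v in rows.items()})


def column_identity_profile(family: AlignedFamily, window: int = 5) -> np.ndarray:
    """Per-reference-position identity profile with a centred rolling mean.

    Raw identity at reference position p is the fraction of non-reference
    rows whose residue at that alignment column equals the reference
    residue; a gap counts as a mismatch. The rolling mean (default window
    5) is truncated — not padded — at the ends, so the profile length
    equals the reference length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    ref_row = family.rows[family.reference_id]
    others = [row for name, row in family.rows.items() if name != family.reference_id]
    if not others:
        raise ValueError("family must contain at least one non-reference row")
    raw = np.empty(family.reference_length)
    for pos in range(1, family.reference_length + 1):
        col = family.refpos_to_column[pos]
        ref_ch = ref_row[col]
        raw[pos - 1] = sum(row[col] == ref_ch for row in others) / len(others)
    smoothed = (
        pd.Series(raw).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return smoothed


def region_lengths(
    family: AlignedFamily,
    region_boundaries: Sequence[tuple[str, int, int]],
) -> pd.DataFrame:
    """Per-homolog region lengths in an alignment.

    A region is a 1-based inclusive span of reference positions; a
    homolog's length for it is its number of non-gap characters in the
    alignment columns spanning those positions. Insertion columns that fall
    after a region's last reference position (before the next region
    starts) are attributed to that region, and columns before reference
    position 1 to the first listed region, so lengths over a full tiling
    partition each homolog's aligned residues.
    """
    n_cols = len(next(iter(family.rows.values())))
    for name, start, end in region_boundaries:
        if not 1 <= start <= end <= family.reference_length:
            raise ValueError(f"region {name!r} outside [1, {family.reference_length}]")
    regions = sorted(region_boundaries, key=lambda r: r[1])
    records = []
    for k, (name, start, end) in enumerate(regions):
        col_start = 0 if k == 0 else family.refpos_to_column[start]
        if k + 1 < len(regions):
            col_end = family.refpos_to_column[regions[k + 1][1]]  # exclusive
        elif end == family.reference_length:
            col_end = n_cols
        else:
            col_end = family.refpos_to_column[end] + 1
        for hid, row in family.rows.items():
            if hid == family.reference_id:
                continue
            length = sum(ch != GAP for ch in row[col_start:col_end])
            records.append({"homolog_id": hid, "region": name, "length": length})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Transmembrane segments


@dataclasses.dataclass
class TMAnnotation:
    """Predicted or annotated transmembrane segments of one homolog.

    Segments are 1-based inclusive ``(start, end)`` pairs, sorted and
    non-overlapping.
    """

    homolog_id: str
    segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.segments = sorted(tuple(s) for s in self.segments)
        prev_end = 0
        for start, end in self.segments:
            if start < 1 or end < start:
                raise ValueError(f"{self.homolog_id}: bad segment ({start}, {end})")
            if start <= prev_end:
                raise ValueError(f"{self.homolog_id}: overlapping segments")
            prev_end = end


def summarize_tm(
    annotations: Sequence[TMAnnotation],
    family_size: int,
) -> dict:
    """Summarize TM-segment architecture over a homolog family.

    Homologs without an annotation row count as zero segments. Returns
    percentages over the {0, 1, 2+} segment-count categories plus start
    positions and lengths of first and second segments (with per-class n).
    """
    seen: set[str] = set()
    for ann in annotations:
        if ann.homolog_id in seen:
            raise ValueError(f"duplicate annotation for {ann.homolog_id!r}")
        seen.add(ann.homolog_id)
    if family_size < len(seen):
        raise ValueError("family_size smaller than number of annotated homologs")
    n_segments = [len(a.segments) for a in annotations]
    n_zero = family_size - sum(1 for n in n_segments if n >= 1)
    n_one = sum(1 for n in n_segments if n == 1)
    n_two_plus = sum(1 for n in n_segments if n >= 2)
    first = [a.segments[0] for a in annotations if len(a.segments) >= 1]
    second = [a.segments[1] for a in annotations if len(a.segments) >= 2]
    return {
        "family_size": family_size,
        "percent": {
            "0": 100.0 * n_zero / family_size,
            "1": 100.0 * n_one / family_size,
            "2+": 100.0 * n_two_plus / family_size,
        },
        "first_tm": {
            "n": len(first),
            "starts": [s for s, _ in first],
            "lengths": [e - s + 1 for s, e in first],
        },
        "second_tm": {
            "n": len(second),
            "starts": [s for s, _ in second],
            "lengths": [e - s + 1 for s, e in second],
        },
    }


# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def hydropathy_tm_predict(
    sequence: str,
    homolog_id: str = "",
    window: int = 19,
    threshold: float = 1.6,
) -> TMAnnotation:
    """Sliding-window hydropathy transmembrane-segment prediction.

    Mean Kyte-Doolittle hydropathy is computed over every window of the
    given length; maximal runs of windows above the threshold are merged,
    and each run's full span (first window start to last window end,
    1-based inclusive) is reported as one segment. Sequences shorter than
    the window yield an empty annotation.
    """
    seq = sequence.upper()
    if len(seq) < window:
        return TMAnnotation(homolog_id=homolog_id, segments=[])
    values = np.array([KYTE_DOOLITTLE.get(ch, 0.0) for ch in seq])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    above = means > threshold
    segments: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append((start + 1, i - 1 + window))
            start = None
    if start is not None:
        segments.append((start + 1, len(above) - 1 + window))
    return TMAnnotation(homolog_id=homolog_id, segments=segments)


# ---------------------------------------------------------------------------
# Domain-hit coverage


def greedy_hit_cover(
    hits: pd.DataFrame,
    p_cutoff: float = 1e-5,
) -> list[tuple[str, int]]:
    """Greedy most-common-hit coverage of a homolog set.

    ``hits`` has columns homolog_id, hit_name, p_value. Rows with
    p_value >= ``p_cutoff`` are discarded (default cutoff 1e-5). Then,
    iteratively: pick the hit present in the most remaining homologs (ties
    to the lexicographically smallest hit name), record it with its
    coverage count, and remove every homolog containing it; stop when no
    homologs with significant hits remain. Each homolog is counted at most
    once, so the counts sum to the number of homologs with at least one
    significant hit.
    """
    if not 0.0 < p_cutoff <= 1.0:
        raise ValueError("p_cutoff must lie in (0, 1]")
    required = {"homolog_id", "hit_name", "p_value"}
    if not required <= set(hits.columns):
        raise ValueError(f"hit table must have columns {sorted(required)}")
    pvals = hits["p_value"].to_numpy(dtype=float)
    if len(pvals) and ((pvals <= 0) | (pvals > 1)).any():
        raise ValueError("p_value must lie in (0, 1]")
    sig = hits[pvals < p_cutoff]
    hit_sets: dict[str, set[str]] = {}
    for hid, hname in zip(sig["homolog_id"], sig["hit_name"]):
        hit_sets.setdefault(hid, set()).add(hname)
    result: list[tuple[str, int]] = []
    remaining = dict(hit_sets)
    while remaining:
        freq: dict[str, int] = {}
        for names in remaining.values():
            for h in names:
                freq[h] = freq.get(h, 0) + 1
        best = min(freq, key=lambda h: (-freq[h], h))
        result.append((best, freq[best]))
        remaining = {hid: s for hid, s in remaining.items() if best not in s}
    return result


# ---------------------------------------------------------------------------
# Clade grouping


def clade_grouping(
    matrix: pd.DataFrame,
    within_threshold: float = 0.90,
    between_threshold: float = 0.20,
) -> tuple[dict[str, int], dict]:
    """Group sequences into clades by single-linkage identity components.

    Clades are connected components of the graph with edges at identity
    strictly above ``within_threshold`` (default 0.90). A well-separated
    clade shares less than ``between_threshold`` (default 0.20) identity
    with everything outside it; cross-clade pairs at or above that level
    are reported and both involved clades flagged non-conforming — they
    are never merged.
    """
    if not 0.0 <= between_threshold < within_threshold <= 1.0:
        raise ValueError("require 0 <= between < within <= 1")
    values = matrix.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.array_equal(values, values.T):
        raise ValueError("identity matrix must be square and symmetric")
    ids = list(matrix.index)
    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if values[i, j] > within_threshold:
                parent[find(i)] = find(j)

    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for i, name in enumerate(ids):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        labels[name] = roots[r]

    violations: list[tuple[str, str, float]] = []
    non_conforming: set[int] = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if labels[ids[i]] != labels[ids[j]] and values[i, j] >= between_threshold:
                violations.append((ids[i], ids[j], float(values[i, j])))
                non_conforming.add(labels[ids[i]])
                non_conforming.add(labels[ids[j]])
    report = {
        "n_clades": len(roots),
        "non_conforming": sorted(non_conforming),
        "violations": violations,
    }
    return labels, report
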