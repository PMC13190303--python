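"""Synthetic inputs with ground truth for every pipeline stage.

The generators emulate the three experimental data sources the analysis
consumes:

* a barcoded transposon library under phage selection, where insertions in
  phage-required genes confer survival and every other clone survives only
  at a small escape rate ε (plating-and-scraping selection is modelled as
  barcode reweighting followed by multinomial resampling);
* protein × sample spectral-count tables with planted bait-proximal
  enrichments (Poisson counts over gamma-distributed per-protein baselines);
* homolog protein families with a conserved C-terminal region, a divergent
  variable-length N-terminal region, and optional transmembrane segments.

Every generator is a pure function of its seed and parameters; truth tables
emitted alongside the data suffice to recompute every generated observable.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from entryscreen.io import MISSING_GENE
from entryscreen.tables import BarcodePool, CountTable

_NUCLEOTIDES = np.array(list("ACGT"))
_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A gene interval on a simulated genome (0-based, half-open)."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: require 0 <= start < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclasses.dataclass(frozen=True)
class SelectionModel:
    """Which genes confer phage survival when disrupted, and the escape rate.

    A clone whose insertion lies in a required gene survives phage challenge
    with weight 1; every other clone survives with weight ``escape_rate``.
    """

    required_genes: frozenset[str]
    escape_rate: float
    moi_label: str = "phage"

    def __post_init__(self) -> None:
        if not 0.0 <= self.escape_rate <= 1.0:
            raise ValueError("escape_rate must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class ReadStructure:
    """Layout of a BarSeq amplicon read: flank + barcode + flank."""

    pre_flank: str
    post_flank: str
    barcode_length: int
    per_base_error: float = 0.0

    def __post_init__(self) -> None:
        for name, flank in (("pre_flank", self.pre_flank), ("post_flank", self.post_flank)):
            if not flank or set(flank) - set("ACGT"):
                raise ValueError(f"{name} must be non-empty and unambiguous ACGT")
        if self.barcode_length < 8:
            raise ValueError("barcode_length must be >= 8")
        if not 0.0 <= self.per_base_error <= 1.0:
            raise ValueError("per_base_error must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class HomologFamilySpec:
    """Parameters of a simulated homolog family.

    ``region_boundaries`` tiles the reference ``[1, reference_length]``
    (1-based inclusive) with named regions, each with its own per-site
    substitution rate. The first region additionally receives a random
    insertion or deletion of up to ``nterm_length_jitter`` residues, so
    N-terminal lengths vary across the family. Transmembrane segments are
    placed within the first 70 residues with length drawn from [10, 20].
    """

    reference_length: int
    region_boundaries: tuple[tuple[str, int, int], ...]
    per_region_substitution_rate: tuple[float, ...]
    nterm_length_jitter: int = 0
    tm_fraction_one: float = 0.0
    tm_fraction_two: float = 0.0

    def __post_init__(self) -> None:
        regions = list(self.region_boundaries)
        if len(regions) != len(self.per_region_substitution_rate):
            raise ValueError("one substitution rate per region required")
        expected = 1
        for name, start, end in regions:
            if start != expected or end < start:
                raise ValueError(
                    f"regions must tile [1, reference_length]; region {name!r} "
                    f"starts at {start}, expected {expected}"
                )
            expected = end + 1
        if expected != self.reference_length + 1:
            raise ValueError("regions must end exactly at reference_length")
        for rate in self.per_region_substitution_rate:
            if not 0.0 <= rate <= 1.0:
                raise ValueError("substitution rates must lie in [0, 1]")
        if self.tm_fraction_one + self.tm_fraction_two > 1.0:
            raise ValueError("tm_fraction_one + tm_fraction_two must be <= 1")


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if 4**length < n:
        raise ValueError(
            f"barcode space exhausted: 4^{length} < {n} requested insertions"
        )
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out), length))
        for row in batch:
            bc = "".join(_NUCLEOTIDES[row])
            if bc not in seen:  # rejection sampling handles collisions
                seen.add(bc)
                out.append(bc)
    return out


def simulate_tn_library(
    genome_length: int,
    gene_models: Sequence[GeneModel],
    n_insertions: int,
    barcode_length: int = 20,
    abundance_dispersion: float = 1.0,
    seed: int = 0,
) -> BarcodePool:
    """Simulate a barcoded transposon-insertion library.

    Each insertion gets a unique random barcode and a uniform-random genome
    position; insertions inside a gene's ``[start, end)`` are labelled with
    that gene, the rest as intergenic (``"-"``). Pre-selection clone
    abundances are log-normal with sigma ``abundance_dispersion`` — the
    standard model for clone-abundance skew in pooled libraries.
    """
    if n_insertions < 1:
        raise ValueError("n_insertions must be >= 1")
    for g in gene_models:
        if g.end > genome_length:
            raise ValueError(f"gene {g.gene_id} extends past genome_length")
    rng = np.random.default_rng(seed)
    barcodes = _random_barcodes(rng, n_insertions, barcode_length)
    positions = rng.integers(0, genome_length, size=n_insertions)
    abundances = rng.lognormal(mean=0.0, sigma=abundance_dispersion, size=n_insertions)

    genes_sorted = sorted(gene_models, key=lambda g: g.start)
    gene_ids = []
    for pos in positions:
        label = MISSING_GENE
        for g in genes_sorted:
            if g.start <= pos < g.end:
                label = g.gene_id
                break
        gene_ids.append(label)

    table = pd.DataFrame(
        {
            "barcode": barcodes,
            "position": positions.astype(int),
            "gene_id": gene_ids,
            "abundance": abundances,
        }
    )
    return BarcodePool(table)


def write_pool_with_truth(pool: BarcodePool, path: str | Path) -> Path:
    """Write the pool TSV plus its ``.truth.tsv`` (identical content: the
    pool table *is* the library's ground truth)."""
    path = Path(path)
    pool.to_tsv(path)
    truth = path.with_suffix(path.suffix + ".truth.tsv")
    pool.to_tsv(truth)
    return truth


def simulate_selection(
    pool: BarcodePool,
    selection_model: SelectionModel,
    depth_control: int,
    depth_phage: int,
    seed: int = 0,
    control_label: str = "noPhage",
) -> tuple[CountTable, pd.DataFrame]:
    """Sample sequencing counts before and after phage selection.

    The control column is a multinomial draw of ``depth_control`` reads over
    pre-selection abundances. The phage column reweights each clone by its
    survival weight (1 for insertions in required genes, ε otherwise) before
    the multinomial draw, which captures the effective statistics of the
    plate-challenge-scrape protocol. Returns the count table and a truth
    frame recording the survival weight per barcode.
    """
    if depth_control < 1 or depth_phage < 1:
        raise ValueError("sequencing depths must be >= 1")
    rng = np.random.default_rng(seed)
    abundance = pool.table["abundance"].to_numpy(dtype=float)
    required = selection_model.required_genes
    weights = np.where(
        pool.table["gene_id"].isin(required),
        1.0,
        selection_model.escape_rate,
    )
    phage_mass = abundance * weights
    if phage_mass.sum() == 0:
        raise ValueError("no surviving population: all survival weights are zero")

    control = rng.multinomial(depth_control, abundance / abundance.sum())
    phage = rng.multinomial(depth_phage, phage_mass / phage_mass.sum())

    counts = np.column_stack([control, phage])
    table = CountTable(pool.barcodes, [control_label, selection_model.moi_label], counts)
    truth = pd.DataFrame(
        {
            "barcode": pool.barcodes,
            "gene_id": pool.table["gene_id"],
            "survival_weight": weights,
        }
    )
    return table, truth


def _mutate_bases(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(arr.size) < error_rate
    if hits.any():
        # substitute with one of the three other bases, uniformly
        for i in np.nonzero(hits)[0]:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def emit_barseq_reads(
    counts: dict[str, int],
    pool: BarcodePool,
    read_structure: ReadStructure,
    path: str | Path,
    seed: int = 0,
) -> int:
    """Write one FASTQ read per count unit for one condition column.

    Reads are ``pre_flank + barcode + post_flank`` with independent per-base
    substitution errors at ``read_structure.per_base_error``; qualities are a
    constant placeholder. Returns the number of reads written.
    """
    known = set(pool.barcodes)
    unknown = set(counts) - known
    if unknown:
        raise ValueError(f"counted barcodes absent from pool: {sorted(unknown)[:3]}")
    rng = np.random.default_rng(seed)
    n_written = 0
    with open(path, "w") as fh:
        for barcode in pool.barcodes:
            n = counts.get(barcode, 0)
            for k in range(n):
                template = read_structure.pre_flank + barcode + read_structure.post_flank
                read = _mutate_bases(rng, template, read_structure.per_base_error)
                qual = "I" * len(read)
                fh.write(f"@{barcode}_{k}\n{read}\n+\n{qual}\n")
                n_written += 1
    return n_written


def simulate_spectral_counts(
    n_proteins: int,
    baseline_mean: float,
    planted: Sequence[tuple[str, float]],
    n_samples: int = 1,
    seed: int = 0,
    baseline_shape: float = 2.0,
):
    """Simulate a protein × sample spectral-count table with planted hits.

    Per-protein baseline abundances are gamma-distributed across proteins
    (shape ``baseline_shape``, mean ``baseline_mean``); counts are Poisson
    around the baseline, multiplied by the planted fold change in bait
    samples. Samples are named ``bait_1..n`` and ``control_1..n``. Planted
    protein ids must be among ``protein_0001 ...``-style generated ids or
    they are appended as extra phage-origin rows.

    Returns ``(SpectralCountTable, truth)`` where truth records each planted
    protein and its fold change.
    """
    from entryscreen.spectral_ratios import SpectralCountTable

    for _, fold in planted:
        if fold <= 0:
            raise ValueError("planted fold_change must be > 0")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_proteins)))
    protein_ids = [f"protein_{i + 1:0{width}d}" for i in range(n_proteins)]
    origins = ["host"] * n_proteins
    planted_map = dict(planted)
    for pid in planted_map:
        if pid not in protein_ids:
            protein_ids.append(pid)
            origins.append("phage")

    baselines = rng.gamma(
        shape=baseline_shape,
        scale=baseline_mean / baseline_shape,
        size=len(protein_ids),
    )
    folds = np.array([planted_map.get(pid, 1.0) for pid in protein_ids])

    samples = [f"bait_{j + 1}" for j in range(n_samples)] + [
        f"control_{j + 1}" for j in range(n_samples)
    ]
    counts = np.empty((len(protein_ids), len(samples)), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = rng.poisson(baselines * folds)
    for j in range(n_samples):
        counts[:, n_samples + j] = rng.poisson(baselines)

    table = SpectralCountTable(
        proteins=list(zip(protein_ids, origins)),
        samples=samples,
        counts=counts,
    )
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "baseline_mean": baselines,
            "fold_change": folds,
        }
    )
    return table, truth


@dataclasses.dataclass
class HomologFamily:
    """Output bundle of :func:`simulate_homolog_family`.

    ``sequences`` are the ungapped homolog sequences (reference included);
    ``alignment`` is the induced true MSA (equal-length gapped rows);
    ``region_truth`` gives true per-homolog region lengths; ``tm_truth``
    lists true transmembrane segments in homolog coordinates (1-based
    inclusive).
    """

    reference_id: str
    sequences: dict[str, str]
    alignment: dict[str, str]
    region_truth: pd.DataFrame
    tm_truth: pd.DataFrame


def simulate_homolog_family(
    spec: HomologFamilySpec,
    n_homologs: int,
    seed: int = 0,
) -> HomologFamily:
    """Simulate a homolog family from a random reference protein.

    Each homolog is the reference with independent per-site substitutions at
    its region's rate, plus an N-terminal insertion or deletion of up to
    ``nterm_length_jitter`` residues applied just after the first reference
    position (insertions) or to the leading residues (deletions). The true
    induced alignment is emitted: insertion columns carry gaps in every
    other row, deleted reference positions carry gaps in the affected
    homolog. Transmembrane segments, when assigned, start within the first
    70 residues with lengths in [10, 20].
    """
    if n_homologs < 2:
        raise ValueError("n_homologs must be >= 2")
    rng = np.random.default_rng(seed)
    L = spec.reference_length
    reference = "".join(rng.choice(_AMINO_ACIDS, size=L))
    ref_id = "reference"

    rate_at = np.empty(L)
    region_of = np.empty(L, dtype=object)
    for (name, start, end), rate in zip(
        spec.region_boundaries, spec.per_region_substitution_rate
    ):
        rate_at[start - 1 : end] = rate
        region_of[start - 1 : end] = name

    homolog_ids = [f"hom_{i + 1:04d}" for i in range(n_homologs)]
    base_rows: dict[str, list[str]] = {}
    insertions: dict[str, str] = {}
    deletions: dict[str, int] = {}

    for hid in homolog_ids:
        chars = list(reference)
        sub = rng.random(L) < rate_at
        for i in np.nonzero(sub)[0]:
            alternatives = [a for a in _AMINO_ACIDS if a != reference[i]]
            chars[i] = alternatives[rng.integers(0, 19)]
        ins_seq, n_del = "", 0
        if spec.nterm_length_jitter > 0:
            length = int(rng.integers(0, spec.nterm_length_jitter + 1))
            if length > 0:
                if rng.random() < 0.5:
                    ins_seq = "".join(rng.choice(_AMINO_ACIDS, size=length))
                else:
                    # deletions stay within the first region
                    n_del = min(length, spec.region_boundaries[0][2])
                    for i in range(n_del):
                        chars[i] = "-"
        base_rows[hid] = chars
        insertions[hid] = ins_seq
        deletions[hid] = n_del

    # Build the induced MSA: one column per reference position, plus an
    # insertion block right after reference position 1 sized to the longest
    # insertion (shorter insertions are left-aligned within the block).
    max_ins = max((len(s) for s in insertions.values()), default=0)
    alignment: dict[str, str] = {}
    ref_row = reference[0] + "-" * max_ins + reference[1:]
    alignment[ref_id] = ref_row
    for hid in homolog_ids:
        chars = base_rows[hid]
        ins = insertions[hid]
        block = ins + "-" * (max_ins - len(ins))
        alignment[hid] = chars[0] + block + "".join(chars[1:])

    sequences = {ref_id: reference}
    for hid in homolog_ids:
        sequences[hid] = alignment[hid].replace("-", "")

    region_rows = []
    for hid in homolog_ids:
        offset_first = len(insertions[hid]) - deletions[hid]
        for (name, start, end) in spec.region_boundaries:
            ref_len = end - start + 1
            length = ref_len + (offset_first if start == 1 else 0)
            region_rows.append(
                {"homolog_id": hid, "region": name, "length": int(length)}
            )
    region_truth = pd.DataFrame(region_rows)

    tm_rows = []
    lengths = {hid: len(sequences[hid]) for hid in homolog_ids}
    for hid in homolog_ids:
        u = rng.random()
        if u < spec.tm_fraction_one:
            n_tm = 1
        elif u < spec.tm_fraction_one + spec.tm_fraction_two:
            n_tm = 2
        else:
            n_tm = 0
        window_end = min(70, lengths[hid])
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < n_tm and attempts < 200:
            attempts += 1
            tm_len = int(rng.integers(10, 21))
            if window_end < tm_len:
                break
            start = int(rng.integers(1, window_end - tm_len + 2))
            end = start + tm_len - 1
            if all(end < s or start > e for s, e in placed):
                placed.append((start, end))
        for start, end in sorted(placed):
            tm_rows.append({"homolog_id": hid, "start": start, "end": end})
    tm_truth = pd.DataFrame(tm_rows, columns=["homolog_id", "start", "end"])

    return HomologFamily(
        reference_id=ref_id,
        sequences=sequences,
        alignment=alignment,
        region_truth=region_truth,
        tm_truth=tm_truth,
    )
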