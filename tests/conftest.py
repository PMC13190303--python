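"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import functools
import itertools

import numpy as np
import pandas as pd
import pytest

from entryscreen.synthetic_data import (
    GeneModel,
    HomologFamilySpec,
    ReadStructure,
    SelectionModel,
    simulate_selection,
    simulate_tn_library,
)
from entryscreen.tables import BarcodePool


# ---------------------------------------------------------------------------
# Screen scenario: 200 genes, 3000 insertions, 2 required genes


def make_gene_models(n_genes: int = 200, gene_length: int = 900, spacing: int = 1000):
    return [
        GeneModel(f"g{i:03d}", i * spacing, i * spacing + gene_length)
        for i in range(n_genes)
    ]


def make_screen(seed: int, escape_rate: float = 1e-3, required=("g010", "g120"),
                n_genes: int = 200, n_insertions: int = 3000, depth: int = 10**6):
    """One synthetic phage-selection screen with known required genes."""
    genes = make_gene_models(n_genes)
    pool = simulate_tn_library(
        genome_length=n_genes * 1000,
        gene_models=genes,
        n_insertions=n_insertions,
        barcode_length=20,
        abundance_dispersion=1.0,
        seed=seed,
    )
    model = SelectionModel(frozenset(required), escape_rate, moi_label="phage")
    table, truth = simulate_selection(pool, model, depth, depth, seed=seed + 10_000)
    return pool, table, truth


@pytest.fixture
def read_structure():
    return ReadStructure(
        pre_flank="GATGTCCACGAGGTCTCT",
        post_flank="CGTACGCTGCAGGTCGAC",
        barcode_length=20,
        per_base_error=0.0,
    )


@pytest.fixture
def small_pool():
    table = pd.DataFrame(
        {
            "barcode": ["AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG", "TTTTTTTTTT"],
            "position": [10, 500, 1200, 1800],
            "gene_id": ["geneA", "geneA", "geneB", "-"],
            "abundance": [1.0, 2.0, 3.0, 4.0],
        }
    )
    return BarcodePool(table)


@pytest.fixture
def homolog_spec():
    """Divergent N-terminal region, conserved C-terminal domain."""
    return HomologFamilySpec(
        reference_length=300,
        region_boundaries=(("nterm", 1, 100), ("cterm", 101, 300)),
        per_region_substitution_rate=(0.5, 0.02),
        nterm_length_jitter=15,
        tm_fraction_one=0.59,
        tm_fraction_two=0.07,
    )


# ---------------------------------------------------------------------------
# Independent alignment oracles (match +1, mismatch 0, gap -1)


def enumerate_alignments_oracle(a: str, b: str):
    """Exhaustively enumerate every global alignment path and return the
    (identity, coverage) of the lexicographic (score, matches) optimum.

    Pure path enumeration — exponential, for tiny sequences only.
    """
    best = None  # (score, matches, columns, pairs)
    stack = [(0, 0, 0, 0, 0, 0)]  # i, j, score, matches, columns, pairs
    la, lb = len(a), len(b)
    while stack:
        i, j, score, matches, columns, pairs = stack.pop()
        if i == la and j == lb:
            key = (score, matches)
            if best is None or key > (best[0], best[1]):
                best = (score, matches, columns, pairs)
            continue
        if i < la and j < lb:
            m = 1 if a[i] == b[j] else 0
            stack.append((i + 1, j + 1, score + m, matches + m, columns + 1, pairs + 1))
        if i < la:
            stack.append((i + 1, j, score - 1, matches, columns + 1, pairs))
        if j < lb:
            stack.append((i, j + 1, score - 1, matches, columns + 1, pairs))
    _, matches, columns, pairs = best
    return matches / columns, pairs / min(la, lb)


def recursive_alignment_oracle(a: str, b: str):
    """Memoized tuple-valued recursion for the same optimum — an
    independent route to (identity, coverage) for sequences up to ~8."""

    @functools.cache
    def rec(i: int, j: int):
        # returns best (score, matches) aligning a[i:] with b[j:]
        if i == len(a) and j == len(b):
            return (0, 0)
        options = []
        if i < len(a) and j < len(b):
            m = 1 if a[i] == b[j] else 0
            s, k = rec(i + 1, j + 1)
            options.append((s + m, k + m))
        if i < len(a):
            s, k = rec(i + 1, j)
            options.append((s - 1, k))
        if j < len(b):
            s, k = rec(i, j + 1)
            options.append((s - 1, k))
        return max(options)

    score, matches = rec(0, 0)
    rec.cache_clear()
    gaps = matches - score
    pairs = (len(a) + len(b) - gaps) // 2
    return matches / (pairs + gaps), pairs / min(len(a), len(b))


def greedy_cover_oracle(hit_sets: dict[str, set[str]]):
    """Independently coded greedy most-common-hit cover."""
    remaining = {h: set(s) for h, s in hit_sets.items() if s}
    out = []
    while remaining:
        all_hits = sorted({h for s in remaining.values() for h in s})
        counts = {h: sum(h in s for s in remaining.values()) for h in all_hits}
        top = max(counts.values())
        pick = sorted(h for h, c in counts.items() if c == top)[0]
        out.append((pick, top))
        remaining = {k: s for k, s in remaining.items() if pick not in s}
    return out
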