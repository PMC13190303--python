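"""Family analytics: alignment identity, dereplication, profiles, TM, cover."""

import itertools

import numpy as np
import pandas as pd
import pytest

from entryscreen.homolog_architecture import (
    AlignedFamily,
    TMAnnotation,
    clade_grouping,
    column_identity_profile,
    dereplicate,
    greedy_hit_cover,
    hydropathy_tm_predict,
    identity_matrix,
    pairwise_identity,
    region_lengths,
    summarize_tm,
)
from entryscreen.synthetic_data import HomologFamilySpec, simulate_homolog_family

from conftest import (
    enumerate_alignments_oracle,
    greedy_cover_oracle,
    recursive_alignment_oracle,
)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKTLV", "MKTLV") == (1.0, 1.0)

    def test_single_substitution(self):
        ident, cov = pairwise_identity("AAAA", "AATA")
        assert ident == 0.75 and cov == 1.0

    def test_prefix_coverage_against_shorter(self):
        long = "M" + "KTLVAWFE" * 12
        short = long[:50]
        ident, cov = pairwise_identity(long, short)
        assert cov == 1.0  # every residue of the shorter aligns
        assert ident == pytest.approx(50 / len(long))

    def test_symmetry(self):
        a, b = "MKTAYIAKQR", "MKTWYIAKR"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "AA")

    def test_agrees_with_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(0)
        alphabet = "ACGT"
        for _ in range(60):
            la, lb = rng.integers(1, 6, size=2)
            a = "".join(rng.choice(list(alphabet), la))
            b = "".join(rng.choice(list(alphabet), lb))
            assert pairwise_identity(a, b) == pytest.approx(
                enumerate_alignments_oracle(a, b)
            ), (a, b)

    def test_agrees_with_independent_recursion_up_to_length_8(self):
        rng = np.random.default_rng(1)
        for _ in range(150):
            la, lb = rng.integers(1, 9, size=2)
            a = "".join(rng.choice(list("ACGT"), la))
            b = "".join(rng.choice(list("ACGT"), lb))
            assert pairwise_identity(a, b) == pytest.approx(
                recursive_alignment_oracle(a, b)
            ), (a, b)

    def test_matrix_symmetric_unit_diagonal(self):
        seqs = {"a": "MKTLVAW", "b": "MKTLVAF", "c": "GGGGGGG"}
        m = identity_matrix(seqs)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)

    def test_region_restricted_identity(self):
        # identical in residues 3-6, divergent elsewhere
        a = "WWABCDWW"
        b = "YYABCDYY"
        full, _ = pairwise_identity(a, b)
        m = identity_matrix({"a": a, "b": b}, region=(3, 6))
        assert m.loc["a", "b"] == 1.0
        assert full < 1.0


class TestDereplicate:
    def test_identical_pair_collapses(self):
        reps, members = dereplicate({"s1": "MKTLVAWFE", "s2": "MKTLVAWFE"})
        assert len(reps) == 1
        assert members["s1"] == members["s2"] == reps[0]

    def test_94_percent_pair_kept_separate_at_default_thresholds(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100))
        mutated = list(base)
        for i in range(0, 60, 10):  # 6 substitutions -> 94% identity
            mutated[i] = "W" if base[i] != "W" else "Y"
        mutated = "".join(mutated)
        assert pairwise_identity(base, mutated)[0] == pytest.approx(0.94)
        reps, _ = dereplicate({"s1": base, "s2": mutated})
        assert len(reps) == 2

    def test_every_member_meets_both_thresholds(self):
        spec = HomologFamilySpec(
            reference_length=80,
            region_boundaries=(("all", 1, 80),),
            per_region_substitution_rate=(0.03,),
        )
        fam = simulate_homolog_family(spec, 12, seed=7)
        reps, members = dereplicate(fam.sequences, 0.9, 0.8)
        for name, rep in members.items():
            if name == rep:
                continue
            ident, cov = pairwise_identity(fam.sequences[name], fam.sequences[rep])
            assert ident >= 0.9 and cov >= 0.8

    def test_deterministic_scan_order(self):
        seqs = {"b": "MKTLVAWFE", "a": "MKTLVAWFE", "c": "GG"}
        reps1, m1 = dereplicate(seqs)
        reps2, m2 = dereplicate(dict(reversed(seqs.items())))
        assert reps1 == reps2 == ["a", "c"]  # ties by id ascending
        assert m1 == m2


def toy_family():
    rows = {
        "ref": "AAAAA",
        "h1": "AAAAA",
        "h2": "AACAA",
        "h3": "CATAA",
    }
    return AlignedFamily(reference_id="ref", rows=rows)


class TestColumnIdentityProfile:
    def test_identical_rows_profile_is_one(self):
        fam = AlignedFamily("ref", {"ref": "MKTLV", "h1": "MKTLV", "h2": "MKTLV"})
        for window in (1, 3, 5):
            assert np.allclose(column_identity_profile(fam, window), 1.0)

    def test_hand_computed_toy_msa(self):
        fam = toy_family()
        raw = column_identity_profile(fam, window=1)
        np.testing.assert_allclose(raw, [2 / 3, 1.0, 1 / 3, 1.0, 1.0])
        smoothed = column_identity_profile(fam, window=5)
        expected = [2 / 3, 3 / 4, 4 / 5, 5 / 6, 7 / 9]
        np.testing.assert_allclose(smoothed, expected)

    def test_gap_counts_as_mismatch(self):
        fam = AlignedFamily("ref", {"ref": "MK", "h1": "M-"})
        np.testing.assert_allclose(column_identity_profile(fam, 1), [1.0, 0.0])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            column_identity_profile(toy_family(), window=4)

    def test_region_rate_ordering_propagates_to_identity(self, homolog_spec):
        for seed in range(5):
            fam = simulate_homolog_family(homolog_spec, 25, seed=seed)
            family = AlignedFamily("reference", fam.alignment)
            profile = column_identity_profile(family, window=5)
            nterm = profile[:100].mean()
            cterm = profile[100:].mean()
            assert cterm > nterm

    def test_profile_bounded_in_unit_interval(self, homolog_spec):
        fam = simulate_homolog_family(homolog_spec, 10, seed=9)
        profile = column_identity_profile(AlignedFamily("reference", fam.alignment))
        assert ((profile >= 0) & (profile <= 1)).all()
        assert len(profile) == 300


class TestRegionLengths:
    def test_ungapped_alignment_gives_reference_lengths(self):
        fam = AlignedFamily("ref", {"ref": "AAAAAA", "h1": "CCCCCC"})
        out = region_lengths(fam, [("r1", 1, 3), ("r2", 4, 6)])
        assert set(out["length"]) == {3}

    def test_insertion_within_region_adds_its_length(self):
        rows = {
            "ref": "A" + "-" * 7 + "AAA",
            "h1": "A" + "WWWWWWW" + "AAA",
        }
        fam = AlignedFamily("ref", rows)
        out = region_lengths(fam, [("r1", 1, 2), ("r2", 3, 4)])
        lengths = dict(zip(out["region"], out["length"]))
        assert lengths == {"r1": 9, "r2": 2}

    def test_fully_gapped_region_has_length_zero(self):
        fam = AlignedFamily("ref", {"ref": "AAAA", "h1": "--AA"})
        out = region_lengths(fam, [("r1", 1, 2), ("r2", 3, 4)])
        lengths = dict(zip(out["region"], out["length"]))
        assert lengths == {"r1": 0, "r2": 2}

    def test_tiling_partitions_homolog_residues(self, homolog_spec):
        fam = simulate_homolog_family(homolog_spec, 10, seed=11)
        family = AlignedFamily("reference", fam.alignment)
        out = region_lengths(family, [("nterm", 1, 100), ("cterm", 101, 300)])
        totals = out.groupby("homolog_id")["length"].sum()
        for hid, total in totals.items():
            assert total == len(fam.sequences[hid])


class TestSummarizeTm:
    def test_category_percentages_and_class_sizes(self):
        anns = [
            TMAnnotation("h1", []),
            TMAnnotation("h2", [(5, 23)]),
            TMAnnotation("h3", [(3, 14), (30, 45)]),
        ]
        s = summarize_tm(anns, family_size=3)
        assert s["percent"]["0"] == pytest.approx(100 / 3)
        assert s["percent"]["1"] == pytest.approx(100 / 3)
        assert s["percent"]["2+"] == pytest.approx(100 / 3)
        assert s["first_tm"]["n"] == 2 and s["second_tm"]["n"] == 1
        assert s["first_tm"]["starts"] == [5, 3]
        assert s["first_tm"]["lengths"] == [19, 12]  # inclusive coordinates

    def test_unannotated_homologs_count_as_zero_segments(self):
        s = summarize_tm([TMAnnotation("h1", [(1, 12)])], family_size=4)
        assert s["percent"]["0"] == 75.0

    def test_duplicate_homolog_is_hard_error(self):
        anns = [TMAnnotation("h1", []), TMAnnotation("h1", [(1, 12)])]
        with pytest.raises(ValueError, match="duplicate"):
            summarize_tm(anns, family_size=2)

    def test_simulated_fractions_recovered(self):
        spec = HomologFamilySpec(
            reference_length=150,
            region_boundaries=(("all", 1, 150),),
            per_region_substitution_rate=(0.05,),
            tm_fraction_one=0.59,
            tm_fraction_two=0.07,
        )
        n = 1000
        fam = simulate_homolog_family(spec, n, seed=13)
        anns = [
            TMAnnotation(hid, [tuple(x) for x in grp[["start", "end"]].to_numpy()])
            for hid, grp in fam.tm_truth.groupby("homolog_id")
        ]
        s = summarize_tm(anns, family_size=n)
        for key, p in (("0", 0.34), ("1", 0.59), ("2+", 0.07)):
            sd = 100 * np.sqrt(p * (1 - p) / n)
            assert abs(s["percent"][key] - 100 * p) < 3 * sd


class TestHydropathyTmPredict:
    def test_hydrophobic_run_yields_single_covering_segment(self):
        seq = "D" * 10 + "I" * 19 + "D" * 10
        ann = hydropathy_tm_predict(seq)
        assert len(ann.segments) == 1
        start, end = ann.segments[0]
        assert start <= 11 and end >= 29  # covers the isoleucine run

    def test_polar_sequence_has_no_segments(self):
        assert hydropathy_tm_predict("D" * 40).segments == []

    def test_short_sequence_yields_empty_annotation(self):
        assert hydropathy_tm_predict("MKT").segments == []

    def test_two_separated_runs_give_sorted_disjoint_segments(self):
        seq = "D" * 8 + "I" * 19 + "D" * 30 + "L" * 19 + "D" * 8
        ann = hydropathy_tm_predict(seq)
        assert len(ann.segments) == 2
        (s1, e1), (s2, e2) = ann.segments
        assert e1 < s2


class TestGreedyHitCover:
    def _table(self, mapping, p=1e-9):
        rows = [
            {"homolog_id": h, "hit_name": hit, "p_value": p}
            for h, hits in mapping.items()
            for hit in hits
        ]
        return pd.DataFrame(rows, columns=["homolog_id", "hit_name", "p_value"])

    def test_simple_two_step_cover(self):
        out = greedy_hit_cover(self._table({"A": {"h1"}, "B": {"h1"}, "C": {"h2"}}))
        assert out == [("h1", 2), ("h2", 1)]

    def test_empty_table_gives_empty_cover(self):
        assert greedy_hit_cover(self._table({})) == []

    def test_insignificant_hits_are_discarded(self):
        df = self._table({"A": {"h1"}}, p=1e-4)  # above the 1e-5 cutoff
        assert greedy_hit_cover(df) == []
        assert greedy_hit_cover(df, p_cutoff=1e-3) == [("h1", 1)]

    def test_counts_sum_to_covered_homologs(self):
        df = self._table({"A": {"h1", "h2"}, "B": {"h2"}, "C": {"h3"}, "D": {"h1", "h3"}})
        out = greedy_hit_cover(df)
        assert sum(c for _, c in out) == 4

    def test_matches_independent_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n_hom = rng.integers(1, 13)
            n_hits = rng.integers(1, 7)
            mapping = {}
            for i in range(n_hom):
                k = rng.integers(0, n_hits + 1)
                mapping[f"H{i}"] = set(
                    f"hit{j}" for j in rng.choice(n_hits, size=k, replace=False)
                )
            expected = greedy_cover_oracle(mapping)
            assert greedy_hit_cover(self._table(mapping)) == expected, mapping


class TestCladeGrouping:
    def _matrix(self, ids, values):
        return pd.DataFrame(np.array(values, dtype=float), index=ids, columns=ids)

    def test_two_clean_blocks_conform(self):
        m = self._matrix(
            ["a", "b", "c", "d"],
            [
                [1.0, 0.95, 0.10, 0.10],
                [0.95, 1.0, 0.10, 0.10],
                [0.10, 0.10, 1.0, 0.95],
                [0.10, 0.10, 0.95, 1.0],
            ],
        )
        labels, report = clade_grouping(m)
        assert labels["a"] == labels["b"] != labels["c"]
        assert report["n_clades"] == 2 and report["non_conforming"] == []

    def test_singleton_forms_its_own_clade(self):
        m = self._matrix(
            ["a", "b", "x"],
            [[1.0, 0.95, 0.05], [0.95, 1.0, 0.05], [0.05, 0.05, 1.0]],
        )
        labels, report = clade_grouping(m)
        assert labels["x"] not in (labels["a"],)
        assert report["n_clades"] == 2

    def test_cross_clade_pair_above_between_threshold_flags_both(self):
        m = self._matrix(
            ["a", "b", "c", "d"],
            [
                [1.0, 0.95, 0.25, 0.10],
                [0.95, 1.0, 0.10, 0.10],
                [0.25, 0.10, 1.0, 0.95],
                [0.10, 0.10, 0.95, 1.0],
            ],
        )
        labels, report = clade_grouping(m)
        assert labels["a"] != labels["c"]  # flagged, never merged
        assert sorted(report["non_conforming"]) == sorted({labels["a"], labels["c"]})
        assert report["violations"][0][:2] == ("a", "c")

    def test_asymmetric_matrix_is_hard_error(self):
        m = self._matrix(["a", "b"], [[1.0, 0.5], [0.6, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            clade_grouping(m)

    def test_threshold_ordering_enforced(self):
        m = self._matrix(["a"], [[1.0]])
        with pytest.raises(ValueError):
            clade_grouping(m, within_threshold=0.2, between_threshold=0.9)
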