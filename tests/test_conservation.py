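"""Codon threading, conservation tiers, window discovery and NJ trees."""

import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import (
    leaf_distance_matrix,
    newick_splits,
    random_additive_tree,
    tree_splits,
)
from mybslim.conservation import (
    ColumnStats,
    DistanceMatrix,
    column_conservation,
    find_conserved_windows,
    neighbor_joining,
    p_distance_matrix,
    thread_codon_alignment,
)
from mybslim.records import MultipleAlignment, SequenceRecord, ungap
from mybslim.synthetic_data import reverse_translate


def aln(rows, alphabet="protein"):
    return MultipleAlignment([(f"r{i}", s) for i, s in enumerate(rows)], alphabet)


class TestThreading:
    def test_direct_threading_with_gap(self):
        pa = MultipleAlignment([("x", "M-A")], "protein")
        cds = {"x": SequenceRecord("x", "ATGGCT", "dna")}
        out = thread_codon_alignment(pa, cds)
        assert out.rows[0][1] == "ATG---GCT"
        assert out.alphabet == "codon"

    def test_terminal_stop_dropped(self):
        pa = MultipleAlignment([("x", "MA")], "protein")
        cds = {"x": SequenceRecord("x", "ATGGCTTGA", "dna")}
        out = thread_codon_alignment(pa, cds)
        assert out.rows[0][1] == "ATGGCT"

    def test_round_trip_translate_identity(self):
        rng = np.random.default_rng(5)
        rows = []
        cds = {}
        for i in range(6):
            prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30))
            gapped = list(prot)
            for pos in sorted(rng.choice(30, 4, replace=False))[::-1]:
                gapped.insert(pos, "-")
            rows.append((f"s{i}", "".join(gapped)))
            cds[f"s{i}"] = SequenceRecord(f"s{i}", reverse_translate(prot, rng), "dna")
        # pad rows to equal length
        width = max(len(s) for _, s in rows)
        pa = MultipleAlignment(
            [(rid, s + "-" * (width - len(s))) for rid, s in rows], "protein"
        )
        out = thread_codon_alignment(pa, cds)
        for (rid, codon_row), (_, prot_row) in zip(out.rows, pa.rows):
            back = str(Seq(ungap(codon_row)).translate())
            assert back == ungap(prot_row)

    def test_length_mismatch_names_offender(self):
        pa = MultipleAlignment([("bad", "MA")], "protein")
        cds = {"bad": SequenceRecord("bad", "ATGGCTAAA", "dna")}
        with pytest.raises(ValueError, match="bad"):
            thread_codon_alignment(pa, cds)

    def test_internal_stop_rejected(self):
        pa = MultipleAlignment([("x", "MKA")], "protein")
        cds = {"x": SequenceRecord("x", "ATGTAAGCT", "dna")}
        with pytest.raises(ValueError, match="internal stop"):
            thread_codon_alignment(pa, cds)


class TestColumnConservation:
    def test_unanimous_dna_column(self):
        stats = column_conservation(aln(["A", "A", "A"], "dna"))
        assert stats[0].identity == 1.0
        assert stats[0].tier == "full"
        assert stats[0].information_content == pytest.approx(2.0)

    def test_hand_counted_mid_column(self):
        rows = list("AACGTTTTTT")  # modal T: 6/10
        stats = column_conservation(aln(rows, "dna"))
        assert stats[0].identity == pytest.approx(0.6)
        assert stats[0].tier == "mid"

    def test_gaps_ignored_uses_residues_only(self):
        rows = ["A", "A", "-", "-", "-"]
        stats = column_conservation(aln(rows, "protein"), ignore_gaps=True)
        assert stats[0].identity == 1.0
        stats = column_conservation(aln(rows, "protein"), ignore_gaps=False)
        assert stats[0].identity == pytest.approx(3 / 5)  # '-' is modal
        assert stats[0].consensus_symbol == "-"

    def test_consensus_tie_breaks_alphabetically(self):
        stats = column_conservation(aln(["C", "A"], "protein"))
        assert stats[0].consensus_symbol == "A"

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            column_conservation(aln(["ACGT"], "dna"))

    @pytest.mark.parametrize(
        "column,identity,tier",
        [
            ("AAAAAAAAAA", 1.0, "full"),          # unanimity: full
            ("AAACGTCGTC", 0.30, "mid"),          # exactly 30%: mid
            ("AACGTCGTAC", 0.30, "mid"),          # 3/10 modal symbol again
            ("ACGTACGTCG", 0.30, "mid"),
            ("AACGTCG", 2 / 7, "low"),            # 28.6% < 30%: low
            ("AAAAAAAAAC", 0.9, "mid"),           # just below unanimity
        ],
    )
    def test_tier_boundaries(self, column, identity, tier):
        """Tier thresholds sit exactly at 100% and 30% identity."""
        stats = column_conservation(aln(list(column), "dna"))
        assert stats[0].identity == pytest.approx(identity)
        assert stats[0].tier == tier


def flat_stats(identities):
    return [ColumnStats(i, v, "low", "A", 0.0) for i, v in enumerate(identities)]


class TestFindConservedWindows:
    def test_uniform_identity_yields_nothing(self):
        stats = flat_stats([0.5] * 100)
        assert find_conserved_windows(stats, (0, 100), 15, 17, 0.05) == []

    def test_planted_block_recovered(self):
        ident = [0.4] * 100
        ident[40:55] = [0.95] * 15
        wins = find_conserved_windows(flat_stats(ident), (0, 100), 15, 17, 0.10)
        assert len(wins) == 1
        w = wins[0]
        overlap = min(w.end_col, 55) - max(w.start_col, 40)
        assert overlap >= 0.8 * 15

    def test_three_separated_blocks_give_three_windows(self):
        ident = [0.35] * 200
        for s in (20, 80, 140):
            ident[s : s + 16] = [0.95] * 16
        wins = find_conserved_windows(flat_stats(ident), (0, 200), 15, 17, 0.10)
        assert len(wins) == 3
        assert [w.label for w in wins] == ["W1", "W2", "W3"]

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(9)
        ident = rng.uniform(0.2, 0.9, 120)
        stats = flat_stats(ident)
        wins = find_conserved_windows(stats, (10, 110), 15, 17, 0.05)
        # oracle: direct enumeration and interval union
        base = ident[10:110].mean() + 0.05
        keep = [
            (s, s + L)
            for L in (15, 16, 17)
            for s in range(10, 110 - L + 1)
            if ident[s : s + L].mean() > base
        ]
        merged = []
        for s, e in sorted(keep):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        assert [(w.start_col, w.end_col) for w in wins] == [tuple(m) for m in merged]

    def test_region_shorter_than_min_len_rejected(self):
        with pytest.raises(ValueError):
            find_conserved_windows(flat_stats([0.5] * 10), (0, 10), 15, 17, 0.1)


class TestPDistance:
    def test_identical_rows_are_zero(self):
        dm = p_distance_matrix(aln(["ACGT", "ACGT", "ACGT"], "dna"))
        assert np.all(dm.d == 0)

    def test_hand_counts(self):
        dm = p_distance_matrix(aln(["AAAA", "AAAT", "A-CG"], "dna"))
        assert dm.d[0, 1] == pytest.approx(0.25)
        # r0 vs r2: comparable columns 0,2,3 -> mismatches at 2,3
        assert dm.d[0, 2] == pytest.approx(2 / 3)

    def test_gap_columns_excluded_from_comparison(self):
        dm = p_distance_matrix(aln(["A-CG", "ATCG", "ATCG"], "dna"))
        assert dm.d[0, 1] == 0.0  # 3 compared columns, all equal


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        nwk = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        splits = newick_splits(nwk, ["a", "b", "c"])
        assert splits[frozenset({"a"})] == pytest.approx((5 + 9 - 10) / 2)
        assert splits[frozenset({"b"})] == pytest.approx((5 + 10 - 9) / 2)
        assert splits[frozenset({"c"})] == pytest.approx((9 + 10 - 5) / 2)

    def test_equal_distances_complete_deterministically(self):
        d = np.ones((5, 5)) - np.eye(5)
        ids = list("abcde")
        nwk1 = neighbor_joining(DistanceMatrix(ids, d.copy()))
        nwk2 = neighbor_joining(DistanceMatrix(ids, d.copy()))
        assert nwk1 == nwk2

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_generating_topology_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        nodes, names, hub = random_additive_tree(n, rng)
        D = leaf_distance_matrix(nodes, names, n)
        nwk = neighbor_joining(DistanceMatrix([names[i] for i in range(n)], D))
        want, taxa = tree_splits(nodes, names, n, hub)
        got = newick_splits(nwk, taxa)
        assert set(want) == set(got)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9)

    def test_matches_scikit_bio_topology(self):
        """Independent cross-check against scikit-bio's NJ on one matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(123)
        nodes, names, hub = random_additive_tree(7, rng)
        D = leaf_distance_matrix(nodes, names, 7)
        ids = [names[i] for i in range(7)]
        ours = newick_splits(neighbor_joining(DistanceMatrix(ids, D)), ids)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        theirs = newick_splits(str(sk_tree).strip(), ids)
        assert set(ours) == set(theirs)

    def test_row_order_invariance_of_windows(self, default_family):
        """Window discovery must not depend on alignment row order."""
        alignment = default_family.alignment
        stats = column_conservation(alignment, ignore_gaps=False)
        wins = find_conserved_windows(stats, (130, alignment.n_columns))
        shuffled = MultipleAlignment(list(reversed(alignment.rows)), "protein")
        stats2 = column_conservation(shuffled, ignore_gaps=False)
        wins2 = find_conserved_windows(stats2, (130, alignment.n_columns))
        assert [(w.start_col, w.end_col) for w in wins] == [
            (w.start_col, w.end_col) for w in wins2
        ]
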