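"""Disorder stand-in, order-dip, enrichment and consensus divergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mybslim.conservation import ConservedWindow
from mybslim.disorder_morf import (
    DisorderProfile,
    MorfParams,
    PhenotypeLabel,
    activator_consensus,
    call_morf_candidates,
    composition_enrichment,
    disorder_profile,
    divergence_to_consensus,
    order_dip,
    window_spans_by_record,
)
from mybslim.records import MultipleAlignment, SequenceRecord


def prof(seq: str, window: int = 21) -> DisorderProfile:
    return disorder_profile(SequenceRecord("p", seq), window)


class TestDisorderProfile:
    def test_disorder_promoting_stretch_scores_high(self):
        p = prof("PESQK" * 12)
        assert np.all(p.scores[5:-5] > 0.5)

    def test_order_promoting_stretch_scores_low(self):
        p = prof("ILVFW" * 12)
        assert np.all(p.scores[5:-5] < 0.5)

    def test_ordered_block_dips_below_flanks(self):
        seq = "PESQK" * 8 + "ILVFWILVFWILVFW" + "PESQK" * 8
        p = prof(seq)
        block = slice(40, 55)
        assert p.scores[block].mean() < p.scores[:40].mean() - 0.1

    def test_scores_bounded_and_id_independent(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80))
        a = disorder_profile(SequenceRecord("a", seq), 21)
        b = disorder_profile(SequenceRecord("b", seq), 21)
        assert np.array_equal(a.scores, b.scores)
        assert np.all((a.scores >= 0) & (a.scores <= 1))
        assert len(a.scores) == len(seq)

    def test_even_or_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            prof("PESQK" * 10, window=10)
        with pytest.raises(ValueError):
            prof("PESQK" * 10, window=3)


class TestOrderDip:
    def _profile(self, scores):
        p = DisorderProfile("x", np.asarray(scores, float), 21)
        return p

    def test_strong_dip_passes(self):
        scores = [0.8] * 30 + [0.3] * 10 + [0.8] * 30
        dip, ok = order_dip(self._profile(scores), (30, 40), flank=25, margin=0.05)
        assert dip == pytest.approx(0.5)
        assert ok

    def test_uniform_profile_fails_any_positive_margin(self):
        scores = [0.7] * 60
        dip, ok = order_dip(self._profile(scores), (20, 30), margin=0.01)
        assert dip == pytest.approx(0.0)
        assert not ok

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError):
            order_dip(self._profile([0.5] * 40), (10, 10))

    def test_planted_morf_beats_random_control_spans(self, default_family):
        """The planted motif span dips; random control spans mostly do not."""
        rid = "ACT00"
        protein = next(p for p in default_family.proteins if p.id == rid)
        profile = disorder_profile(protein, 21)
        span = default_family.manifest.records[rid]["motif_spans"]["S6B"]
        dip, ok = order_dip(profile, tuple(span), flank=25, margin=0.05)
        assert ok
        rng = np.random.default_rng(0)
        cterm_start = default_family.manifest.records[rid]["domain_span"][1] + 10
        motif_spans = list(
            default_family.manifest.records[rid]["motif_spans"].values()
        )
        hits = 0
        trials = 0
        pad = 10  # keep controls clear of the motifs and smoothing halo
        while trials < 100:
            s = int(rng.integers(cterm_start, len(protein.residues) - 16))
            if any(s - pad < te and ts < s + 16 + pad for ts, te in motif_spans):
                continue
            trials += 1
            _, passed = order_dip(profile, (s, s + 16), flank=25, margin=0.05)
            hits += passed
        assert hits <= 0.05 * trials


class TestCompositionEnrichment:
    def test_closed_form_binomial_tail(self):
        # all 5 residues in the target set, background fraction 0.3
        bg = "DEI" + "G" * 7  # 3/10 hydrophobic+acidic
        frac, p, flag = composition_enrichment("DEILV", bg)
        assert frac == 1.0
        assert p == pytest.approx(0.3**5, rel=1e-9)
        assert not flag

    def test_zero_target_residues(self):
        frac, p, _ = composition_enrichment("GGGGG", "DEILVGGGGG")
        assert frac == 0.0 and p == 1.0

    def test_generic_phi_motif_span_is_enriched(self):
        # hydrophobic-rich span vs a disordered background
        frac, p, _ = composition_enrichment("LDDLL", "PESQKGRN" * 10)
        assert frac == 1.0 and p < 0.01

    def test_degenerate_background_flagged(self):
        _, p, flag = composition_enrichment("LLLLL", "GGGG")
        assert flag and p in (0.0, 1.0)


def _toy_alignment_and_phenotypes():
    rows = [
        ("a1", "PESQKPESQKILVFWILVFWPESQKPESQKPESQKPESQK"),
        ("a2", "PESQKPESQKILVFWILVFWPESQKPESQKPESQKPESQK"),
        ("n1", "PESQKPESQKSQPEKQPESKPESQKPESQKPESQKPESQK"),
    ]
    aln = MultipleAlignment(rows, "protein")
    phen = {
        "a1": PhenotypeLabel("a1", 7),
        "a2": PhenotypeLabel("a2", 4),
        "n1": PhenotypeLabel("n1", 0),
    }
    return aln, phen


class TestCallMorfCandidates:
    def test_flag_logic_requires_all_three(self):
        aln, phen = _toy_alignment_and_phenotypes()
        profiles = {
            rid: disorder_profile(SequenceRecord(rid, seq), 11)
            for rid, seq in aln.rows
        }
        window = ConservedWindow(10, 20, mean_identity=1.0, label="W1")
        unconserved = ConservedWindow(10, 20, mean_identity=0.2, label="W2")
        cands = call_morf_candidates(
            [window, unconserved], profiles, aln, phen,
            MorfParams(flank=10, dip_margin=0.05, alpha=0.05),
        )
        assert cands[0].called
        assert "conserved" not in cands[1].flags and not cands[1].called

    def test_no_activators_is_an_error(self):
        aln, phen = _toy_alignment_and_phenotypes()
        phen = {rid: PhenotypeLabel(rid, 0) for rid in phen}
        with pytest.raises(ValueError, match="activator"):
            call_morf_candidates([], {}, aln, phen)

    def test_row_order_permutation_leaves_calls_unchanged(self, default_family):
        from mybslim import pipeline as pl

        fam = default_family
        res1 = pl.run_pipeline_objects(
            fam.proteins, fam.cds, fam.alignment, fam.seed_alignment, fam.phenotypes
        )
        shuffled = MultipleAlignment(list(reversed(fam.alignment.rows)), "protein")
        res2 = pl.run_pipeline_objects(
            list(reversed(fam.proteins)), fam.cds, shuffled,
            fam.seed_alignment, fam.phenotypes,
        )
        assert [c.called for c in res1.candidates] == [c.called for c in res2.candidates]
        assert res1.summary["windows"] == res2.summary["windows"]

    def test_gappy_rows_abstain_from_spans(self):
        rows = [("a", "AAAAAAAA"), ("b", "AA----AA"), ("c", "AAAAAAAA")]
        aln = MultipleAlignment(rows, "protein")
        spans = window_spans_by_record(
            ConservedWindow(2, 6, 1.0, "W"), aln, max_gap_fraction=0.5
        )
        assert "b" not in spans and spans["a"] == (2, 6)


class TestDivergence:
    def test_identical_region_has_no_mismatches(self):
        rep = divergence_to_consensus("RPQPRIFM", "RPQPRIFM")
        assert rep.mismatch_count == 0

    def test_single_substitution_located(self):
        rep = divergence_to_consensus("RPQPKIFM", "RPQPRIFM")
        assert rep.mismatch_positions == (5,)

    def test_gap_counts_as_mismatch(self):
        rep = divergence_to_consensus("RP-PRIFM", "RPQPRIFM")
        assert rep.mismatch_positions == (3,)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            divergence_to_consensus("RPQ", "RPQP")

    def test_nonactivators_diverge_more_than_activators(self, default_family):
        """Planted divergence: non-activators drift from the activator
        consensus at every motif."""
        fam = default_family
        window = ConservedWindow(0, 0, 1.0, "S6A")
        span = fam.manifest.records["ACT00"]["motif_spans"]["S6A"]
        window = ConservedWindow(span[0], span[1], 1.0, "S6A")
        cons = activator_consensus(fam.alignment, window, fam.phenotypes)
        act_counts, non_counts = [], []
        for rid, seq in fam.alignment.rows:
            region = seq[window.start_col : window.end_col]
            n = divergence_to_consensus(region, cons, rid, "S6A").mismatch_count
            (act_counts if fam.phenotypes[rid].activator else non_counts).append(n)
        assert np.mean(non_counts) > np.mean(act_counts)


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_divergence_count_matches_position_list(seed):
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    a = "".join(rng.choice(aas, 12))
    b = "".join(rng.choice(aas, 12))
    rep = divergence_to_consensus(a, b)
    assert rep.mismatch_count == sum(x != y for x, y in zip(a, b))
    assert all(a[p - 1] != b[p - 1] for p in rep.mismatch_positions)
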