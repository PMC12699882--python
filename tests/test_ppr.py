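import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitoscope.io_formats import DomainHit, ProteinRecord, StructureTrack
from mitoscope import ppr
from mitoscope.ppr import (ConfusionCounts, HitLabel, MotifReference,
                           PprConfig)


def hit(pid, start, end, e, profile="plant_P_type"):
    return DomainHit(pid, profile, start, end, i_evalue=e)


# ---------------------------------------------------------------------------
# precision / recall / F1

class TestPrecisionRecallF1:
    def test_perfect_separation(self):
        prf = ppr.precision_recall_f1(ConfusionCounts(79, 0, 0))
        assert (prf.precision, prf.recall, prf.f1) == (1.0, 1.0, 1.0)

    def test_formula_oracle(self):
        prf = ppr.precision_recall_f1(ConfusionCounts(60, 20, 20))
        assert prf.precision == pytest.approx(0.75)
        assert prf.recall == pytest.approx(0.75)
        assert prf.f1 == pytest.approx(60 / 80)

    def test_all_zero_is_undefined(self):
        prf = ppr.precision_recall_f1(ConfusionCounts(0, 0, 0))
        assert prf.precision is None and prf.recall is None \
            and prf.f1 is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)

    @given(tp=st.integers(1, 500), fp=st.integers(0, 500),
           fn=st.integers(0, 500))
    def test_f1_is_harmonic_mean_of_p_and_r(self, tp, fp, fn):
        prf = ppr.precision_recall_f1(ConfusionCounts(tp, fp, fn))
        harmonic = (2 * prf.precision * prf.recall
                    / (prf.precision + prf.recall))
        assert prf.f1 == pytest.approx(harmonic)


# ---------------------------------------------------------------------------
# reference matching

REF = MotifReference(
    positive_motifs=(("p1", (11, 46)),),
    negative_motifs=(("p2", (0, 35)),),
)


class TestMatchHitsToReference:
    def test_majority_overlap_is_tp_candidate(self):
        (lh,) = ppr.match_hits_to_reference([hit("p1", 9, 44, 1.0)], REF)
        assert lh.label is HitLabel.TP_CANDIDATE
        assert lh.overlap_fraction == pytest.approx(33 / 35)

    def test_no_overlap_is_unlabeled(self):
        (lh,) = ppr.match_hits_to_reference([hit("p1", 100, 135, 1.0)],
                                            REF)
        assert lh.label is HitLabel.UNLABELED

    def test_exact_negative_span_is_fp_candidate(self):
        (lh,) = ppr.match_hits_to_reference([hit("p2", 0, 35, 1.0)], REF)
        assert lh.label is HitLabel.FP_CANDIDATE

    def test_below_min_overlap_is_unlabeled(self):
        (lh,) = ppr.match_hits_to_reference([hit("p1", 30, 65, 1.0)], REF)
        assert lh.overlap_fraction == 0.0
        assert lh.label is HitLabel.UNLABELED


# ---------------------------------------------------------------------------
# threshold selection

def labeled_instance(pos_evalues, neg_evalues):
    """One reference motif per e-value, each matched by exactly one hit."""
    ref = MotifReference(
        positive_motifs=tuple((f"P{k}", (0, 35))
                              for k in range(len(pos_evalues))),
        negative_motifs=tuple((f"N{k}", (0, 35))
                              for k in range(len(neg_evalues))),
    )
    hits = [hit(f"P{k}", 0, 35, e) for k, e in enumerate(pos_evalues)]
    hits += [hit(f"N{k}", 0, 35, e) for k, e in enumerate(neg_evalues)]
    return ppr.match_hits_to_reference(hits, ref), ref


def bruteforce_select(pos_evalues, neg_evalues, thresholds):
    """Exhaustive oracle over the same candidate grid."""
    best = None
    rows = []
    for t in sorted(set(thresholds)):
        tp = sum(e < t for e in pos_evalues)
        fp = sum(e < t for e in neg_evalues)
        fn = len(pos_evalues) - tp
        f1 = tp / (tp + 0.5 * (fp + fn)) if tp + fp + fn else None
        rows.append((t, tp, fp, fn, f1))
    perfect = [t for t, tp, fp, fn, _ in rows if fp == 0 and fn == 0]
    if perfect:
        return max(perfect)
    best_f1 = max(f1 for *_, f1 in rows if f1 is not None)
    return max(t for t, *_, f1 in rows if f1 == best_f1)


class TestSelectThreshold:
    def test_separable_picks_largest_clean_threshold(self):
        labeled, ref = labeled_instance([0.5, 2.0, 4.9], [150.0, 900.0])
        cal = ppr.select_threshold(labeled, ref,
                                   candidate_thresholds=[1, 5, 8.6, 50,
                                                         200])
        assert cal.selected_threshold == 50
        assert cal.perfect_separation

    def test_single_pair_threshold_lies_between(self):
        labeled, ref = labeled_instance([2.0], [40.0])
        cal = ppr.select_threshold(labeled, ref)
        assert 2.0 < cal.selected_threshold <= 40.0
        assert cal.perfect_separation

    def test_inseparable_falls_back_to_max_f1(self):
        rng = np.random.default_rng(3)
        pos = list(10.0 ** rng.uniform(-3, 2, 40))
        neg = list(10.0 ** rng.uniform(-1, 4, 60))
        labeled, ref = labeled_instance(pos, neg)
        cal = ppr.select_threshold(labeled, ref)
        expected = bruteforce_select(pos, neg, cal.thresholds_evaluated)
        assert not cal.perfect_separation
        assert cal.selected_threshold == pytest.approx(expected)

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = list(10.0 ** rng.uniform(-6, 3, rng.integers(1, 30)))
        neg = list(10.0 ** rng.uniform(-2, 6, rng.integers(1, 30)))
        labeled, ref = labeled_instance(pos, neg)
        cal = ppr.select_threshold(labeled, ref)
        expected = bruteforce_select(pos, neg, cal.thresholds_evaluated)
        assert cal.selected_threshold == pytest.approx(expected)

    def test_counts_monotone_in_threshold(self):
        labeled, ref = labeled_instance([0.1, 1.0, 5.0], [3.0, 80.0])
        cal = ppr.select_threshold(labeled, ref)
        tab = cal.table.sort_values("threshold")
        assert tab.tp.is_monotonic_increasing
        assert tab.fp.is_monotonic_increasing

    def test_unmatched_positive_is_fn_everywhere(self):
        labeled, ref = labeled_instance([1.0], [50.0])
        ref2 = MotifReference(
            positive_motifs=ref.positive_motifs + (("lost", (0, 35)),),
            negative_motifs=ref.negative_motifs)
        cal = ppr.select_threshold(labeled, ref2)
        assert not cal.perfect_separation
        assert (cal.table.fn >= 1).all()


# ---------------------------------------------------------------------------
# gap candidates

class TestFindGapCandidates:
    def test_flanked_gap_region_arithmetic(self):
        # motifs ending at residue 100 and starting at 136 (1-based):
        # gap of 35 residues, region 91..145
        spans = [(65, 100), (135, 170)]  # internal half-open
        (region,) = ppr.find_gap_candidates(spans, protein_length=300)
        assert region == (90, 145)  # == 1-based 91..145

    def test_short_gap_ignored(self):
        spans = [(0, 35), (64, 99)]  # gap 29
        assert ppr.find_gap_candidates(spans, 300) == []

    def test_terminal_gap_needs_two_flanking_motifs(self):
        spans = [(35, 70)]  # nothing upstream of the gap at the start
        assert ppr.find_gap_candidates(spans, 300) == []

    def test_overlapping_motifs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ppr.find_gap_candidates([(0, 35), (30, 65)], 300)

    def test_region_clipped_to_protein(self):
        spans = [(0, 10), (45, 80)]
        (region,) = ppr.find_gap_candidates(spans, protein_length=50)
        assert region == (0, 50)

    @given(gap=st.integers(30, 40), flank=st.integers(0, 15))
    def test_region_bounds_property(self, gap, flank):
        spans = [(50, 85), (85 + gap, 120 + gap)]
        (region,) = ppr.find_gap_candidates(spans, 1000, flank=flank)
        assert region[0] == 85 - flank
        assert region[1] == 85 + gap + flank


# ---------------------------------------------------------------------------
# structure validation

def track(labels, pid="p1"):
    return StructureTrack(pid, labels)


class TestValidateStructure:
    def test_canonical_helix_turn_helix(self):
        labels = "H" * 10 + "TTT" + "H" * 18  # length 31
        motif = ppr.validate_structure((0, 31), track(labels))
        assert motif.structure_valid
        assert motif.structure.helix_a_count == 10
        assert motif.structure.helix_b_count == 18

    def test_helix_a_below_seven_fails(self):
        labels = "H" * 6 + "CCCC" + "TTT" + "H" * 18
        motif = ppr.validate_structure((0, 31), track(labels))
        assert not motif.structure_valid
        assert motif.structure.helix_a_count == 6

    def test_turn_must_sit_at_positions_11_to_13(self):
        labels = "H" * 11 + "TTT" + "H" * 17  # turn at 12-14
        motif = ppr.validate_structure((0, 31), track(labels))
        assert not motif.structure_valid
        assert not motif.structure.turn_ok

    def test_g_and_i_count_as_helix_forming(self):
        labels = "HGIHGIH" + "CCC" + "TTT" + "GIHGIHG" + "C" * 11
        motif = ppr.validate_structure((0, 31), track(labels))
        assert motif.structure_valid

    def test_invariant_to_labels_outside_span(self):
        inner = "H" * 10 + "TTT" + "H" * 18
        for context in ("C" * 20, "E" * 20, "T" * 20):
            motif = ppr.validate_structure(
                (20, 51), track(context + inner + context))
            assert motif.structure_valid

    def test_span_outside_track_is_error(self):
        with pytest.raises(ValueError, match="track"):
            ppr.validate_structure((0, 31), track("H" * 20))

    def test_length_outside_range_is_error(self):
        with pytest.raises(ValueError, match="length"):
            ppr.validate_structure((0, 30), track("H" * 100))


# ---------------------------------------------------------------------------
# profile construction

class TestBuildProfile:
    MOTIF35 = "VVYNTLIDGLCKAGRVDEAMELFREMKEKGIKPDV"

    def test_two_identical_motifs_pseudocount_arithmetic(self):
        prof = ppr.build_profile([self.MOTIF35, self.MOTIF35])
        assert prof.consensus == self.MOTIF35
        j = 0
        idx = ppr.AA_INDEX[self.MOTIF35[0]]
        assert prof.probabilities[j, idx] == \
            pytest.approx((2 + 0.5) / (2 + 20 * 0.5))

    def test_mixed_length_classes_use_longest(self):
        prof = ppr.build_profile([self.MOTIF35[:31], self.MOTIF35])
        assert prof.length == 35
        assert prof.alignment[0].endswith("----")

    def test_single_motif_is_error(self):
        with pytest.raises(ValueError, match="two"):
            ppr.build_profile([self.MOTIF35])

    def test_length_out_of_range_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            ppr.build_profile([self.MOTIF35, self.MOTIF35 + "AAAAAA"])

    def test_probability_rows_sum_to_one(self):
        prof = ppr.build_profile([self.MOTIF35, self.MOTIF35[:31]])
        assert np.allclose(prof.probabilities.sum(axis=1), 1.0)

    def test_alignment_exports_parse(self, tmp_path):
        from Bio import AlignIO
        prof = ppr.build_profile([self.MOTIF35, self.MOTIF35])
        sto = tmp_path / "a.sto"
        fasta = tmp_path / "a.afa"
        ppr.write_stockholm(prof, sto)
        ppr.write_alignment_fasta(prof, fasta)
        assert len(AlignIO.read(str(sto), "stockholm")) == 2
        assert len(AlignIO.read(str(fasta), "fasta")) == 2


# ---------------------------------------------------------------------------
# internal scanner

@pytest.fixture(scope="module")
def profile():
    rng = np.random.default_rng(0)
    variants = []
    for _ in range(20):
        s = list(TestBuildProfile.MOTIF35)
        for j in rng.integers(0, 35, size=3):
            s[j] = ppr.AA_ORDER[rng.integers(0, 20)]
        variants.append("".join(s))
    return ppr.build_profile(variants)


class TestScanWithProfile:
    MOTIF = TestBuildProfile.MOTIF35

    def test_consensus_window_scores_highest(self, profile):
        rng = np.random.default_rng(1)
        flank = "".join(ppr.AA_ORDER[i]
                        for i in rng.integers(0, 20, size=60))
        seq = flank + profile.consensus + flank
        enc = ppr._encode(seq)
        scores = ppr._window_scores(enc, profile.log_odds)
        assert int(np.argmax(scores)) == 60

    def test_planted_motif_recovered_with_small_evalue(self, profile):
        rng = np.random.default_rng(2)
        flank = "".join(ppr.AA_ORDER[i]
                        for i in rng.integers(0, 20, size=100))
        rec = ProteinRecord("x", flank + self.MOTIF + flank)
        hits = ppr.scan_with_profile(profile, [rec], null_decoys=50,
                                     seed=3)
        assert any(h.start == 100 and h.i_evalue <= 1 for h in hits)

    def test_shuffled_decoy_scores_near_null_expectation(self, profile):
        """A hit's empirical E-value on its own shuffled decoy is, by
        construction, about the null expectation at that score."""
        rng = np.random.default_rng(4)
        seq = "".join(ppr.AA_ORDER[i]
                      for i in rng.integers(0, 20, size=300))
        rec = ProteinRecord("x", seq)
        hits = ppr.scan_with_profile(profile, [rec], null_decoys=100,
                                     seed=5, score_floor=-1e9)
        # every reported window on a random sequence has a large E-value
        assert hits and min(h.i_evalue for h in hits) >= 0.01
        evalues = sorted(h.i_evalue for h in hits)
        assert evalues[len(evalues) // 2] > 0.5

    def test_short_protein_skipped(self, profile):
        rec = ProteinRecord("tiny", "MKR")
        assert ppr.scan_with_profile(profile, [rec], null_decoys=10,
                                     seed=0) == []

    def test_empty_proteome(self, profile):
        assert ppr.scan_with_profile(profile, [], null_decoys=10,
                                     seed=0) == []


# ---------------------------------------------------------------------------
# full pipeline plumbing

class TestIterateDiscovery:
    def test_supplied_thresholds_skip_calibration(self, small_data):
        tracks = {t.protein_id: t for t in small_data.tracks}
        res = ppr.iterate_discovery(
            small_data.proteins, small_data.hits, ref=None, tracks=tracks,
            config=PprConfig(threshold1=8.6, threshold2=11,
                             null_decoys=20))
        assert res.threshold1 == 8.6 and res.threshold2 == 11
        assert res.calibration1 is None and res.calibration2 is None

    def test_no_structure_tracks_degrades_gracefully(self, small_data):
        res = ppr.iterate_discovery(
            small_data.proteins, small_data.hits,
            ref=small_data.motif_reference, tracks=None,
            config=PprConfig(null_decoys=20))
        assert "gap_rescue_skipped_no_structure_tracks" in res.flags
        assert res.rescued_motifs == []
        assert res.final_motifs  # pipeline still completes

    def test_neither_reference_nor_threshold_is_error(self, small_data):
        with pytest.raises(ValueError, match="reference or threshold"):
            ppr.iterate_discovery(small_data.proteins, small_data.hits)

    def test_external_second_hits_preferred(self, small_data):
        tracks = {t.protein_id: t for t in small_data.tracks}
        second = [hit("SYN_00001", 0, 35, 1e-6, profile="dipl")]
        res = ppr.iterate_discovery(
            small_data.proteins, small_data.hits, tracks=tracks,
            config=PprConfig(threshold1=8.6, threshold2=11),
            second_hits=second)
        assert "iteration2_internal_scanner" not in res.flags
        assert [m.span for m in res.final_motifs] == [(0, 35)]
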