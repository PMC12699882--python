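import dataclasses

import pytest

from mitoscope import io_formats as iof
from mitoscope import locpred, ms_enrichment, ppr, synth
from conftest import SMALL_SYNTH


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synth.write_all(synth.generate_all(SMALL_SYNTH), d1)
        synth.write_all(synth.generate_all(SMALL_SYNTH), d2)
        for name in ("proteome.fasta", "predictors.tsv",
                     "plant_ppr_hits.domtblout", "structures.tsv",
                     "quant.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seed_differs(self):
        a = synth.generate_all(SMALL_SYNTH)
        b = synth.generate_all(
            dataclasses.replace(SMALL_SYNTH, seed=SMALL_SYNTH.seed + 1))
        assert a.proteins != b.proteins


class TestEmittedFilesAreValid:
    def test_round_trip_through_validators(self, tmp_path, small_data):
        paths = synth.write_all(small_data, tmp_path)
        proteins = iof.read_fasta(paths["fasta"])
        assert proteins == small_data.proteins
        rows = iof.read_predictor_table(
            paths["predictors"],
            small_data.config.norm_constant_tertiary)
        assert len(rows) == len(small_data.predictor_rows)
        hits = iof.read_domtblout(paths["domtblout"])
        assert len(hits) == len(small_data.hits)
        tracks = iof.read_structure_table(paths["structures"])
        by_id = {p.id: p for p in proteins}
        for t in tracks:
            assert len(t.labels) == by_id[t.protein_id].length
        quants = iof.read_quant_table(paths["quant"])
        assert len(quants) == len(small_data.quants)
        truth = synth.GroundTruth.from_json(paths["truth"])
        assert truth.ppr_motifs == small_data.truth.ppr_motifs


class TestProteomeTruthConsistency:
    def test_planted_spans_ordered_and_disjoint(self, small_data):
        for spans in small_data.truth.ppr_motifs.values():
            assert spans == sorted(spans)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_no_ppr_proteins_means_no_truth_spans(self):
        cfg = dataclasses.replace(SMALL_SYNTH, n_ppr_proteins=0)
        proteins, truth = synth.make_proteome(cfg)
        assert truth.ppr_motifs == {}
        with pytest.raises(ValueError, match="reference sizes"):
            synth.make_motif_reference(cfg, truth)

    def test_cx9c_proteins_carry_expected_twins(self, small_data):
        from mitoscope import motif_scan
        by_id = {p.id: p for p in small_data.proteins}
        found = 0
        for pid, n in small_data.truth.cx9c_proteins.items():
            call = motif_scan.scan_cx9c(by_id[pid])
            if len(call.motifs) == n:
                found += 1
        assert found >= 0.95 * len(small_data.truth.cx9c_proteins)

    def test_ak_proteins_pass_composition_screen(self, small_data):
        from mitoscope import motif_scan
        by_id = {p.id: p for p in small_data.proteins}
        for pid in small_data.truth.ak_proteins:
            assert motif_scan.ak_composition_screen(by_id[pid]).flagged

    def test_motif_sequences_resemble_consensus(self, small_data):
        by_id = {p.id: p for p in small_data.proteins}
        for pid, spans in small_data.truth.ppr_motifs.items():
            for s, e in spans:
                seq = by_id[pid].sequence[s:e]
                matches = sum(a == b for a, b in
                              zip(seq, synth.PPR_CONSENSUS))
                assert matches >= 0.6 * (e - s)


class TestPredictorTable:
    def test_all_nonmito_concentrates_wa_at_zero(self):
        cfg = dataclasses.replace(SMALL_SYNTH, fraction_mito=0.0,
                                  n_proteins=1000, n_ppr_proteins=0,
                                  n_decoy_proteins=0, n_cx9c_proteins=0,
                                  n_ak_proteins=0)
        _, truth = synth.make_proteome(cfg)
        rows = synth.make_predictor_table(cfg, truth)
        calls = [locpred.wa_score(r) for r in rows]
        zero_rate = sum(c.wa_score == 0 for c in calls) / len(calls)
        assert zero_rate > 0.9

    def test_degenerate_distributions_separate_perfectly(self):
        cfg = dataclasses.replace(SMALL_SYNTH,
                                  mito_beta=(5000.0, 1e-3),
                                  nonmito_beta=(1e-3, 5000.0),
                                  tool_correlation_kappa=5000.0)
        _, truth = synth.make_proteome(cfg)
        rows = synth.make_predictor_table(cfg, truth)
        for r in rows:
            call = locpred.wa_score(r)
            if truth.mito[r.protein_id]:
                assert call.band is locpred.Band.ALMOST_CERTAINLY
            else:
                assert call.band is locpred.Band.NON_MITOCHONDRIAL


class TestHitsAndStructures:
    def test_omitted_motifs_are_interior_and_bookkept(self, small_data):
        truth = small_data.truth
        hit_spans = {(h.protein_id, h.span) for h in small_data.hits}
        for pid, span in truth.omitted_motifs:
            assert (pid, span) not in hit_spans
            spans = truth.ppr_motifs[pid]
            k = spans.index(span)
            assert 0 < k < len(spans) - 1

    def test_noise_free_motifs_all_validate(self):
        cfg = dataclasses.replace(SMALL_SYNTH, structure_noise=0.0)
        proteins, truth = synth.make_proteome(cfg)
        _, tracks = synth.make_hits_and_structs(cfg, proteins, truth)
        by_id = {t.protein_id: t for t in tracks}
        for pid, spans in truth.ppr_motifs.items():
            for span in spans:
                motif = ppr.validate_structure(span, by_id[pid])
                assert motif.structure_valid

    def test_full_noise_validation_near_chance(self):
        cfg = dataclasses.replace(SMALL_SYNTH, structure_noise=1.0)
        proteins, truth = synth.make_proteome(cfg)
        _, tracks = synth.make_hits_and_structs(cfg, proteins, truth)
        by_id = {t.protein_id: t for t in tracks}
        n = valid = 0
        for pid, spans in truth.ppr_motifs.items():
            for span in spans:
                n += 1
                valid += ppr.validate_structure(span,
                                                by_id[pid]).structure_valid
        # the three-consecutive-turn criterion alone has chance (1/8)^3
        assert valid / n < 0.05

    def test_decoy_motifs_fail_validation(self):
        cfg = dataclasses.replace(SMALL_SYNTH, structure_noise=0.0)
        proteins, truth = synth.make_proteome(cfg)
        _, tracks = synth.make_hits_and_structs(cfg, proteins, truth)
        by_id = {t.protein_id: t for t in tracks}
        for pid, spans in truth.decoy_motifs.items():
            for span in spans:
                assert not ppr.validate_structure(
                    span, by_id[pid]).structure_valid

    def test_evalue_classes_are_separable(self, small_data):
        true_spans = {(pid, s)
                      for pid, v in small_data.truth.ppr_motifs.items()
                      for s in v}
        true_es = [h.i_evalue for h in small_data.hits
                   if (h.protein_id, h.span) in true_spans]
        decoy_es = [h.i_evalue for h in small_data.hits
                    if (h.protein_id, h.span) not in true_spans]
        assert max(true_es) < min(decoy_es)


class TestQuantTable:
    def test_unit_factors_detect_nothing(self):
        cfg = dataclasses.replace(SMALL_SYNTH, enrich_mito_factor=1.0,
                                  enrich_cyto_factor=1.0,
                                  quant_noise_sigma=0.0,
                                  whole_cell_dropout=0.0,
                                  in_complex_rate=0.0)
        _, truth = synth.make_proteome(cfg)
        quants = synth.make_quant_table(cfg, truth)
        floors = {m: ms_enrichment.compute_floors(quants, m)
                  for m in ms_enrichment.METRICS}
        detected = [ms_enrichment.combined_call(q, floors).detected
                    for q in quants]
        assert sum(detected) / len(detected) < 0.05  # Poisson noise only

    def test_noise_free_recall_and_precision_are_perfect(self):
        cfg = dataclasses.replace(SMALL_SYNTH, quant_noise_sigma=0.0,
                                  whole_cell_dropout=0.0,
                                  base_spectral_counts=1e4,
                                  in_complex_rate=0.0)
        _, truth = synth.make_proteome(cfg)
        quants = synth.make_quant_table(cfg, truth)
        floors = {m: ms_enrichment.compute_floors(quants, m)
                  for m in ms_enrichment.METRICS}
        for q in quants:
            call = ms_enrichment.combined_call(q, floors)
            assert call.detected == truth.enriched[q.protein_id]

    def test_dropout_exercises_floor_rule(self, default_data):
        substituted = [q for q in default_data.quants
                       if q.ion_intensities["whole_cell"] == 0.0]
        assert substituted  # the floor path is actually exercised
        for q in substituted:
            assert default_data.truth.enriched[q.protein_id]
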