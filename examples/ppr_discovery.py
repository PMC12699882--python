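"""Two-iteration, F1-calibrated PPR-motif discovery on synthetic data.

Generates a small proteome with planted PPR arrays, decoy (TPR-like)
repeats and a curated motif reference, then runs: threshold calibration
on the generic-profile hits, gap rescue with helix-turn-helix structure
validation, lineage-specific profile construction, and a second search
with the built-in scanner.
"""

from mitoscope import ppr, synth

cfg = synth.SynthConfig(
    n_proteins=200, n_ppr_proteins=15, n_decoy_proteins=60,
    n_cx9c_proteins=4, n_ak_proteins=4,
    protein_ref_sizes=(40, 40), motif_ref_sizes=(30, 200), seed=11,
)
data = synth.generate_all(cfg)
tracks = {t.protein_id: t for t in data.tracks}

result = ppr.iterate_discovery(
    data.proteins, data.hits,
    ref=data.motif_reference, tracks=tracks,
    config=ppr.PprConfig(null_decoys=50, seed=cfg.seed),
)

cal1 = result.calibration1
print(f"iteration 1: calibrated i-E-value threshold = "
      f"{result.threshold1:.3g} "
      f"(perfect separation: {cal1.perfect_separation}) -> "
      f"{len(result.iter1_motifs)} motifs")
print(f"gap rescue: {len(result.rescued_motifs)} motifs recovered from "
      f"30-40 residue gaps and validated by the helix-turn-helix "
      f"criteria")
print(f"profile: {result.profile.length}-column position-specific "
      f"scoring profile from "
      f"{len(result.profile.alignment)} aligned motifs")
print(f"iteration 2: threshold = {result.threshold2:.3g} -> "
      f"{len(result.final_motifs)} final motifs in "
      f"{len(result.ppr_proteins)} proteins")

truth = set(data.truth.ppr_motifs)
called = result.ppr_proteins
print(f"\nplanted PPR proteins recovered: "
      f"{len(truth & called)}/{len(truth)}; "
      f"decoy-repeat proteins wrongly called: "
      f"{len(set(data.truth.decoy_motifs) & called)}")
counts = sorted(result.motif_counts().values(), reverse=True)
print(f"motifs per called protein (top 5): {counts[:5]} — tandem arrays "
      f"of up to ~11 repeats, as expected for this family")
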