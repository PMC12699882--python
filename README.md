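# mitoscope

Computational screens for inferring a mitochondrial proteome from a
diplonemid (e.g. *Diplonema papillatum*) protein catalogue: ensemble
scoring of mitochondrial targeting predictions, mass-spectrometry
enrichment classification across subcellular fractions, deterministic
sequence screens (twin-Cx9C motifs, Ala/Lys composition, Pfam-style
domain-table filtering), and an iterative, F1-calibrated pipeline for
discovering pentatricopeptide-repeat (PPR) motifs — the RNA-binding
repeats implicated in the fragmented-gene RNA metabolism of diplonemid
mitochondria.

The package is a library first (`import mitoscope`), with short narrative
scripts under `examples/` and a thin `mitoscope` command-line wrapper.
A synthetic-data module generates every pipeline input with known ground
truth, so the whole analysis runs and is validated without any downloads.

## The methods

**Localization ensemble.** Three subcellular-localization predictors are
combined into a weighted-average mitochondrion score per protein

    WA = (2.5 · s_MULocDeep + 1.5 · s̃_WoLFPSORT + 6 · s_DeepLoc2) / 10

where `s̃_WoLFPSORT = min(1, raw/c)` normalizes the unbounded third score.
The best tool's categorical call dominates: if it assigns the protein to
the mitochondrion the raw WA stands; if only the second-best tool does,
WA is downgraded ×0.25 (landing in (0, 0.25)); if both reject, WA ≡ 0.
Scores bin into confidence bands — non-mitochondrial (0), low probability
(0, 0.25), likely [0.25, 0.5), very likely [0.5, 0.75), almost certainly
[0.75, 1] — whose likelihood ratios (mitochondrial : non-mitochondrial)
are calibrated from curated positive/negative reference proteins.

**MS enrichment.** For each protein, mitochondrial and cytosolic
quantities (spectral counts or ion intensities) are divided by the
whole-cell quantity (or by the dataset's minimal non-zero value when the
protein is absent from the whole-cell lysate). The protein is *detected
in mitochondria* when mito:whole > cyto:whole and mito:whole > 1.5, or
when it was identified in purified mitochondrial complexes. iBAQ
(intensity over the count of observable fully tryptic 7–30-mers) is the
abundance metric.

**PPR discovery.** Hits of generic PPR profiles are filtered at an
i-E-value threshold chosen as the largest cutoff retrieving every
expert-curated positive reference motif and no negative (TPR/Ankyrin)
one, falling back to the max-F1 cutoff (`F1 = TP/(TP + (FP+FN)/2)`) when
perfect separation is impossible. Motifs missed inside 30–40-residue
gaps between assigned motifs are rescued if their secondary structure
shows two helices of ≥ 7 helix-forming residues (H/G/I) around three
consecutive turn residues at motif positions 11–13. The enlarged motif
set is aligned into a lineage-specific position-probability profile, and
a second search (external hmmsearch tables, or the built-in log-odds
scanner with shuffled-decoy empirical E-values) is filtered at a second
calibrated threshold. A protein is PPR-containing when it retains ≥ 1
final motif.

## Worked example

`python examples/ppr_discovery.py` plants 15 PPR-motif arrays among 200
synthetic proteins (with 60 decoy-repeat proteins and a curated motif
reference) and runs the full two-iteration discovery:

```
iteration 1: calibrated i-E-value threshold = 100 (perfect separation: True) -> 91 motifs
gap rescue: 13 motifs recovered from 30-40 residue gaps and validated by the helix-turn-helix criteria
profile: 35-column position-specific scoring profile from 104 aligned motifs
iteration 2: threshold = 0.04 -> 105 final motifs in 15 proteins

planted PPR proteins recovered: 15/15; decoy-repeat proteins wrongly called: 0
motifs per called protein (top 5): [11, 11, 11, 9, 9] — tandem arrays of up to ~11 repeats
```

The calibrated threshold separates the planted (true) i-E-value class
from the decoy class perfectly; gap rescue recovers the motifs that were
deliberately withheld from the hit table; and the second search with the
diplonemid-style profile recalls every planted array while calling no
decoy protein. The other example scripts demonstrate localization
scoring with band-odds calibration, enrichment calls with the
zero-divisor floor, the sequence screens, and the end-to-end pipeline
(`run_all`) that joins all evidence into a per-protein annotation table.

## Command line

```sh
mitoscope synth --outdir data/           # synthetic benchmark with truth
mitoscope locscore --predictors data/predictors.tsv --out loc.tsv
mitoscope enrich --quant data/quant.tsv --out enrich.tsv
mitoscope scan --fasta data/proteome.fasta --out screens.tsv
mitoscope ppr --fasta data/proteome.fasta --domtbl1 data/plant_ppr_hits.domtblout \
    --ref-pos data/ref_motifs_positive.tsv --ref-neg data/ref_motifs_negative.tsv \
    --structs data/structures.tsv --out-motifs motifs.tsv
mitoscope all --config config.yaml --outdir out/
```

## Layout

- `src/mitoscope/io_formats.py` — FASTA / HMMER3 domtblout / TSV readers
  and writers; 1-based inclusive coordinates at every file boundary,
  0-based half-open in memory
- `src/mitoscope/locpred.py` — WA ensemble, bands, odds calibration
- `src/mitoscope/ms_enrichment.py` — enrichment rule, floors, iBAQ
- `src/mitoscope/motif_scan.py` — twin-Cx9C, Ala/Lys, domain filtering
- `src/mitoscope/ppr.py` — calibration, gap rescue, structure
  validation, profile building, internal scanner, iterative discovery
- `src/mitoscope/synth.py` — ground-truthed synthetic data generator
- `src/mitoscope/pipeline.py`, `src/mitoscope/cli.py` — end-to-end run,
  report, command-line wrapper

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
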