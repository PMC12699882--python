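# Methods

This note documents the models, rules and numerical choices implemented
in `mitoscope`, the defaults behind them, and what the synthetic
benchmark does and does not establish.

## Coordinates

Every external file uses 1-based inclusive residue coordinates (the
HMMER convention); everything in memory is 0-based half-open. The
conversion happens only in `io_formats`, so span lengths are preserved
exactly and the gap arithmetic of the PPR pipeline needs no off-by-one
corrections. Non-standard residue codes (B, Z, U, O, J) are mapped to X
on read; X counts toward length and composition denominators, which
keeps the composition screens deterministic.

## Localization ensemble

The weighted average

    WA = (2.5 · s_secondary + 1.5 · s̃_tertiary + 6 · s_primary) / 10

weights the three predictors by their performance on curated reference
proteins; the primary (DeepLoc2-style) predictor carries most of the
weight and its categorical assignment decides the regime: raw WA when it
assigns the protein to the mitochondrion, ×0.25 (multiplicative, no
clamping — penalized scores therefore lie in (0, 0.25)) when only the
secondary (MULocDeep-style) tool assigns it, and WA ≡ 0 when both
reject. The tertiary (WoLF PSORT-style) score is unbounded and is
normalized by a user-supplied constant `c` with `min(1, raw/c)`; the
constant is a required parameter of the reader because no universal
value exists — the default used throughout the package is 28, the
approximate maximum of that tool's score scale in our emulation.

Band edges are 0.25 / 0.5 / 0.75 with half-open intervals
`[lower, upper)` and the top band closed at 1. Two interval readings
circulate for these bands (0.25–0.49 vs 0.2–0.5 etc.); the edges here
follow the classifier's operating definition, are configurable in
`EnsembleConfig`, and the half-open convention closes the apparent gaps
at 0.49–0.5 and 0.74–0.75. The boundary point 0.75 belongs to the top
band.

Band odds are raw band-conditional rate ratios over the positive and
negative reference sets — no smoothing, no pseudocounts. A band with
positives but no negatives reports infinite odds; a band containing no
reference protein reports *undefined* rather than a fabricated number.
This mirrors how such likelihoods are reported in practice (8:1, 27:1,
1:41-style figures) and keeps the calibration auditable.

Candidate selection takes every protein at or above a minimum band
(default: very likely) plus explicit overrides; each override must carry
a free-text justification and refer to a scored protein, mirroring how
low-scoring proteins are admitted on direct experimental evidence.

## MS enrichment

The rule operates per metric (spectral counts, ion intensities) on the
three fractions whole cell / cytosol / mitochondria:

1. divisor = whole-cell value, or the dataset's minimal non-zero value
   for that metric when the whole-cell value is 0 (recorded as
   `divisor_substituted`);
2. detected ⇔ mito/divisor > cyto/divisor and mito/divisor > 1.5
   (strict; equality at 1.5 is not detected), or the protein appears in
   the mitochondrial-complex (respirasome/mitoribosome) datasets.

When both metrics are available the combined verdict fires if either
metric passes — the per-metric verdicts remain available. Replicates
are assumed summed upstream of the table. The floor construction makes
the rule invariant under rescaling one metric's values by any positive
constant (exercised as a property test; exact boundary cases such as a
ratio of exactly 1.5 are excluded from that property because floating
point cannot preserve them under rescaling).

iBAQ divides summed precursor intensity by the count of fully tryptic
peptides of length 7–30 (cleavage after K/R, not before P, zero missed
cleavages, enumerated with `pyteomics`). This is the standard
reconstruction of the metric; a protein with no observable peptide
yields an undefined iBAQ rather than zero.

## Sequence screens

Twin-Cx9C scanning is greedy left-to-right for C·x9·C (and C·x10·C when
enabled, the Cox12-style variant; mixed 9/10 twins may chain). Motif
interiors may not contain cysteine — the canonical twin-disulfide
chemistry — and a candidate counts only when chained to a neighbour at a
spacer of 3–50 residues (bracketing the observed 5–38 range; both bounds
configurable). The scanner is verified against a regex brute-force
oracle on random sequences.

The Ala/Lys screen flags proteins whose A+K content strictly exceeds
60% and extracts the C-terminal 80-residue window for downstream
HMG-box-style tail matching by the generic profile machinery; the screen
itself is composition-only and permutation-invariant.

Domain-table filtering retains hits with i-E-value ≤ cutoff (default
0.05) and tabulates per-protein domain counts and the per-profile
"proteins with ≥ 1 domain" census; it is idempotent and
order-independent.

## PPR discovery

**Reference matching.** A hit is a true-positive candidate when it
overlaps a positive reference motif by ≥ 50% of the shorter interval
(false-positive candidate for negative-reference spans; larger overlap
wins when both apply, ties to the positive list). Reference motifs never
touched by any hit are false negatives at every threshold. Motif-level
(not protein-level) counting is used throughout.

**Threshold selection.** Retention is strict (`i_evalue < t`).
Candidate thresholds default to the distinct observed i-E-values plus
midpoints plus one value above the maximum, which contains the optimum
of any threshold rule that depends only on retained sets. The selected
threshold is the largest candidate with zero false positives and zero
false negatives; when no candidate separates perfectly the max-F1
candidate is chosen with ties toward the larger threshold (consistent
with preferring the most permissive clean cutoff). With strict
retention, the smallest negative e-value is itself a clean cutoff, so a
selected threshold equal to it is expected behaviour. The full
F1-vs-threshold table is retained for plotting and audit.

**Gap rescue.** Adjacent assigned motifs separated by a 30–40-residue
gap flank a candidate region: the gap extended by 10 residues on both
sides, clipped to the protein. Within the region, all windows of length
31–40 are tested against the structure criteria: helix A = motif
positions 1–10, three consecutive turn (T) residues at positions 11–13,
helix B = positions 14–end; each helix needs ≥ 7 helix-forming residues
(H/G/I in the 8-state alphabet), non-helical residues being permitted
inside helices. Among valid windows the one with maximal overlap with
the gap wins (the missed motif is expected to fill the gap — the flanks
exist to give structural context), then minimal overhang outside the
gap, then helix content, then position. Gaps at protein termini are not
candidates: rescue requires flanking motifs on both sides.

**Profile.** Validated motifs are grouped by length class (canonical
classes 31 and 35; accepted range 31–40) and merged onto the longest
class by C-terminal padding — an ungapped positional alignment, adequate
for repeats whose length classes differ by terminal truncation. Column
probabilities use a Laplace pseudocount α = 0.5 over the 20 standard
amino acids (gap and X positions do not count toward a column's total);
log-odds are natural-log ratios against a uniform background by default
(dataset-empirical background optional). The alignment is emitted in
aligned FASTA and Stockholm for external `hmmbuild`.

**Internal scanner.** When no external second-iteration search table is
supplied, the profile is slid over every window of profile length; a
window's score is its summed log-odds (X scores 0, i.e. background).
Hits above a score floor (default 0: better than background) are made
near-non-overlapping greedily by score, allowing up to 8 residues of
overlap between reported hits — tandem 31-residue motifs sit closer
together than a 35-column profile is long, so a strict non-overlap rule
would drop every second motif of a mixed-length array, while shifted
re-reports of the same motif (overlap near the profile length) must be
suppressed. The empirical E-value of score *s* is the count of windows
scoring ≥ s across 200 within-protein residue-shuffled copies of the
proteome, divided by 200 (i.e. the expected count in one null
proteome), floored at 1/200 — the resolution of the decoy ensemble —
so that E-values remain positive. The decoy count and the shuffle seed
are parameters; an external hmmsearch table is always preferred when
available. The scanner is a single-block position-specific scoring
model, not a Plan7 profile HMM: no insert/delete states, no forward
algorithm.

**Iteration order.** (1) threshold the generic-profile hits at the
first calibrated (or supplied) threshold; (2) rescue gap motifs by
structure; (3) build the lineage-specific profile from both sets; (4)
search again and filter at the second calibrated (or supplied)
threshold. Final motif calls and the per-protein "PPR-containing"
verdict come from the second iteration; every motif carries its source
(profile hit vs gap rescue) and iteration. Without structure tracks the
rescue stage is skipped and flagged; without either a reference or
explicit thresholds the pipeline refuses to run rather than guess.

## Synthetic benchmark

The generator emits every input the pipeline consumes, with ground
truth, under full determinism (each sub-generator draws from its own
seed-derived stream, so outputs are independent of call order).

Defaults encode the study conditions where they are stated: reference
sizes 469/482 proteins and 79/1,457 motifs, 247 decoy-repeat proteins,
2–11 motifs per planted array, motif length classes 31/35 (70% at 35),
Cx9C spacers 5–38, true vs decoy i-E-values log-uniform on
[1e-30, 1e-3] vs [1e2, 1e6], 5%-per-residue structure-label noise, MS
enrichment factors 5× (mitochondrial fraction) and 0.2× (cytosol).
The proteome size (1,200 proteins, 200–500-residue backgrounds) is a
desk-scale stand-in for a full proteome, chosen so the complete pipeline
and its validation run in seconds.

Choices the data do not dictate, made once:

- **Tool-correlated predictor scores.** The primary predictor's score
  is the protein's class-conditional Beta draw (Beta(8,2) mitochondrial,
  Beta(2,8) not); the other two tools score the *same protein*, so their
  scores are drawn around the primary's with concentration κ = 12.
  Independent per-tool draws would put essentially no genuine
  mitochondrial protein into the intermediate bands (a protein scoring
  0.8 with one tool would rarely score 0.4 with another), leaving the
  band-odds calibration nothing to calibrate; correlated tools reproduce
  the observed pattern of odds rising steadily across bands.
- **Positive motif reference = hit-bearing motifs.** Motifs
  deliberately omitted from the hit table (the gap-rescue targets) stay
  out of the positive reference, as a real expert reference built from
  retrieved motifs would; otherwise perfect-separation calibration would
  be impossible by construction.
- **Decoy repeats are column-shuffled consensus.** Same composition,
  scrambled positions: separable from true motifs by a positional
  profile yet non-trivial for calibration, standing in for TPR/Ankyrin
  confusions.
- **Whole-cell dropout only for enriched proteins** (10%): low-copy
  mitochondrial proteins fall below detection in the whole-cell
  background; this is also what exercises the minimal-non-zero divisor
  rule. Quantities for both metrics derive from one latent per-fraction
  level (intensities proportional, counts Poisson), as in real data.
- **Uniform background amino-acid frequencies** for background
  sequence; mutation rate 0.1 per residue on planted motif copies.

What passing on this benchmark shows — and does not. The synthetic data
make the intended signal cleanly present (separable e-value classes,
correct helix-turn-helix labels up to 5% noise, 5× enrichment), so the
end-to-end ≥ 95% planted-truth recovery demonstrates that the rules,
thresholds, coordinate handling and plumbing are implemented correctly,
not that the method would achieve those rates on real proteomes — real
predictors err systematically (shared biases, not independent noise),
real motif boundaries are fuzzy, and real MS data have structured
missingness far beyond whole-cell dropout. Distributional properties of
the calibration (band-odds monotonicity) are asserted on counts pooled
over replicate generator draws, because a single 469/482 reference draw
leaves the sparse middle bands with single-digit counts whose sample
odds can invert by chance.

## Numerical notes

- The e-value floor 1/decoys bounds, rather than estimates, small
  E-values; calibrated thresholds on internal-scanner output are
  therefore coarser than on hmmsearch output.
- Window scoring uses float32 accumulation; scores are ~10² in
  magnitude, so the rounding error (~1e-4) is far below any decision
  boundary.
- `precision_recall_f1` reports 0/0 ratios as undefined (`None`), never
  silently as 0; the F1 definition `TP/(TP + (FP+FN)/2)` is used
  directly and coincides with 2PR/(P+R) wherever P and R are defined
  and non-zero.
- Ties in greedy window selection break by position (leftmost), making
  scans deterministic.
- An empty FASTA is an error in the reader (an empty proteome file is
  almost always an upstream failure), so the end-to-end runner aborts
  with a stage-named error rather than emitting empty outputs.

## Known limitations

- The internal scanner is not HMMER: no position-specific gap states,
  no composition bias correction, empirical instead of analytic
  E-values. It exists so the second iteration is testable end-to-end;
  real hmmsearch domain tables take precedence whenever supplied.
- The ungapped, terminal-padded motif alignment assumes length classes
  differ only by truncation; repeats with internal indels would need a
  true aligner upstream.
- Band-odds calibration requires reference proteins spanning all bands;
  with small references the middle bands may be undefined.
- The Ala/Lys screen and Cx9C scanner are intentionally rule-exact
  rather than probabilistic; borderline compositions (exactly 60%) and
  non-canonical spacers fall outside by definition.
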