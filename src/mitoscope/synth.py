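"""Synthetic proteomes with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:
class-conditional localization-predictor scores (Beta(8,2) for
mitochondrial proteins vs Beta(2,8) for the rest), tandem arrays of mutated
PPR-consensus motifs (2–11 per protein, length classes 31 and 35) with
separable i-E-value distributions against column-shuffled decoy repeats,
twin-Cx9C proteins with spacers in the observed 5–38 range, Ala/Lys-rich
proteins, noisy helix-turn-helix structure labels, and fraction-wise MS
quantities with planted mitochondrial enrichment.  Reference-set sizes
default to the study's: 469/482 proteins and 79/1,457 motifs.

Everything is deterministic under a fixed seed: each generator draws from
an independent, seed-derived ``numpy`` Generator stream, so outputs do not
depend on call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (DomainHit, ProteinRecord, QuantRecord,
                         StructureTrack, to_external, to_internal,
                         write_domtblout, write_fasta, write_predictor_table,
                         write_quant_table, write_span_table,
                         write_structure_table, PredictorRow)
from .locpred import ReferenceSet
from .ppr import MotifReference

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SynthData",
    "PPR_CONSENSUS",
    "make_proteome",
    "make_predictor_table",
    "make_hits_and_structs",
    "make_quant_table",
    "make_motif_reference",
    "make_protein_reference",
    "generate_all",
    "write_all",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_C = AA20.replace("C", "")
STRUCT_STATES = "HGIEBTSC"

#: 35-residue P-type PPR-like consensus used for planting motif arrays
PPR_CONSENSUS = "VVYNTLIDGLCKAGRVDEAMELFREMKEKGIKPDV"
assert len(PPR_CONSENSUS) == 35


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    Sizes and distributions mirror the real study where it states them
    (reference sizes, motifs-per-array ceiling, Cx9C spacer range,
    i-E-value separability); the proteome size is a desk-scale stand-in
    for the full proteome.
    """

    n_proteins: int = 1200
    fraction_mito: float = 0.45
    seed: int = 42

    # planted protein families
    n_ppr_proteins: int = 50
    n_decoy_proteins: int = 247
    n_cx9c_proteins: int = 18
    n_ak_proteins: int = 21
    motifs_per_array: tuple[int, int] = (2, 11)
    decoy_motifs_per_array: tuple[int, int] = (5, 9)
    motif_mutation_rate: float = 0.1
    prob_length_35: float = 0.7
    ppr_mito_rate: float = 0.9
    cx9c_spacer_range: tuple[int, int] = (5, 38)
    background_length: tuple[int, int] = (200, 500)

    # predictor emulation
    mito_beta: tuple[float, float] = (8.0, 2.0)
    nonmito_beta: tuple[float, float] = (2.0, 8.0)
    tool_correlation_kappa: float = 12.0
    assignment_cutoff: float = 0.5
    norm_constant_tertiary: float = 28.0
    tertiary_noise: float = 0.05

    # HMM-hit emulation
    true_ievalue_range: tuple[float, float] = (1e-30, 1e-3)
    decoy_ievalue_range: tuple[float, float] = (1e2, 1e6)
    hit_omission_rate: float = 0.2
    structure_noise: float = 0.05

    # MS emulation
    enrich_mito_factor: float = 5.0
    enrich_cyto_factor: float = 0.2
    quant_noise_sigma: float = 0.1
    base_spectral_counts: float = 200.0
    base_intensity: float = 1e6
    intensity_spread_sigma: float = 1.0
    whole_cell_dropout: float = 0.1
    in_complex_rate: float = 0.05

    # reference sizes (positives, negatives)
    protein_ref_sizes: tuple[int, int] = (469, 482)
    motif_ref_sizes: tuple[int, int] = (79, 1457)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_mito <= 1.0):
            raise ValueError("fraction_mito must lie in [0, 1]")
        n_special = (self.n_ppr_proteins + self.n_decoy_proteins
                     + self.n_cx9c_proteins + self.n_ak_proteins)
        if n_special > self.n_proteins:
            raise ValueError("planted families exceed n_proteins")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one stream, derived from the seed."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted truth consistent with the emitted files."""

    mito: dict[str, bool] = field(default_factory=dict)
    enriched: dict[str, bool] = field(default_factory=dict)
    #: true PPR motifs: protein id -> list of 0-based half-open spans
    ppr_motifs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    #: decoy (TPR-like) repeats, same shape
    decoy_motifs: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict)
    #: true motifs deliberately left out of the emitted hit table
    omitted_motifs: list[tuple[str, tuple[int, int]]] = field(
        default_factory=list)
    cx9c_proteins: dict[str, int] = field(default_factory=dict)
    ak_proteins: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mito": self.mito,
            "enriched": self.enriched,
            "ppr_motifs": {pid: [list(to_external(s)) for s in spans]
                           for pid, spans in self.ppr_motifs.items()},
            "decoy_motifs": {pid: [list(to_external(s)) for s in spans]
                             for pid, spans in self.decoy_motifs.items()},
            "omitted_motifs": [[pid, *to_external(span)]
                               for pid, span in self.omitted_motifs],
            "cx9c_proteins": self.cx9c_proteins,
            "ak_proteins": sorted(self.ak_proteins),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mito=d["mito"],
            enriched=d["enriched"],
            ppr_motifs={pid: [tuple(to_internal(a, b)) for a, b in spans]
                        for pid, spans in d["ppr_motifs"].items()},
            decoy_motifs={pid: [tuple(to_internal(a, b)) for a, b in spans]
                          for pid, spans in d["decoy_motifs"].items()},
            omitted_motifs=[(pid, to_internal(a, b))
                            for pid, a, b in d["omitted_motifs"]],
            cx9c_proteins=d["cx9c_proteins"],
            ak_proteins=set(d["ak_proteins"]),
        )


def _random_seq(rng: np.random.Generator, length: int,
                alphabet: str = AA20) -> str:
    return "".join(np.array(list(alphabet))[
        rng.integers(0, len(alphabet), size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AA20[rng.integers(0, 20)]
    return "".join(out)


def _decoy_consensus(cfg: SynthConfig) -> str:
    """Column-shuffled variant of the PPR consensus: same composition,
    scrambled positions, so calibration is non-trivial but separable."""
    rng = cfg.rng(9)
    perm = rng.permutation(len(PPR_CONSENSUS))
    return "".join(PPR_CONSENSUS[j] for j in perm)


def make_proteome(cfg: SynthConfig) -> tuple[list[ProteinRecord],
                                             GroundTruth]:
    """Generate the proteome FASTA content plus its ground truth.

    Layout per planted family: PPR proteins carry contiguous tandem arrays
    of mutated consensus motifs (so that omitting an interior hit later
    leaves a 31–40-residue gap between its neighbours — the gap-rescue
    situation); decoy proteins carry arrays of the column-shuffled
    consensus; twin-Cx9C proteins carry 2–4 chained motifs on a
    cysteine-free background; Ala/Lys-rich proteins draw A and K at 35%
    each.
    """
    rng = cfg.rng(1)
    truth = GroundTruth()
    proteins: list[ProteinRecord] = []

    ids = [f"SYN_{i:05d}" for i in range(1, cfg.n_proteins + 1)]
    cursor = 0

    def next_id() -> str:
        nonlocal cursor
        pid = ids[cursor]
        cursor += 1
        return pid

    decoy_cons = _decoy_consensus(cfg)

    for _ in range(cfg.n_ppr_proteins):
        pid = next_id()
        n_motifs = int(rng.integers(cfg.motifs_per_array[0],
                                    cfg.motifs_per_array[1] + 1))
        flank_n = _random_seq(rng, int(rng.integers(30, 81)))
        flank_c = _random_seq(rng, int(rng.integers(30, 81)))
        parts, spans = [flank_n], []
        pos = len(flank_n)
        for _ in range(n_motifs):
            length = 35 if rng.random() < cfg.prob_length_35 else 31
            motif = _mutate(rng, PPR_CONSENSUS[:length],
                            cfg.motif_mutation_rate)
            parts.append(motif)
            spans.append((pos, pos + length))
            pos += length
        parts.append(flank_c)
        proteins.append(ProteinRecord(pid, "".join(parts)))
        truth.ppr_motifs[pid] = spans
        truth.mito[pid] = bool(rng.random() < cfg.ppr_mito_rate)

    for _ in range(cfg.n_decoy_proteins):
        pid = next_id()
        n_motifs = int(rng.integers(cfg.decoy_motifs_per_array[0],
                                    cfg.decoy_motifs_per_array[1] + 1))
        flank_n = _random_seq(rng, int(rng.integers(30, 81)))
        flank_c = _random_seq(rng, int(rng.integers(30, 81)))
        parts, spans = [flank_n], []
        pos = len(flank_n)
        for _ in range(n_motifs):
            motif = _mutate(rng, decoy_cons, cfg.motif_mutation_rate)
            parts.append(motif)
            spans.append((pos, pos + len(motif)))
            pos += len(motif)
        parts.append(flank_c)
        proteins.append(ProteinRecord(pid, "".join(parts)))
        truth.decoy_motifs[pid] = spans
        truth.mito[pid] = bool(rng.random() < cfg.fraction_mito)

    for _ in range(cfg.n_cx9c_proteins):
        pid = next_id()
        n_motifs = int(rng.integers(2, 5))
        parts = [_random_seq(rng, int(rng.integers(20, 41)), AA_NO_C)]
        for k in range(n_motifs):
            parts.append("C" + _random_seq(rng, 9, AA_NO_C) + "C")
            if k < n_motifs - 1:
                spacer = int(rng.integers(cfg.cx9c_spacer_range[0],
                                          cfg.cx9c_spacer_range[1] + 1))
                parts.append(_random_seq(rng, spacer, AA_NO_C))
        parts.append(_random_seq(rng, int(rng.integers(20, 41)), AA_NO_C))
        proteins.append(ProteinRecord(pid, "".join(parts)))
        truth.cx9c_proteins[pid] = n_motifs
        truth.mito[pid] = True

    for _ in range(cfg.n_ak_proteins):
        pid = next_id()
        length = int(rng.integers(150, 251))
        draws = rng.random(length)
        seq = "".join(
            "A" if d < 0.35 else ("K" if d < 0.70
                                  else AA20[rng.integers(0, 20)])
            for d in draws)
        proteins.append(ProteinRecord(pid, seq))
        truth.ak_proteins.add(pid)
        truth.mito[pid] = True

    while cursor < cfg.n_proteins:
        pid = next_id()
        length = int(rng.integers(cfg.background_length[0],
                                  cfg.background_length[1] + 1))
        proteins.append(ProteinRecord(pid, _random_seq(rng, length)))
        truth.mito[pid] = bool(rng.random() < cfg.fraction_mito)

    truth.enriched = dict(truth.mito)
    return proteins, truth


def make_predictor_table(cfg: SynthConfig,
                         truth: GroundTruth) -> list[PredictorRow]:
    """Class-conditional, tool-correlated predictor scores and flags.

    The primary (best-performing) predictor's score is the protein's
    class-conditional Beta draw; the other two tools score the same
    protein, so their scores concentrate around the primary's with
    concentration ``tool_correlation_kappa`` — borderline proteins look
    borderline to every tool, which is what places genuine mitochondrial
    proteins into the intermediate confidence bands.
    """
    rng = cfg.rng(2)
    kappa = cfg.tool_correlation_kappa
    rows = []
    for pid in sorted(truth.mito):
        a, b = cfg.mito_beta if truth.mito[pid] else cfg.nonmito_beta
        q = min(max(float(rng.beta(a, b)), 1e-6), 1 - 1e-6)
        s_primary = q
        s_secondary = float(rng.beta(q * kappa, (1 - q) * kappa))
        s_tertiary = float(rng.beta(q * kappa, (1 - q) * kappa))
        raw = max(0.0, cfg.norm_constant_tertiary
                  * (s_tertiary + rng.normal(0.0, cfg.tertiary_noise)))
        rows.append(PredictorRow(
            protein_id=pid,
            score_primary=s_primary,
            assigned_primary=s_primary > cfg.assignment_cutoff,
            score_secondary=s_secondary,
            assigned_secondary=s_secondary > cfg.assignment_cutoff,
            score_tertiary_raw=raw,
            norm_constant_tertiary=cfg.norm_constant_tertiary,
        ))
    return rows


def _log_uniform(rng: np.random.Generator,
                 lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _motif_struct_pattern(length: int, turn_at_11_13: bool = True) -> str:
    """Helix-turn-helix label pattern; decoys put the turn one position
    late, which fails the positional criterion."""
    if turn_at_11_13:
        return "H" * 10 + "TTT" + "H" * (length - 13)
    return "H" * 11 + "TTT" + "H" * (length - 14)


def make_hits_and_structs(cfg: SynthConfig,
                          proteins: Sequence[ProteinRecord],
                          truth: GroundTruth,
                          ) -> tuple[list[DomainHit], list[StructureTrack]]:
    """Domain-hit table and structure tracks consistent with the truth.

    True motifs draw i-E-values log-uniform from the separable 'true'
    range, decoy repeats from the 'decoy' range.  A fraction of interior
    true motifs is omitted from the hit table (never two adjacent ones) —
    these are the gap-rescue targets; ``truth.omitted_motifs`` records
    them.  Structure labels are correct helix-turn-helix patterns on true
    motifs, near-miss patterns on decoys, coil elsewhere, with per-residue
    noise.
    """
    rng = cfg.rng(3)
    by_id = {p.id: p for p in proteins}
    hits: list[DomainHit] = []
    tracks: list[StructureTrack] = []
    truth.omitted_motifs = []

    for pid in sorted(truth.ppr_motifs):
        spans = truth.ppr_motifs[pid]
        omitted_prev = True  # protects the first (terminal) motif
        omitted_flags = []
        for k, span in enumerate(spans):
            interior = 0 < k < len(spans) - 1
            omit = (interior and not omitted_prev
                    and rng.random() < cfg.hit_omission_rate)
            omitted_flags.append(omit)
            omitted_prev = omit
        for span, omit in zip(spans, omitted_flags):
            if omit:
                truth.omitted_motifs.append((pid, span))
            else:
                e = _log_uniform(rng, *cfg.true_ievalue_range)
                hits.append(DomainHit(pid, "plant_P_type", span[0], span[1],
                                      i_evalue=e,
                                      bit_score=-float(np.log10(e))))
        labels = ["C"] * by_id[pid].length
        for span in spans:
            pattern = _motif_struct_pattern(span[1] - span[0])
            labels[span[0]:span[1]] = list(pattern)
        tracks.append(_noisy_track(rng, pid, labels, cfg.structure_noise))

    for pid in sorted(truth.decoy_motifs):
        spans = truth.decoy_motifs[pid]
        for span in spans:
            e = _log_uniform(rng, *cfg.decoy_ievalue_range)
            hits.append(DomainHit(pid, "plant_P_type", span[0], span[1],
                                  i_evalue=e, bit_score=0.0))
        labels = ["C"] * by_id[pid].length
        for span in spans:
            pattern = _motif_struct_pattern(span[1] - span[0],
                                            turn_at_11_13=False)
            labels[span[0]:span[1]] = list(pattern)
        tracks.append(_noisy_track(rng, pid, labels, cfg.structure_noise))

    return hits, tracks


def _noisy_track(rng: np.random.Generator, pid: str,
                 labels: list[str], noise: float) -> StructureTrack:
    out = list(labels)
    for i in range(len(out)):
        if rng.random() < noise:
            out[i] = STRUCT_STATES[rng.integers(0, len(STRUCT_STATES))]
    return StructureTrack(pid, "".join(out))


def make_quant_table(cfg: SynthConfig,
                     truth: GroundTruth) -> list[QuantRecord]:
    """Fraction-wise MS quantities with planted mitochondrial enrichment.

    Spectral counts and ion intensities derive from the same latent
    per-fraction level, as they do in real data.  Whole-cell dropout (zero
    in both metrics) affects enriched proteins only — mirroring low-copy
    mitochondrial proteins falling below detection in the whole-cell
    background — and exercises the minimal-non-zero divisor rule.
    """
    rng = cfg.rng(4)
    records = []
    for pid in sorted(truth.enriched):
        enriched = truth.enriched[pid]
        abundance = float(np.exp(rng.normal(0.0,
                                            cfg.intensity_spread_sigma)))
        factors = {
            "whole_cell": 1.0,
            "cytosol": cfg.enrich_cyto_factor if enriched else 1.0,
            "mitochondria": cfg.enrich_mito_factor if enriched else 1.0,
        }
        level = {f: abundance * factors[f]
                 * float(np.exp(rng.normal(0.0, cfg.quant_noise_sigma)))
                 for f in factors}
        dropout = enriched and rng.random() < cfg.whole_cell_dropout
        if dropout:
            level["whole_cell"] = 0.0
        sc = {f: int(rng.poisson(cfg.base_spectral_counts * level[f]))
              for f in level}
        ii = {f: cfg.base_intensity * level[f] for f in level}
        in_complex = enriched and rng.random() < cfg.in_complex_rate
        records.append(QuantRecord(
            protein_id=pid, spectral_counts=sc, ion_intensities=ii,
            in_complex_datasets=in_complex))
    return records


def make_motif_reference(cfg: SynthConfig,
                         truth: GroundTruth) -> MotifReference:
    """Sample the motif-level calibration reference from the truth.

    Positives are drawn only from true motifs that received a hit (the
    real positive reference was itself the subset of expert motifs
    retrieved by the HMM search); negatives from the decoy repeats.
    """
    rng = cfg.rng(5)
    omitted = set(truth.omitted_motifs)
    pos_pool = sorted(
        (pid, span) for pid, spans in truth.ppr_motifs.items()
        for span in spans if (pid, span) not in omitted)
    neg_pool = sorted(
        (pid, span) for pid, spans in truth.decoy_motifs.items()
        for span in spans)
    n_pos, n_neg = cfg.motif_ref_sizes
    if n_pos > len(pos_pool) or n_neg > len(neg_pool):
        raise ValueError(
            f"motif reference sizes {cfg.motif_ref_sizes} exceed pools "
            f"({len(pos_pool)} positive, {len(neg_pool)} negative)")
    pos_idx = rng.choice(len(pos_pool), size=n_pos, replace=False)
    neg_idx = rng.choice(len(neg_pool), size=n_neg, replace=False)
    return MotifReference(
        positive_motifs=tuple(pos_pool[i] for i in sorted(pos_idx)),
        negative_motifs=tuple(neg_pool[i] for i in sorted(neg_idx)),
    )


def make_protein_reference(cfg: SynthConfig,
                           truth: GroundTruth) -> ReferenceSet:
    """Sample the protein-level positive/negative localization reference."""
    rng = cfg.rng(6)
    pos_pool = sorted(pid for pid, m in truth.mito.items() if m)
    neg_pool = sorted(pid for pid, m in truth.mito.items() if not m)
    n_pos, n_neg = cfg.protein_ref_sizes
    if n_pos > len(pos_pool) or n_neg > len(neg_pool):
        raise ValueError(
            f"protein reference sizes {cfg.protein_ref_sizes} exceed pools "
            f"({len(pos_pool)} positive, {len(neg_pool)} negative)")
    pos_idx = rng.choice(len(pos_pool), size=n_pos, replace=False)
    neg_idx = rng.choice(len(neg_pool), size=n_neg, replace=False)
    return ReferenceSet(
        positives=frozenset(pos_pool[i] for i in pos_idx),
        negatives=frozenset(neg_pool[i] for i in neg_idx),
    )


@dataclass
class SynthData:
    """One fully generated benchmark dataset."""

    config: SynthConfig
    proteins: list[ProteinRecord]
    truth: GroundTruth
    predictor_rows: list[PredictorRow]
    hits: list[DomainHit]
    tracks: list[StructureTrack]
    quants: list[QuantRecord]
    motif_reference: MotifReference
    protein_reference: ReferenceSet


def generate_all(cfg: SynthConfig = SynthConfig()) -> SynthData:
    proteins, truth = make_proteome(cfg)
    hits, tracks = make_hits_and_structs(cfg, proteins, truth)
    return SynthData(
        config=cfg,
        proteins=proteins,
        truth=truth,
        predictor_rows=make_predictor_table(cfg, truth),
        hits=hits,
        tracks=tracks,
        quants=make_quant_table(cfg, truth),
        motif_reference=make_motif_reference(cfg, truth),
        protein_reference=make_protein_reference(cfg, truth),
    )


def write_all(data: SynthData, outdir: str | Path) -> dict[str, Path]:
    """Emit every input file of the pipeline plus the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteome.fasta",
        "predictors": outdir / "predictors.tsv",
        "domtblout": outdir / "plant_ppr_hits.domtblout",
        "structures": outdir / "structures.tsv",
        "quant": outdir / "quant.tsv",
        "ref_motifs_pos": outdir / "ref_motifs_positive.tsv",
        "ref_motifs_neg": outdir / "ref_motifs_negative.tsv",
        "ref_proteins_pos": outdir / "ref_proteins_positive.txt",
        "ref_proteins_neg": outdir / "ref_proteins_negative.txt",
        "truth": outdir / "truth.json",
    }
    write_fasta(data.proteins, paths["fasta"])
    write_predictor_table(data.predictor_rows, paths["predictors"])
    write_domtblout(data.hits, paths["domtblout"])
    write_structure_table(data.tracks, paths["structures"])
    write_quant_table(data.quants, paths["quant"])
    write_span_table(data.motif_reference.positive_motifs,
                     paths["ref_motifs_pos"])
    write_span_table(data.motif_reference.negative_motifs,
                     paths["ref_motifs_neg"])
    paths["ref_proteins_pos"].write_text(
        "\n".join(sorted(data.protein_reference.positives)) + "\n")
    paths["ref_proteins_neg"].write_text(
        "\n".join(sorted(data.protein_reference.negatives)) + "\n")
    data.truth.to_json(paths["truth"])
    return paths
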