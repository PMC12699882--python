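"""End-to-end run: join localization, MS and motif evidence per protein.

``run_all`` reads every configured input, runs the ensemble scorer, the
enrichment classifier, the sequence screens and the PPR pipeline, writes
the per-protein annotation table, and summarizes the run (candidate count,
share of candidates with WA > 0.5, per-band counts, detection rates) in
JSON and plain text.  Outputs are byte-deterministic for a fixed config
and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from . import io_formats as iof
from . import locpred, motif_scan, ms_enrichment, ppr

log = logging.getLogger("mitoscope")

__all__ = ["PipelineConfig", "RunResult", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run; file paths may be omitted to
    skip the corresponding stage."""

    fasta: Path
    predictors: Optional[Path] = None
    domtblout: Optional[Path] = None
    structures: Optional[Path] = None
    quant: Optional[Path] = None
    ref_proteins_pos: Optional[Path] = None
    ref_proteins_neg: Optional[Path] = None
    ref_motifs_pos: Optional[Path] = None
    ref_motifs_neg: Optional[Path] = None

    norm_constant_tertiary: float = 28.0
    ensemble: locpred.EnsembleConfig = field(
        default_factory=locpred.EnsembleConfig)
    ppr_config: ppr.PprConfig = field(default_factory=ppr.PprConfig)
    min_band: locpred.Band = locpred.Band.VERY_LIKELY
    overrides: dict[str, str] = field(default_factory=dict)
    allow_cx10c: bool = True
    ak_threshold_pct: float = 60.0
    domain_max_evalue: float = 0.05
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent

        def p(key):
            return (base / raw[key]) if key in raw and raw[key] else None

        kwargs: dict = {k: p(k) for k in (
            "fasta", "predictors", "domtblout", "structures", "quant",
            "ref_proteins_pos", "ref_proteins_neg",
            "ref_motifs_pos", "ref_motifs_neg") if p(k) is not None}
        if "fasta" not in kwargs:
            raise StageError("config: a proteome 'fasta' path is required")
        if "ensemble" in raw:
            kwargs["ensemble"] = locpred.EnsembleConfig(**raw["ensemble"])
        if "ppr" in raw:
            kwargs["ppr_config"] = ppr.PprConfig(**raw["ppr"])
        for key in ("norm_constant_tertiary", "overrides", "allow_cx10c",
                    "ak_threshold_pct", "domain_max_evalue", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "min_band" in raw:
            kwargs["min_band"] = locpred.Band.from_label(raw["min_band"])
        return cls(**kwargs)

    def validate(self) -> None:
        for name in ("fasta", "predictors", "domtblout", "structures",
                     "quant", "ref_proteins_pos", "ref_proteins_neg",
                     "ref_motifs_pos", "ref_motifs_neg"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise StageError(f"config: input '{name}' not found: {path}")


@dataclass
class RunResult:
    summary: dict
    calls: dict[str, locpred.LocalizationCall]
    enrichment: dict[str, ms_enrichment.EnrichmentCall]
    ppr_result: Optional[ppr.PprDiscoveryResult]
    annotation_path: Optional[Path]


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _read_id_list(path: Path) -> frozenset[str]:
    return frozenset(line.strip() for line in Path(path).read_text()
                     .splitlines() if line.strip())


def run_all(config: PipelineConfig,
            outdir: str | Path | None = None) -> RunResult:
    """Run every configured stage and write the annotation + summary."""
    config.validate()
    for name in ("fasta", "predictors", "domtblout", "quant"):
        path = getattr(config, name)
        if path is not None:
            log.info("input %s: %s (sha256 %s)", name, path, _digest(path))

    try:
        proteome = iof.read_fasta(config.fasta)
    except iof.FormatError as e:
        raise StageError(f"read_fasta: {e}") from e
    by_id = {p.id: p for p in proteome}
    summary: dict = {"n_proteins": len(proteome)}

    # --- localization ensemble
    calls: dict[str, locpred.LocalizationCall] = {}
    candidates = locpred.CandidateSet(frozenset(), {})
    if config.predictors is not None:
        try:
            rows = iof.read_predictor_table(config.predictors,
                                            config.norm_constant_tertiary)
            calls = {r.protein_id: locpred.wa_score(r, config.ensemble)
                     for r in rows}
            if config.ref_proteins_pos and config.ref_proteins_neg:
                ref = locpred.ReferenceSet(
                    _read_id_list(config.ref_proteins_pos),
                    _read_id_list(config.ref_proteins_neg))
                odds = locpred.calibrate_band_odds(calls, ref)
                calls = locpred.annotate_band_odds(calls, odds)
                summary["band_odds"] = {
                    b.label: (None if o.odds is None
                              else ("inf" if o.odds == float("inf")
                                    else round(o.odds, 3)))
                    for b, o in odds.items()}
            candidates = locpred.select_candidates(
                calls, config.min_band, config.overrides)
        except (iof.FormatError, ValueError) as e:
            raise StageError(f"locpred: {e}") from e
        band_counts = {b.label: 0 for b in locpred.Band}
        for call in calls.values():
            band_counts[call.band.label] += 1
        n_cand = len(candidates.ids)
        above_half = sum(1 for pid in candidates.ids
                         if calls[pid].wa_score > 0.5)
        summary.update(
            band_counts=band_counts,
            n_candidates=n_cand,
            pct_candidates_wa_above_half=(
                round(100.0 * above_half / n_cand, 1) if n_cand else 0.0),
            n_overrides=len(candidates.overrides),
        )

    # --- MS enrichment
    enrichment: dict[str, ms_enrichment.EnrichmentCall] = {}
    if config.quant is not None:
        try:
            quants = iof.read_quant_table(config.quant)
            floors = {m: ms_enrichment.compute_floors(quants, m)
                      for m in ms_enrichment.METRICS}
            enrichment = {
                q.protein_id: ms_enrichment.combined_call(q, floors)
                for q in quants}
        except (iof.FormatError, ValueError) as e:
            raise StageError(f"ms_enrichment: {e}") from e
        summary["n_detected_in_mito"] = sum(
            1 for c in enrichment.values() if c.detected)
        summary["n_via_complex"] = sum(
            1 for c in enrichment.values() if c.via_complex)

    # --- sequence screens
    motifs: dict[str, dict] = {}
    for rec in proteome:
        cx = motif_scan.scan_cx9c(rec, allow_cx10c=config.allow_cx10c)
        ak = motif_scan.ak_composition_screen(
            rec, threshold_pct=config.ak_threshold_pct)
        entry: dict = {}
        if cx.motifs:
            entry["cx9c"] = len(cx.motifs)
        if ak.flagged:
            entry["ak_rich"] = True
        if entry:
            motifs[rec.id] = entry
    summary["n_cx9c_proteins"] = sum(
        1 for m in motifs.values() if m.get("cx9c"))
    summary["n_ak_rich_proteins"] = sum(
        1 for m in motifs.values() if m.get("ak_rich"))

    # --- PPR discovery
    ppr_result: Optional[ppr.PprDiscoveryResult] = None
    if config.domtblout is not None:
        try:
            hits = iof.read_domtblout(config.domtblout)
            tracks = None
            if config.structures is not None:
                tracks = {t.protein_id: t for t in
                          iof.read_structure_table(config.structures)}
            ref = None
            if config.ref_motifs_pos and config.ref_motifs_neg:
                ref = ppr.MotifReference(
                    tuple(iof.read_span_table(config.ref_motifs_pos)),
                    tuple(iof.read_span_table(config.ref_motifs_neg)))
            ppr_result = ppr.iterate_discovery(
                proteome, hits, ref=ref, tracks=tracks,
                config=config.ppr_config)
        except (iof.FormatError, ValueError) as e:
            raise StageError(f"ppr: {e}") from e
        for pid, count in ppr_result.motif_counts().items():
            motifs.setdefault(pid, {})["ppr"] = count
        log.info("ppr thresholds: iteration1=%g iteration2=%s",
                 ppr_result.threshold1, ppr_result.threshold2)
        n_ppr = len(ppr_result.ppr_proteins)
        summary.update(
            ppr_threshold1=ppr_result.threshold1,
            ppr_threshold2=ppr_result.threshold2,
            n_ppr_proteins=n_ppr,
            n_ppr_motifs=len(ppr_result.final_motifs),
            n_ppr_rescued_motifs=len(ppr_result.rescued_motifs),
            n_ppr_mito_targeted=sum(
                1 for pid in ppr_result.ppr_proteins
                if pid in candidates.ids),
            ppr_flags=list(ppr_result.flags),
        )

    # --- outputs
    annotation_path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        annotation_path = outdir / "annotation.tsv"
        iof.write_annotation_table(calls, motifs, enrichment,
                                   annotation_path)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        (outdir / "summary.txt").write_text(_format_summary(summary))
    return RunResult(summary=summary, calls=calls, enrichment=enrichment,
                     ppr_result=ppr_result, annotation_path=annotation_path)


def _format_summary(summary: Mapping) -> str:
    lines = ["mitoscope run summary", "====================="]
    for key in sorted(summary):
        lines.append(f"{key}: {summary[key]}")
    return "\n".join(lines) + "\n"
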