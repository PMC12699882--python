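"""Weighted-average ensemble scoring of mitochondrial localization.

Three subcellular-localization predictors are combined into a single
weighted-average (WA) mitochondrion score per protein:

    WA = (w_s * secondary + w_t * tertiary + w_p * primary) / divisor

with default weights 2.5 (MULocDeep-style), 1.5 (normalized WoLF
PSORT-style) and 6 (DeepLoc2-style), divisor 10, so WA lies in [0, 1].
The primary predictor's categorical assignment dominates: proteins it
assigns to the mitochondrion keep their raw WA; proteins it rejects but the
secondary predictor assigns are downgraded by a multiplicative penalty
(default 0.25, landing them in (0, 0.25)); proteins rejected by both
default to WA = 0 and are called non-mitochondrial outright.

WA scores are binned into confidence bands whose empirical likelihood
ratios (mitochondrial : non-mitochondrial) can be calibrated from curated
positive/negative reference proteins.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional

from .io_formats import PredictorRow

__all__ = [
    "Band",
    "EnsembleConfig",
    "LocalizationCall",
    "ReferenceSet",
    "BandOdds",
    "CandidateSet",
    "wa_score",
    "assign_band",
    "calibrate_band_odds",
    "select_candidates",
]


class Band(enum.IntEnum):
    """Confidence bands, ordered from least to most mitochondrial."""

    NON_MITOCHONDRIAL = 0
    LOW_PROBABILITY = 1
    LIKELY = 2
    VERY_LIKELY = 3
    ALMOST_CERTAINLY = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Band":
        return cls[label.upper()]


@dataclass(frozen=True)
class EnsembleConfig:
    """Weights, penalty and band edges of the WA ensemble."""

    weight_primary: float = 6.0
    weight_secondary: float = 2.5
    weight_tertiary: float = 1.5
    divisor: float = 10.0
    penalty_factor: float = 0.25
    band_edges: tuple[float, float, float] = (0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        weights = (self.weight_primary, self.weight_secondary,
                   self.weight_tertiary)
        if any(w <= 0 for w in weights):
            raise ValueError("ensemble weights must be positive")
        if not math.isclose(sum(weights), self.divisor):
            raise ValueError(
                f"weights {weights} must sum to the divisor {self.divisor}"
            )
        if not (0.0 < self.penalty_factor < 1.0):
            raise ValueError("penalty_factor must lie in (0, 1)")
        e = self.band_edges
        if not (0.0 < e[0] < e[1] < e[2] < 1.0):
            raise ValueError(
                f"band edges must be strictly increasing within (0, 1): {e}"
            )


@dataclass(frozen=True)
class LocalizationCall:
    protein_id: str
    wa_score: float
    penalized: bool
    band: Band
    band_odds: Optional[float] = None


def assign_band(wa: float, penalized: bool,
                cfg: EnsembleConfig = EnsembleConfig()) -> Band:
    """Map a WA score to its confidence band.

    Intervals are half-open [lower, upper) with the top band closed at 1;
    WA = 0 is non-mitochondrial by definition, so the bands partition [0, 1].
    """
    if not (0.0 <= wa <= 1.0) or math.isnan(wa):
        raise ValueError(f"WA score outside [0, 1]: {wa}")
    low, mid, high = cfg.band_edges
    if wa == 0.0:
        return Band.NON_MITOCHONDRIAL
    if wa < low:
        return Band.LOW_PROBABILITY
    if wa < mid:
        return Band.LIKELY
    if wa < high:
        return Band.VERY_LIKELY
    return Band.ALMOST_CERTAINLY


def wa_score(row: PredictorRow,
             cfg: EnsembleConfig = EnsembleConfig()) -> LocalizationCall:
    """Score one protein with the weighted-average ensemble.

    The raw weighted average is kept as-is when the primary predictor
    assigns the protein to the mitochondrion, multiplied by
    ``cfg.penalty_factor`` when only the secondary predictor does, and
    replaced by 0 when neither does.
    """
    raw = (
        cfg.weight_secondary * row.score_secondary
        + cfg.weight_tertiary * row.score_tertiary
        + cfg.weight_primary * row.score_primary
    ) / cfg.divisor
    if row.assigned_primary:
        wa, penalized = raw, False
    elif row.assigned_secondary:
        wa, penalized = cfg.penalty_factor * raw, True
    else:
        wa, penalized = 0.0, False
    return LocalizationCall(
        protein_id=row.protein_id,
        wa_score=wa,
        penalized=penalized,
        band=assign_band(wa, penalized, cfg),
    )


@dataclass(frozen=True)
class ReferenceSet:
    """Curated positive/negative reference protein ids (disjoint sets)."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positives or not self.negatives:
            raise ValueError("both reference sets must be non-empty")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(
                f"reference sets overlap: {sorted(overlap)[:5]} ..."
            )


@dataclass(frozen=True)
class BandOdds:
    """Per-band likelihood ratio with its raw reference counts.

    ``odds`` is (fraction of positives in the band) / (fraction of
    negatives in the band): ``math.inf`` when positives land in the band
    but no negatives do, ``None`` (undefined) when the band holds no
    reference protein at all.  No smoothing is applied — raw likelihoods
    are reported exactly as counted.
    """

    band: Band
    n_positive: int
    n_negative: int
    positive_rate: float
    negative_rate: float
    odds: Optional[float]


def calibrate_band_odds(calls: Mapping[str, LocalizationCall],
                        ref: ReferenceSet) -> dict[Band, BandOdds]:
    """Estimate each band's mitochondrial : non-mitochondrial odds."""
    missing = (ref.positives | ref.negatives) - set(calls)
    if missing:
        raise ValueError(
            f"reference ids without a localization call: "
            f"{sorted(missing)[:5]} ..."
        )
    pos_counts = {b: 0 for b in Band}
    neg_counts = {b: 0 for b in Band}
    for pid in ref.positives:
        pos_counts[calls[pid].band] += 1
    for pid in ref.negatives:
        neg_counts[calls[pid].band] += 1
    n_pos, n_neg = len(ref.positives), len(ref.negatives)
    out: dict[Band, BandOdds] = {}
    for band in Band:
        p_rate = pos_counts[band] / n_pos
        n_rate = neg_counts[band] / n_neg
        if pos_counts[band] == 0 and neg_counts[band] == 0:
            odds: Optional[float] = None
        elif neg_counts[band] == 0:
            odds = math.inf
        else:
            odds = p_rate / n_rate
        out[band] = BandOdds(band, pos_counts[band], neg_counts[band],
                             p_rate, n_rate, odds)
    return out


def annotate_band_odds(calls: Mapping[str, LocalizationCall],
                       odds: Mapping[Band, BandOdds],
                       ) -> dict[str, LocalizationCall]:
    """Return calls with each protein's band odds filled in."""
    return {
        pid: replace(call, band_odds=odds[call.band].odds)
        for pid, call in calls.items()
    }


@dataclass(frozen=True)
class CandidateSet:
    """Candidate mitoproteins: band-selected ids plus justified overrides."""

    ids: frozenset[str]
    overrides: Mapping[str, str]


def select_candidates(calls: Mapping[str, LocalizationCall],
                      min_band: Band = Band.VERY_LIKELY,
                      overrides: Mapping[str, str] | None = None,
                      ) -> CandidateSet:
    """Select proteins at or above ``min_band``, plus explicit overrides.

    Overrides admit proteins below the band cutoff on external evidence
    (e.g. direct isolation from purified mitochondria); each must name its
    protein and carry a free-text reason, and must refer to a scored
    protein.
    """
    overrides = dict(overrides or {})
    absent = set(overrides) - set(calls)
    if absent:
        raise ValueError(
            f"override ids without a localization call: {sorted(absent)}"
        )
    selected = {pid for pid, call in calls.items() if call.band >= min_band}
    selected.update(overrides)
    return CandidateSet(ids=frozenset(selected), overrides=overrides)
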