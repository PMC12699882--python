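"""Mitochondrial-enrichment calls from fraction-wise MS quantities.

For each protein, the mitochondrial and cytosolic quantities (spectral
counts or ion intensities) are divided by the whole-cell quantity; when
nothing was detected in the whole-cell lysate, the divisor is replaced by
the smallest non-zero value observed in the dataset for that metric, so the
ratios remain finite and the rule stays scale-invariant.  A protein is
'detected in mitochondria' when the mitochondrion : whole-cell ratio
exceeds the cytosol : whole-cell ratio and is itself > 1.5 (strict), or
unconditionally when the protein was identified in purified mitochondrial
complexes (respirasome / mitoribosome pull-downs).

iBAQ values (summed precursor intensity over the count of theoretically
observable fully tryptic 7–30-mers) are provided as the abundance metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from pyteomics import parser as _pt_parser

from .io_formats import FRACTIONS, QuantRecord

__all__ = [
    "METRICS",
    "FloorConstants",
    "EnrichmentCall",
    "IbaqResult",
    "compute_floors",
    "enrichment_call",
    "combined_call",
    "ibaq",
    "category_summary",
]

METRICS = ("spectral_counts", "ion_intensity")

#: cleave after K/R except before P; no missed cleavages
TRYPSIN_RULE = r"[KR](?!P)"


def _values(q: QuantRecord, metric: str) -> Mapping[str, float]:
    if metric == "spectral_counts":
        return q.spectral_counts
    if metric == "ion_intensity":
        return q.ion_intensities
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


@dataclass(frozen=True)
class FloorConstants:
    """Zero-divisor replacement: the dataset's minimal non-zero value."""

    metric: str
    floor: float

    def __post_init__(self) -> None:
        if not self.floor > 0:
            raise ValueError("floor must be > 0")


def compute_floors(quants: Iterable[QuantRecord],
                   metric: str) -> FloorConstants:
    """Smallest strictly positive value of ``metric`` over all proteins and
    fractions; errors on an all-zero dataset."""
    floor = math.inf
    for q in quants:
        for v in _values(q, metric).values():
            if 0 < v < floor:
                floor = v
    if not math.isfinite(floor):
        raise ValueError(f"no non-zero {metric} value in the dataset")
    return FloorConstants(metric=metric, floor=floor)


@dataclass(frozen=True)
class EnrichmentCall:
    protein_id: str
    metric: str
    ratio_mito: float
    ratio_cyto: float
    divisor_substituted: bool
    detected: bool
    via_complex: bool


def enrichment_call(q: QuantRecord, metric: str,
                    floors: FloorConstants,
                    ratio_cutoff: float = 1.5) -> EnrichmentCall:
    """Apply the enrichment rule to one protein for one metric."""
    if floors.metric != metric:
        raise ValueError(
            f"floors computed for {floors.metric!r}, not {metric!r}"
        )
    vals = _values(q, metric)
    missing = [f for f in FRACTIONS if f not in vals]
    if missing:
        raise ValueError(
            f"protein {q.protein_id!r}: missing fractions {missing}"
        )
    whole = vals["whole_cell"]
    substituted = whole == 0
    divisor = floors.floor if substituted else whole
    ratio_mito = vals["mitochondria"] / divisor
    ratio_cyto = vals["cytosol"] / divisor
    detected = (ratio_mito > ratio_cyto and ratio_mito > ratio_cutoff)
    via_complex = bool(q.in_complex_datasets)
    return EnrichmentCall(
        protein_id=q.protein_id,
        metric=metric,
        ratio_mito=ratio_mito,
        ratio_cyto=ratio_cyto,
        divisor_substituted=substituted,
        detected=detected or via_complex,
        via_complex=via_complex,
    )


def combined_call(q: QuantRecord,
                  floors_by_metric: Mapping[str, FloorConstants],
                  ratio_cutoff: float = 1.5) -> EnrichmentCall:
    """Detected when the rule passes for at least one available metric.

    The per-metric verdicts remain available through ``enrichment_call``;
    the combined call reports the metric that fired (the first of
    ``METRICS`` whose rule passed, or the first metric otherwise).
    """
    calls = [enrichment_call(q, m, floors_by_metric[m], ratio_cutoff)
             for m in METRICS if m in floors_by_metric]
    if not calls:
        raise ValueError("no metric supplied")
    for c in calls:
        if c.detected:
            return c
    return calls[0]


@dataclass(frozen=True)
class IbaqResult:
    protein_id: str
    value: Optional[float]
    n_peptides: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def tryptic_peptides(sequence: str,
                     min_length: int = 7,
                     max_length: int = 30) -> list[str]:
    """Fully tryptic peptides of observable length, in sequence order."""
    return [pep for _, pep in _pt_parser.icleave(
        sequence, TRYPSIN_RULE, missed_cleavages=0)
        if min_length <= len(pep) <= max_length]


def ibaq(intensity_sum: float, sequence: str,
         protein_id: str = "") -> IbaqResult:
    """Intensity-based absolute quantification for one protein."""
    if intensity_sum < 0:
        raise ValueError("negative intensity")
    if not sequence:
        raise ValueError("empty sequence")
    n = len(tryptic_peptides(sequence))
    value = None if n == 0 else intensity_sum / n
    return IbaqResult(protein_id=protein_id, value=value, n_peptides=n)


VALID_CATEGORIES = tuple("ABCDEFGHIJ")


def category_summary(detected: Mapping[str, bool],
                     categories: Mapping[str, str]) -> pd.DataFrame:
    """Per-functional-category totals, detected counts and percentages.

    ``categories`` maps protein_id -> functional category label A–J;
    ``detected`` maps protein_id -> MS-detection verdict.  Returns one row
    per category plus a 'total' row, with columns ``n_proteins``,
    ``n_detected`` and ``pct_detected``.
    """
    unknown = sorted(set(categories.values()) - set(VALID_CATEGORIES))
    if unknown:
        raise ValueError(f"unknown category labels {unknown}")
    missing = sorted(set(detected) - set(categories))
    if missing:
        raise ValueError(
            f"proteins without a category label: {missing[:5]} ..."
        )
    rows = []
    total_n = total_d = 0
    for cat in VALID_CATEGORIES:
        ids = [pid for pid, c in categories.items() if c == cat]
        n = len(ids)
        d = sum(bool(detected.get(pid, False)) for pid in ids)
        rows.append((cat, n, d, 100.0 * d / n if n else 0.0))
        total_n += n
        total_d += d
    rows.append(("total", total_n, total_d,
                 100.0 * total_d / total_n if total_n else 0.0))
    return pd.DataFrame(
        rows, columns=["category", "n_proteins", "n_detected",
                       "pct_detected"],
    ).set_index("category")
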