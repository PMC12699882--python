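"""Deterministic sequence screens: twin-Cx9C motifs, Ala/Lys composition,
and generic domain-table filtering.

Twin-Cx9C (CHCH-fold) proteins of the mitochondrial intermembrane space
carry paired cysteine motifs C-x9-C separated by short spacers; some Cox12
orthologs use a Cx10C variant for the second motif.  The scan is greedy
left-to-right, motif interiors may not contain cysteine (canonical twin
disulfide chemistry), and motifs count only when chained to at least one
other motif at a plausible spacer distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .io_formats import DomainHit, ProteinRecord

__all__ = [
    "CxMotif",
    "TwinCxCall",
    "AkScreenResult",
    "DomainFilterResult",
    "scan_cx9c",
    "ak_composition_screen",
    "filter_domain_hits",
]


@dataclass(frozen=True)
class CxMotif:
    """One C-x{9,10}-C motif; ``start`` is the 0-based index of the first
    cysteine, ``inner_length`` the number of residues between the two."""

    protein_id: str
    start: int
    inner_length: int
    motif_string: str

    @property
    def end(self) -> int:
        """0-based half-open end (one past the closing cysteine)."""
        return self.start + self.inner_length + 2

    @property
    def start_1based(self) -> int:
        return self.start + 1


@dataclass(frozen=True)
class TwinCxCall:
    """Chained Cx9C motifs of one protein with inter-motif spacers.

    ``spacers[i]`` is the number of residues strictly between motif ``i``'s
    closing cysteine and motif ``i+1``'s opening cysteine, the bracketed
    numbers of the field's usual motif-structure notation."""

    protein_id: str
    motifs: tuple[CxMotif, ...]
    spacers: tuple[int, ...]


def _candidate_motifs(protein: ProteinRecord,
                      allow_cx10c: bool) -> list[CxMotif]:
    """Greedy left-to-right scan for C·x{9,10}·C with cysteine-free
    interiors; overlaps resolved by taking the leftmost match and resuming
    after its closing cysteine."""
    seq = protein.sequence
    inner_lengths = (9, 10) if allow_cx10c else (9,)
    out: list[CxMotif] = []
    i = 0
    while i < len(seq):
        if seq[i] != "C":
            i += 1
            continue
        matched = False
        for inner in inner_lengths:
            j = i + inner + 1
            if j < len(seq) and seq[j] == "C" and "C" not in seq[i + 1:j]:
                out.append(CxMotif(protein.id, i, inner, seq[i:j + 1]))
                i = j + 1
                matched = True
                break
        if not matched:
            i += 1
    return out


def scan_cx9c(protein: ProteinRecord,
              allow_cx10c: bool = False,
              min_spacer: int = 3,
              max_spacer: int = 50) -> TwinCxCall:
    """Find chained twin-Cx9C motifs in one protein.

    A candidate motif is retained only when the spacer to at least one
    neighbouring candidate lies within ``[min_spacer, max_spacer]`` —
    isolated Cx9C occurrences are noise, the CHCH fold requires the twin.
    Returns an empty call when nothing chains.
    """
    cands = _candidate_motifs(protein, allow_cx10c)
    keep = [False] * len(cands)
    for k in range(len(cands) - 1):
        spacer = cands[k + 1].start - cands[k].end
        if min_spacer <= spacer <= max_spacer:
            keep[k] = keep[k + 1] = True
    motifs = tuple(m for m, k in zip(cands, keep) if k)
    spacers = tuple(motifs[k + 1].start - motifs[k].end
                    for k in range(len(motifs) - 1))
    return TwinCxCall(protein.id, motifs, spacers)


@dataclass(frozen=True)
class AkScreenResult:
    protein_id: str
    flagged: bool
    ak_percent: float
    c_terminal_tail: str


def ak_composition_screen(protein: ProteinRecord,
                          threshold_pct: float = 60.0,
                          tail_window: int = 80) -> AkScreenResult:
    """Flag proteins whose Ala+Lys content strictly exceeds the threshold.

    Also reports the C-terminal ``tail_window`` residues, the region the
    HMG-box-like tail profile is matched against downstream.  X residues
    count toward the length denominator.
    """
    counts = Counter(protein.sequence)
    pct = 100.0 * (counts["A"] + counts["K"]) / protein.length
    return AkScreenResult(
        protein_id=protein.id,
        flagged=pct > threshold_pct,
        ak_percent=pct,
        c_terminal_tail=protein.sequence[-tail_window:],
    )


@dataclass(frozen=True)
class DomainFilterResult:
    """E-value-filtered hits with the two standard censuses."""

    hits: tuple[DomainHit, ...]
    #: (protein_id, profile_name) -> number of retained domains
    domain_counts: dict[tuple[str, str], int]
    #: profile_name -> number of proteins with ≥ 1 retained domain
    protein_counts: dict[str, int]


def filter_domain_hits(hits: Iterable[DomainHit],
                       max_evalue: float = 0.05) -> DomainFilterResult:
    """Retain hits with i-E-value ≤ ``max_evalue`` and tabulate them.

    Idempotent and order-independent: the retained hits keep input order,
    but the censuses depend only on the hit set.
    """
    if max_evalue <= 0:
        raise ValueError("max_evalue must be > 0")
    kept = tuple(h for h in hits if h.i_evalue <= max_evalue)
    domain_counts: Counter = Counter(
        (h.protein_id, h.profile_name) for h in kept)
    proteins_per_profile: dict[str, set[str]] = {}
    for h in kept:
        proteins_per_profile.setdefault(h.profile_name, set()).add(
            h.protein_id)
    return DomainFilterResult(
        hits=kept,
        domain_counts=dict(domain_counts),
        protein_counts={p: len(s) for p, s in proteins_per_profile.items()},
    )
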