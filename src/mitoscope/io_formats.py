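"""Readers and writers for the pipeline's external file formats.

External files use 1-based inclusive residue coordinates (the HMMER
convention); everything in memory is 0-based half-open.  Conversion happens
only here, at the I/O boundary, so span lengths are preserved and gap
arithmetic downstream never needs an off-by-one correction.

Formats handled: protein FASTA, HMMER3 ``--domtblout`` domain tables,
tab-separated predictor / quantification / secondary-structure tables with
mandatory headers, span (motif reference) tables, and the final per-protein
annotation table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ProteinRecord",
    "PredictorRow",
    "DomainHit",
    "QuantRecord",
    "StructureTrack",
    "FRACTIONS",
    "STRUCTURE_ALPHABET",
    "read_fasta",
    "write_fasta",
    "read_domtblout",
    "write_domtblout",
    "read_predictor_table",
    "write_predictor_table",
    "read_quant_table",
    "write_quant_table",
    "read_structure_table",
    "write_structure_table",
    "read_span_table",
    "write_span_table",
    "write_annotation_table",
    "read_annotation_table",
    "to_internal",
    "to_external",
]


class FormatError(ValueError):
    """A file violated the expected format or a record invariant."""


STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: non-standard one-letter codes collapsed to X on read
_AMBIGUOUS = str.maketrans({c: "X" for c in "BZUOJ"})

#: subcellular fractions of the MS experiment, in canonical column order
FRACTIONS = ("whole_cell", "cytosol", "mitochondria")

#: 8-state secondary-structure alphabet (DSSP-style, NetSurfP output)
STRUCTURE_ALPHABET = frozenset("HGIEBTSC")


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive span to 0-based half-open."""
    return start_1based - 1, end_1based


def to_external(span: tuple[int, int]) -> tuple[int, int]:
    """Convert a 0-based half-open span to 1-based inclusive."""
    return span[0] + 1, span[1]


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: accession plus amino-acid sequence.

    Non-standard residues are already mapped to X and a trailing stop ('*')
    stripped by the reader; X counts toward length and composition
    denominators.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_AA - {"X"}
        if bad:
            raise FormatError(
                f"protein {self.id!r}: non-amino-acid letters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PredictorRow:
    """Per-protein output of the three localization predictors.

    ``score_primary`` is the DeepLoc2-style mitochondrion probability,
    ``score_secondary`` the MULocDeep-style one (both already in [0, 1]);
    ``score_tertiary_raw`` is the WoLF PSORT-style unnormalized score, mapped
    into [0, 1] by ``min(1, raw / norm_constant_tertiary)``.  The assignment
    flags are the tools' own categorical calls and are required input — each
    tool's internal assignment rule is proprietary to the tool, so they are
    never re-derived from the scores.
    """

    protein_id: str
    score_primary: float
    assigned_primary: bool
    score_secondary: float
    assigned_secondary: bool
    score_tertiary_raw: float
    norm_constant_tertiary: float

    def __post_init__(self) -> None:
        for name in ("score_primary", "score_secondary"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or math.isnan(v):
                raise FormatError(
                    f"protein {self.protein_id!r}: {name}={v} outside [0, 1]"
                )
        if self.score_tertiary_raw < 0:
            raise FormatError(
                f"protein {self.protein_id!r}: negative tertiary score"
            )
        if self.norm_constant_tertiary <= 0:
            raise FormatError("norm_constant_tertiary must be > 0")

    @property
    def score_tertiary(self) -> float:
        """Tertiary score normalized into [0, 1], clamped at 1."""
        return min(1.0, self.score_tertiary_raw / self.norm_constant_tertiary)


@dataclass(frozen=True)
class DomainHit:
    """One profile-vs-protein domain hit.

    ``start``/``end`` are the envelope coordinates, 0-based half-open
    internally; ``env_start``/``env_end`` expose the file's 1-based
    inclusive view.  ``i_evalue`` is HMMER's independent E-value for this
    single domain, the statistic every downstream filter operates on.
    """

    protein_id: str
    profile_name: str
    start: int
    end: int
    i_evalue: float
    bit_score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"hit on {self.protein_id!r}: invalid span "
                f"{self.start}..{self.end} (half-open)"
            )
        if not (self.i_evalue > 0) or math.isnan(self.i_evalue):
            raise FormatError(
                f"hit on {self.protein_id!r}: i-Evalue must be > 0, "
                f"got {self.i_evalue}"
            )

    @property
    def env_start(self) -> int:
        return self.start + 1

    @property
    def env_end(self) -> int:
        return self.end

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class QuantRecord:
    """MS quantities for one protein across subcellular fractions."""

    protein_id: str
    spectral_counts: Mapping[str, int]
    ion_intensities: Mapping[str, float]
    in_complex_datasets: bool = False

    def __post_init__(self) -> None:
        if not self.spectral_counts and not self.ion_intensities:
            raise FormatError(
                f"protein {self.protein_id!r}: no fraction quantities"
            )
        for name, table in (
            ("spectral_counts", self.spectral_counts),
            ("ion_intensities", self.ion_intensities),
        ):
            for frac, v in table.items():
                if frac not in FRACTIONS:
                    raise FormatError(
                        f"protein {self.protein_id!r}: unknown fraction {frac!r}"
                    )
                if v < 0:
                    raise FormatError(
                        f"protein {self.protein_id!r}: negative {name} in {frac}"
                    )


@dataclass(frozen=True)
class StructureTrack:
    """Per-residue 8-state secondary-structure labels for one protein."""

    protein_id: str
    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - STRUCTURE_ALPHABET
        if bad:
            raise FormatError(
                f"structure track {self.protein_id!r}: labels outside "
                f"8-state alphabet: {sorted(bad)}"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into validated records, in file order.

    Trailing '*' (stop) is stripped; B/Z/U/O/J map to X; duplicate ids and
    residual non-amino-acid letters are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n = 0
    for n, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper().rstrip("*").translate(_AMBIGUOUS)
        if rec.id in seen:
            raise FormatError(
                f"{path}: record {n}: duplicate protein id {rec.id!r}"
            )
        seen.add(rec.id)
        try:
            records.append(ProteinRecord(rec.id, seq))
        except FormatError as e:
            raise FormatError(f"{path}: record {n}: {e}") from e
    if n == 0:
        raise FormatError(f"{path}: empty FASTA")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# HMMER3 domtblout

# column indices in a HMMER3 --domtblout row
_DT_TARGET, _DT_QUERY, _DT_IEVAL, _DT_SCORE = 0, 3, 12, 13
_DT_ENV_FROM, _DT_ENV_TO = 19, 20
_DT_MIN_COLS = 23


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 per-domain table into hits.

    Envelope ("env from"/"env to") columns define each hit's span; the
    i-Evalue column is the hit's independent E-value.  Malformed rows are
    reported with their line number.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DT_MIN_COLS:
                raise FormatError(
                    f"{path}: line {lineno}: expected ≥{_DT_MIN_COLS} "
                    f"columns, got {len(fields)}"
                )
            try:
                i_evalue = float(fields[_DT_IEVAL])
                bit_score = float(fields[_DT_SCORE])
                env_from = int(fields[_DT_ENV_FROM])
                env_to = int(fields[_DT_ENV_TO])
            except ValueError as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from e
            try:
                start, end = to_internal(env_from, env_to)
                hits.append(DomainHit(
                    protein_id=fields[_DT_TARGET],
                    profile_name=fields[_DT_QUERY],
                    start=start,
                    end=end,
                    i_evalue=i_evalue,
                    bit_score=bit_score,
                ))
            except FormatError as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from e
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path,
                    profile_length: int = 35) -> None:
    """Emit hits in the HMMER3 ``--domtblout`` dialect (one domain per row)."""
    header = (
        "#                                                               "
        "--- full sequence --- -------------- this domain -------------   "
        "hmm coord   ali coord   env coord\n"
        "# target name        accession   tlen query name           "
        "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
        "i-Evalue  score  bias  from    to  from    to  from    to  acc "
        "description of target\n"
    )
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.protein_id, []).append(h)
    with open(path, "w") as fh:
        fh.write(header)
        for pid, group in grouped.items():
            group = sorted(group, key=lambda h: h.start)
            tlen = max(h.end for h in group)
            for k, h in enumerate(group, start=1):
                s1, e1 = to_external(h.span)
                fh.write(
                    f"{h.protein_id:<20} -          {tlen:5d} "
                    f"{h.profile_name:<20} -          {profile_length:5d} "
                    f"{h.i_evalue:9.3g} {h.bit_score:6.1f}   0.0 "
                    f"{k:3d} {len(group):3d} {h.i_evalue:9.3g} "
                    f"{h.i_evalue:9.3g} {h.bit_score:6.1f}   0.0 "
                    f"{1:5d} {profile_length:5d} {s1:5d} {e1:5d} "
                    f"{s1:5d} {e1:5d} 0.90 -\n"
                )


# ---------------------------------------------------------------------------
# delimited tables

def _require_columns(df: pd.DataFrame, cols: Sequence[str],
                     path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(value, path, col) -> bool:
    if isinstance(value, (bool,)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise FormatError(f"{path}: column {col!r}: not a boolean: {value!r}")


PREDICTOR_COLUMNS = (
    "protein_id", "score_primary", "assigned_primary",
    "score_secondary", "assigned_secondary", "score_tertiary_raw",
)


def read_predictor_table(path: str | Path,
                         norm_constant_tertiary: float) -> list[PredictorRow]:
    """Read the three-predictor score table (TSV with mandatory header)."""
    if norm_constant_tertiary <= 0:
        raise FormatError("norm_constant_tertiary must be > 0")
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, PREDICTOR_COLUMNS, path)
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(PredictorRow(
            protein_id=rec.protein_id,
            score_primary=float(rec.score_primary),
            assigned_primary=_parse_bool(rec.assigned_primary, path,
                                         "assigned_primary"),
            score_secondary=float(rec.score_secondary),
            assigned_secondary=_parse_bool(rec.assigned_secondary, path,
                                           "assigned_secondary"),
            score_tertiary_raw=float(rec.score_tertiary_raw),
            norm_constant_tertiary=norm_constant_tertiary,
        ))
    return rows


def write_predictor_table(rows: Iterable[PredictorRow],
                          path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.protein_id, r.score_primary, r.assigned_primary,
             r.score_secondary, r.assigned_secondary, r.score_tertiary_raw)
            for r in rows
        ],
        columns=list(PREDICTOR_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


QUANT_COLUMNS = (
    "protein_id",
    "sc_whole_cell", "sc_cytosol", "sc_mitochondria",
    "ii_whole_cell", "ii_cytosol", "ii_mitochondria",
    "in_complex_datasets",
)


def read_quant_table(path: str | Path) -> list[QuantRecord]:
    """Read the protein × fraction MS quantification table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, QUANT_COLUMNS, path)
    records = []
    for rec in df.itertuples(index=False):
        records.append(QuantRecord(
            protein_id=rec.protein_id,
            spectral_counts={
                "whole_cell": int(rec.sc_whole_cell),
                "cytosol": int(rec.sc_cytosol),
                "mitochondria": int(rec.sc_mitochondria),
            },
            ion_intensities={
                "whole_cell": float(rec.ii_whole_cell),
                "cytosol": float(rec.ii_cytosol),
                "mitochondria": float(rec.ii_mitochondria),
            },
            in_complex_datasets=_parse_bool(rec.in_complex_datasets, path,
                                            "in_complex_datasets"),
        ))
    return records


def write_quant_table(records: Iterable[QuantRecord],
                      path: str | Path) -> None:
    rows = []
    for q in records:
        rows.append((
            q.protein_id,
            q.spectral_counts.get("whole_cell", 0),
            q.spectral_counts.get("cytosol", 0),
            q.spectral_counts.get("mitochondria", 0),
            q.ion_intensities.get("whole_cell", 0.0),
            q.ion_intensities.get("cytosol", 0.0),
            q.ion_intensities.get("mitochondria", 0.0),
            q.in_complex_datasets,
        ))
    pd.DataFrame(rows, columns=list(QUANT_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def read_structure_table(path: str | Path) -> list[StructureTrack]:
    """Read per-protein 8-state secondary-structure label strings."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("protein_id", "labels"), path)
    return [StructureTrack(r.protein_id, r.labels)
            for r in df.itertuples(index=False)]


def write_structure_table(tracks: Iterable[StructureTrack],
                          path: str | Path) -> None:
    pd.DataFrame(
        [(t.protein_id, t.labels) for t in tracks],
        columns=["protein_id", "labels"],
    ).to_csv(path, sep="\t", index=False)


def read_span_table(path: str | Path) -> list[tuple[str, tuple[int, int]]]:
    """Read a 3-column motif span table (protein_id, start, end; 1-based
    inclusive) into internal half-open spans."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("protein_id", "start", "end"), path)
    spans = []
    for lineno, rec in enumerate(df.itertuples(index=False), start=2):
        s1, e1 = int(rec.start), int(rec.end)
        if not (1 <= s1 <= e1):
            raise FormatError(f"{path}: line {lineno}: invalid span {s1}..{e1}")
        spans.append((rec.protein_id, to_internal(s1, e1)))
    return spans


def write_span_table(spans: Iterable[tuple[str, tuple[int, int]]],
                     path: str | Path) -> None:
    rows = [(pid, *to_external(span)) for pid, span in spans]
    pd.DataFrame(rows, columns=["protein_id", "start", "end"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# final annotation table

ANNOTATION_COLUMNS = (
    "protein_id", "wa_score", "penalized", "band", "band_odds",
    "detected_in_mito", "via_complex", "n_ppr_motifs", "n_cx9c_motifs",
    "ak_rich",
)


def write_annotation_table(calls, motifs, enrichment,
                           path: str | Path) -> None:
    """Join per-protein evidence into one deterministic annotation table.

    ``calls`` maps protein_id -> LocalizationCall, ``motifs`` maps
    protein_id -> dict with 'ppr'/'cx9c'/'ak_rich' entries, ``enrichment``
    maps protein_id -> EnrichmentCall; any of them may omit proteins.
    """
    ids: list[str] = []
    seen = set()
    for source in (calls, motifs, enrichment):
        for pid in source:
            if pid not in seen:
                seen.add(pid)
                ids.append(pid)
    rows = []
    for pid in sorted(ids):
        call = calls.get(pid)
        m = motifs.get(pid, {})
        e = enrichment.get(pid)
        odds = getattr(call, "band_odds", None) if call else None
        rows.append((
            pid,
            f"{call.wa_score:.6g}" if call else "NA",
            str(bool(call.penalized)) if call else "NA",
            call.band.label if call else "NA",
            ("inf" if odds == math.inf else f"{odds:.6g}")
            if odds is not None else "NA",
            str(bool(e.detected)) if e else "NA",
            str(bool(e.via_complex)) if e else "NA",
            int(m.get("ppr", 0)),
            int(m.get("cx9c", 0)),
            str(bool(m.get("ak_rich", False))),
        ))
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    if df["protein_id"].duplicated().any():
        dup = df.loc[df["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise FormatError(f"{path}: duplicate protein id {dup!r}")
    return df
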