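"""Deterministic sequence screens: twin-Cx9C motifs and Ala/Lys content.

Twin-Cx9C (CHCH-fold) proteins of the mitochondrial intermembrane space
carry chained C-x9-C cysteine pairs; Ala/Lys-rich proteins (> 60% A+K)
form an unusual family implicated in mitochondrial DNA metabolism.
"""

from mitoscope import motif_scan
from mitoscope.io_formats import DomainHit, ProteinRecord

# A twin-Cx9C protein in the style of an NDUFS5 subunit: two motifs
# separated by a 13-residue spacer.
chch = ProteinRecord(
    "ndufs5_like",
    "MLSTQV" + "CHMFKRSFNLC" + "ALDEGHIKNMLDE" + "CAIEKEDWYNC" + "GRKES",
)
call = motif_scan.scan_cx9c(chch, allow_cx10c=True)
print(f"{chch.id}: {len(call.motifs)} chained Cx9C motifs")
for motif, spacer in zip(call.motifs, call.spacers + (None,)):
    bracket = f" - [{spacer}] -" if spacer is not None else ""
    print(f"  {motif.motif_string} (start {motif.start_1based})"
          f"{bracket}")

ak = ProteinRecord("hmg_like", "MA" + "AK" * 60 + "GSGS" + "AAKK" * 10)
res = motif_scan.ak_composition_screen(ak)
print(f"\n{ak.id}: A+K = {res.ak_percent:0.1f}% -> "
      f"{'flagged' if res.flagged else 'not flagged'} "
      f"(strict > 60% rule); C-terminal 80-mer kept for tail-profile "
      f"matching ({len(res.c_terminal_tail)} aa)")

# Generic domain-table filtering, e.g. a mitochondrial-carrier census.
hits = [
    DomainHit("carrier1", "MC_carr", 10, 100, i_evalue=1e-12),
    DomainHit("carrier1", "MC_carr", 110, 200, i_evalue=3e-4),
    DomainHit("carrier2", "MC_carr", 5, 95, i_evalue=0.04),
    DomainHit("spurious", "MC_carr", 0, 90, i_evalue=0.8),
]
filtered = motif_scan.filter_domain_hits(hits, max_evalue=0.05)
print(f"\ndomain filter at E <= 0.05: {len(filtered.hits)} of "
      f"{len(hits)} hits kept; proteins with >= 1 MC_carr domain: "
      f"{filtered.protein_counts['MC_carr']}")
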