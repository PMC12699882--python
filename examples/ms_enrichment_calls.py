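"""Call 'detected in mitochondria' from fraction-wise MS quantities.

Shows the enrichment rule (mito:whole > cyto:whole and > 1.5), the
minimal-non-zero divisor substitution when a protein is missing from the
whole-cell lysate, the complex-association override, and iBAQ abundance.
"""

from mitoscope import ms_enrichment as ms
from mitoscope.io_formats import QuantRecord

quants = [
    QuantRecord("enriched", {"whole_cell": 10, "cytosol": 2,
                             "mitochondria": 20},
                {"whole_cell": 1e6, "cytosol": 2e5,
                 "mitochondria": 5e6}),
    QuantRecord("cytosolic", {"whole_cell": 10, "cytosol": 9,
                              "mitochondria": 9},
                {"whole_cell": 1e6, "cytosol": 9e5,
                 "mitochondria": 9e5}),
    QuantRecord("mito_only", {"whole_cell": 0, "cytosol": 0,
                              "mitochondria": 6},
                {"whole_cell": 0.0, "cytosol": 0.0,
                 "mitochondria": 9e5}),
    QuantRecord("in_respirasome", {"whole_cell": 5, "cytosol": 5,
                                   "mitochondria": 5},
                {"whole_cell": 5e5, "cytosol": 5e5,
                 "mitochondria": 5e5},
                in_complex_datasets=True),
]

floors = {m: ms.compute_floors(quants, m) for m in ms.METRICS}
print(f"divisor floors: spectral counts = "
      f"{floors['spectral_counts'].floor:g}, ion intensity = "
      f"{floors['ion_intensity'].floor:g}")

print("\nenrichment calls (either metric may fire):")
for q in quants:
    call = ms.combined_call(q, floors)
    note = " (whole-cell divisor substituted)" if \
        call.divisor_substituted else ""
    note += " (via complex association)" if call.via_complex else ""
    print(f"  {q.protein_id:<15} mito:whole={call.ratio_mito:7.2f} "
          f"cyto:whole={call.ratio_cyto:5.2f} "
          f"detected={call.detected}{note}")

seq = "MAAAAAAKLLLLLLRWDDDDDDKPEEEEEEK"
result = ms.ibaq(2.4e6, seq, protein_id="demo")
print(f"\niBAQ: intensity 2.4e6 over {result.n_peptides} observable "
      f"tryptic 7-30mers = {result.value:g}")
print("The iBAQ value approximates molar abundance: summed intensity "
      "normalized by the\nnumber of peptides the mass spectrometer could "
      "in principle have seen.")
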