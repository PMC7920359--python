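"""Simulate barcode reads with errors and sweep the mismatch tolerance.

Draws 20,000 reads from a 16-barcode pool with a per-cycle substitution
rate that rises across the barcode cycles (barcodes are read in the last
— noisiest — cycles of a run), then decodes the same reads at mismatch
tolerances 2, 3 and 4.
"""

from bcbalance import (
    ErrorModel,
    WeightedBarcodeSet,
    make_random_panel,
    run_mismatch_sweep,
)

panel = make_random_panel(16, L=10, min_distance=4, seed=12)
wset = WeightedBarcodeSet.equal(panel.ids)
em = ErrorModel.ramp(0.005, 0.03)

rows = run_mismatch_sweep(wset, panel, 20_000, em, seed=0,
                          m_values=[2, 3, 4])
print("m  correct  misassigned  undecoded  %undecoded  %rescued")
for row in rows:
    s = row.stats
    print(f"{s.m}  {s.n_correct:7d}  {s.n_misassigned:11d}  "
          f"{s.n_undecoded:9d}  {s.frac_undecoded:9.3%}  "
          f"{row.rescued_vs_first:8.1%}")

print("\nRaising the tolerance rescues undecoded reads but starts "
      "assigning reads that sit close to two barcodes at once — with "
      "d_min=4, tolerances above 2 risk connecting samples, which is "
      "why 2 is the recommended default.")
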