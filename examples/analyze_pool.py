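"""Analyze the color balance of a pooled barcode set.

Builds an exactly balanced 8-barcode panel, pools it first at equal
proportions and then at 1:4:1:4:... shares, and prints the per-position
nucleotide fractions with the strong/lite verdicts.  At equal shares
every fraction is 0.25 (PASS); skewed shares push fractions off 0.25 and
can fail the strong corridor.
"""

from bcbalance import (
    WeightedBarcodeSet,
    analyze_set,
    make_balanced_set,
)

panel = make_balanced_set(8, L=10, seed=7)

for label, weights in [("equal shares", None),
                       ("1:4 alternating shares", [1, 4] * 4)]:
    wset = WeightedBarcodeSet(panel.ids, weights or [])
    report = analyze_set(wset, panel)
    print(f"\n== {label} ==")
    print("pos  " + "  ".join(f"{b}     " for b in "ACGT"))
    for p in range(panel.L):
        row = "  ".join(f"{v:.3f}" for v in
                        report.fraction_matrix.values[p])
        print(f"{p + 1:>3}  {row}")
    for v in report.verdicts:
        word = "PASS" if v.passed else "FAIL"
        print(f"{v.criterion.name}: {word} (outside={v.n_outside}, "
              f"max deviation {v.max_deviation:.3f})")

print("\nA fraction of 0.25 means all four fluorophore channels are "
      "equally represented at that cycle; the strong corridor rejects "
      "any position drifting far from it.")
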