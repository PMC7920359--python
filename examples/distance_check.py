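"""Pairwise distances and mismatch-tolerance safety of a pool.

Generates a 24-barcode panel with minimum pairwise Hamming distance 4
(the spacing of typical vendor panels) and checks whether decoding with
up to 2 mismatches is safe.
"""

from bcbalance import decodability_check, hamming_matrix, make_random_panel

panel = make_random_panel(24, L=10, min_distance=4, seed=3)
dm = hamming_matrix(panel)
print(f"{len(panel)} barcodes, d_min={dm.d_min} "
      f"(pair {dm.argmin_pair}), d_max={dm.d_max}")

report = decodability_check(panel, m=2)
print(f"no-merge condition (m < d_min): {report.no_merge_ok}")
print(f"unique-decode guarantee (d_min >= 2m+1): {report.unique_decode_ok}")
print(f"pairs at ambiguity risk: {len(report.ambiguous_risk_pairs)}")

print("\nWith d_min=4 and m=2, two read errors can never turn one "
      "barcode into another (no merging), but a read midway between a "
      "distance-4 pair ties and must be discarded as ambiguous — the "
      "unique-decode guarantee needs d_min >= 5.")
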