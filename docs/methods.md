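# Methods

## Model

A barcode pool is a weighted set of fixed-length ACGT sequences drawn
from a panel. The central quantity is the weighted per-position
nucleotide fraction

    f(p, b) = sum_i w_i * [seq_i[p] = b] / sum_i w_i,

an L × 4 row-stochastic matrix. It models the channel occupancy of each
barcode sequencing cycle on a synchronous-read flow cell: when one base
is overrepresented at a cycle, the signal-to-noise separation of the
four channels collapses and basecalling at that cycle becomes
unreliable. The fraction matrix is invariant to rescaling all weights,
so weights can be given on any convenient scale (molarities, share
ratios such as 9:9:9:9:5:5:5:5:5:5, or normalized fractions).

Balance is judged by a *criterion*: a corridor `[lower, upper]`
bracketing 0.25, a border tolerance, and an allowed number of violating
positions. A cell is **outside** when `f < lower − border_tol` or
`f > upper + border_tol`, **border** when within `border_tol` of either
bound, **inside** otherwise; a *position's* status is the worst of its
four cells (violating positions are counted, not cells, because a cycle
fails as a whole). The verdict passes when the number of outside
positions is at most `max_outside`.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| strong corridor | [0.15, 0.35] | tight band modelled on vendor-approved sets |
| lite corridor | [0.05, 0.45] | empirical instrument tolerance |
| `border_tol` | 0.01 | width of the "on the border" band; exact float equality with a bound is meaningless |
| `max_outside` | 0 | violating positions allowed; up to 2 is defensible in expert use, but since read failures have causes beyond imbalance the default refuses any violation |
| mismatch tolerance `m` | 2 | demultiplexing mismatch cap; values above 2 risk connecting samples on distance-4 panels |
| barcode length `L` | 10 | a panel property, not a constant — taken from the panel file |

The corridor intercepts are design choices, not measured constants: the
tight and wide bands are documented in the source material only as
plot lines, never as printed numbers. The package therefore treats both
corridors as configuration (TOML, `load_criterion`/`dump_criterion`)
and offers the faithful derivation path instead:
`derive_corridor_from_sets` computes the `[min, max]` envelope of the
fraction matrices of user-supplied reference sets (e.g. the
vendor-approved combination sets), which is how a tight corridor is
obtained from sets known to sequence well. A single perfectly balanced
reference yields the degenerate corridor `[0.25, 0.25]` with
`border_tol` 0.

Positions are reported 1-based everywhere users see them; text reports
round fractions to 3 decimals while JSON carries full precision.

## Distances and decodability

Distances are substitution-only Hamming: barcodes are read in
fixed-length synchronous cycles, so insertions and deletions cannot
occur between cycles. Two safety conditions are reported side by side
for a mismatch tolerance m:

* **no-merge**, `m < d_min`: no error pattern of weight ≤ m can convert
  one pool barcode into another;
* **unique-decode**, `d_min ≥ 2m + 1`: every read with ≤ m errors has a
  unique nearest barcode within m (the standard minimum-distance
  decoding bound).

A distance-4 panel at m = 2 satisfies the first but not the second:
reads equidistant from a distance-4 pair tie at 2 and must be dropped.
Both conditions list their violating pairs so the user sees exactly
which barcodes to separate.

## Decoder and simulator

The decoder assigns a read to the unique member at minimal Hamming
distance ≤ m; it returns UNDECODED when nothing is within m **or** when
two members tie at the minimal distance (ambiguous). Ties are never
broken arbitrarily — an arbitrary assignment would silently merge two
samples, which is worse than losing the read. By default only the
pooled set's members are scanned; `scan_panel=True` scans the whole
panel, since restricting the reference list barely changes the
undecoded share but does change what counts as a misassignment.
Decoding is vectorized in numpy over blocks of 8,192 reads.

The simulator draws each read's source barcode from the normalized
weights and substitutes each position independently with probability
taken from the error model: `uniform` (constant q) or `ramp` (linear
from `q_start` to `q_end` across positions), the latter reflecting that
the per-cycle error rate rises toward the end of a run — where barcode
cycles sit. The substituted base is uniform over the three
alternatives. A single `numpy.random.default_rng(seed)` drives member
choice, error placement and substitution, so output is byte-identical
per seed. The mismatch sweep decodes *one* simulated read set at every
tolerance, so rows differ only in the tolerance; `rescued_vs_first` is
the fraction of the first tolerance's undecoded reads recovered.

What the simulator does *not* emulate: correlated errors between
cycles, quality-score information, index hopping, phasing/prephasing,
or the absolute undecoded rates of a real run (which depend on cluster
density and chemistry). Passing simulation tests therefore demonstrates
the decoder's combinatorial correctness and the direction of the
tolerance trade-off, not real-run percentages.

## Synthetic panels

`make_balanced_set(n, L, seed)` builds each position as a shuffled
multiset of n/4 copies of every base, so the equal-weight fraction
matrix is exactly 0.25 everywhere by construction (n must be a multiple
of 4); duplicate sequences are regenerated. `make_random_panel(n, L,
min_distance, seed)` rejection-samples sequences until all pairwise
distances reach `min_distance`, with an attempt cap that turns
infeasible requests into a clear error. Generated panels emulate the
two structural properties of real vendor panels that the method depends
on — the existence of exactly balanced sub-sets and a minimum pairwise
distance of 4 at length 10 — and nothing else (real panels are also
screened for synthesis and GC constraints, which are out of scope).

## Set completion

`complete_set` searches for k pool barcodes whose addition keeps the
combined set within a criterion. Candidates are ranked by the
lexicographic score `(n_outside, max |f − 0.25|, RMS deviation)`; lower
is better and `(0, 0, 0)` is a perfect pool. All C(|pool|, k)
combinations are enumerated when that count is ≤ 100,000 (C(96, 3) ≈
143k already exceeds this, C(96, 4) explodes); above the cap a
deterministic greedy beam search (width 64) extends partial selections
scored with the first few new weights, and the result is flagged
`exhaustive=False`. When the new weights are unequal, the
weight-to-barcode pairing changes the fraction matrix, so all k!
assignments are scored exactly for k ≤ 5 and a greedy pairing is used
beyond. All tie-breaks are lexicographic on barcode ids in panel/file
order, making ranked output fully deterministic. A failed search
returns the best near-miss with its offending positions so the user can
relax to the lite corridor or raise `max_outside`.

## Numerical choices and degenerate inputs

* Row-stochasticity of fraction matrices is validated to 1e-9; weights
  are validated strictly positive.
* A single-barcode distance matrix has undefined `d_min`/`d_max`
  (`None`), not an error — but decodability of a singleton is trivially
  safe.
* Corridor bounds are inclusive of 0.25 on both sides so that derived
  degenerate corridors are representable.
* Lowercase input sequences are uppercased silently; any non-ACGT
  character (including IUPAC ambiguity codes) is a hard error with the
  offending id and 1-based position, because the fraction computation
  counts exact identities.
* Reverse complements are never taken: barcodes are compared in the
  written orientation only.

## Problem sizes

The test suite and the reproduction script run at desk scale: balanced
panels of 4–16 barcodes, random panels up to 96, 20k–50k simulated
reads, selection problems with pools ≤ 12 and k ≤ 3 checked against
exhaustive enumeration oracles. These sizes were chosen to make every
stochastic check decisive (e.g. chi-square at n = 100k for weight
proportionality) while keeping a full run in well under a minute.

## Known limitations

* The shipped corridor intercepts are defaults, not vendor truth;
  regenerate the strong corridor from your vendor's approved sets.
* Beam search is heuristic: above the exhaustive cap the top candidate
  may be suboptimal (never invalid — every returned candidate passes).
* No modelling of lane-level effects (index hopping, cluster density)
  or of per-cycle quality metrics themselves; the corridor is a proxy
  validated against their degradation, not a predictor of them.
* One pool per invocation; multi-lane pooling optimization is out of
  scope.
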