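# Methods

## Problem and recurrence

`gedmatch` decides *k*-mismatch matches under a weighted edit distance.  For
input `X` (length *i*) and pattern `Y` (length *j*) the prefix distances fill
an `(i+1) × (j+1)` matrix `D` with `D[0][0] = 0`, boundary row/column equal to
cumulative insertion/deletion costs, and interior cells equal to the minimum
over the three operator terms (substitution from the diagonal predecessor,
deletion from above, insertion from the left).  `X` matches `Y` iff
`D[i][j] ≤ k`.  Only distances are computed; no alignment traceback is kept.

All shipped cost models satisfy `substitution(x, x) = 0`, symmetric
substitution, and finite positive indel costs.  The shape metric's indel cost
depends on the pattern length, so the resulting distance is deliberately not
symmetric under swapping input and pattern; all other shipped metrics are
true metrics on strings.

## Engines and thresholded semantics

`vertical` and `diagonal` fill the complete matrix (column-major versus
anti-diagonal order) and are bit-identical to each other; they are the
reference implementations.  The three thresholded engines share one
semantics:

* any computed cell with value `≤ k` equals the exact distance;
* any cell stored as the `OVER_K` sentinel, or with value `> k`, is an upper
  bound — computed values never underestimate, because each cell's minimum is
  taken over a subset of its predecessors.

`cellwise` visits every interior cell in vertical order but evaluates an
operator only when its predecessor cell is `≤ k`.  This engine is exact for
*every* cost model: the decision always equals thresholding the full DP.

`diag-skip` walks anti-diagonals `a + b = t` from the upper-right cell
downward, guided by the pruning register — one bit per pattern column, bit 0
(the boundary column) always set, and a bit may only be set when its left
neighbour already is, so set bits always form a prefix of columns.  At each
cell: if the current column's bit is set, the rest of the traversal is
abandoned (`break`) and those cells are counted as skipped; if the left
column's bit is set (and the cell is not in column 1), the insertion term is
dropped, since its predecessor lies in a pruned column; after computing the
cell, its column's bit is set when the value exceeds `k` and the left bit is
set.  Column 1 always uses the full three-way minimum: column 0 holds valid
boundary values that may well be `≤ k`, so excluding them would be unsound —
its register bit being set is an initialization convention, not a claim about
boundary cells.  Once the last column's bit is set no cell of that column can
come in under `k`, so the engine may stop early (default when the caller does
not request the matrix).

`diag-skip2` adds per-operator predecessor checks against `k`; a cell with no
admissible operator becomes `OVER_K`.  It computes the same decisions as
`diag-skip` with fewer cost-function evaluations, at the price of three extra
comparisons per cell — worthwhile exactly when the cost functions are
expensive.

### When is the register exact?

The register's inductive claim — "every remaining cell of a pruned column
exceeds `k`" — is self-sustaining for columns ≥ 2 (all of a pruned cell's
out-of-column predecessors lie in the previously pruned column), but its base
case rests on column 1 values never dipping back below `k` once they exceed
it.  Down column 1,

```
D[a+1][1] − D[a][1] ≥ deletion − max substitution
```

so the register is **exact whenever every substitution cost is at most the
indel cost**.  The Levenshtein metric (1 ≤ 1) and the shape metric at
realistic pattern lengths (max substitution `C/2.13 ≈ 0.47` versus indel
≥ `1/e · e^{L̄/j}`, which stays above 0.47 for `j ≲ 4·L̄`) satisfy this.  The
keyboard metric (max key distance 9.0 versus mean-distance indel ≈ 4.43) and
substitution tables with entries above the indel cost do not: there the
register can over-prune, and the skipping engines may miss a true match.

The error is one-sided in every case: computed values never underestimate, so
a **reported match is always a true match** and its distance is exact; only
false rejections are possible, and empirically they are rare (no decision
flips in 10⁴ random keyboard-metric runs; isolated flips observed with the
high-substitution table metric).  Applications that need exact decisions with
such metrics should use `cellwise` (still prunes operator evaluations, exact
for any model) or rescale indel costs; the test suite asserts exactness for
the compliant metrics and one-sidedness for all of them.

### Numerical choices

Costs are IEEE doubles; the threshold comparison is a strict `value > k` with
no epsilon, matching the pruning rule literally — users with cost tables that
place values exactly at `k` should be aware that ties count as matches
(`≤ k`).  The `OVER_K` sentinel is `inf`; predecessor checks treat it as
over-threshold and it never enters cost arithmetic.  `k = 0` performs exact
matching; empty input or pattern degenerates to pure boundary costs.  Cell
ties between operators need no tie-break because only the minimum value is
kept.  Matrix dumps print the sentinel as `INF`.

## Cost models

* **Levenshtein** — all operators cost 1; the baseline and the metric of the
  worked examples.
* **Shape** — `substitution(x, y) = C / s(x, y)` from a table of glyph
  similarities `s > 0`; `C > 0` (default 1.0) is a free scale, so only cost
  ratios are meaningful (e.g. `s('a','b') = 2.13`, `s('o','e') = 4.13` makes
  the a/b confusion 1.94× dearer).  Deletion and insertion share
  `exp(L̄/j)/e` with `L̄` the average word length (default 9.4 characters)
  and `j` the current pattern's length, evaluated once per pattern: the cost
  is 1 at average length, higher for short patterns, and decays toward `1/e`.
  Pairs missing from the table default to the smallest similarity present
  (i.e. the largest cost) — the conservative choice; a strict mode errors
  instead.  The shipped sample table carries only the two quantified pairs;
  full-alphabet tables are user-supplied TSV.
* **Keyboard** — `substitution = scale · ‖pos(x) − pos(y)‖₂` on a US QWERTY
  letter layout with rows at `y = 0, 1, 2` and horizontal stagger 0, 0.25,
  0.75 key pitches, so horizontally adjacent keys are exactly 1 pitch apart
  (`q`–`w` costs 1.0).  The layout is replaceable via a `char x y` TSV.
  Indel cost defaults to the layout's mean pairwise key distance — a
  mid-range cost, one constant for both operators to keep the metric
  symmetric.  Characters absent from the layout cost the maximum key
  distance by default (strict mode errors).
* **Table** — arbitrary symmetric pair table with constant or per-character
  indels; with an empty table and unit defaults it reproduces Levenshtein
  exactly, and setting all substitutions to twice the deletion cost realizes
  the classic 2:1 weighting.

Inputs are lowercased by default (CLI flag to disable).  Cost tables are
three-column TSV with `#` comments; parse errors name the offending line.

## Skip accounting

Each interior cell owes up to three operator evaluations.  A cell skipped by
a traversal `break` (or never reached after early termination) avoids all
three; a register-dropped insertion or a predecessor-checked operator avoids
one.  The combined skip ratio is therefore

```
(3·skipped_cells + skipped_insertion_ops + skipped_operator_evals) / (3·i·j)
```

Raw counts are always reported alongside the ratio so any alternative
normalization can be formed.  On random word pairs the ratio falls
monotonically in `k` — pruning is front-loaded at small thresholds.

## Synthetic data

The generator emulates a natural-language dictionary's length profile: word
lengths ~ Normal(mean 9.4, sd 2.90), rounded, truncated at 1 (the truncation
affects < 0.2% of draws at these defaults); characters i.i.d. uniform over
the alphabet (`a–z` default, `acgt` preset).  Divergence is controlled by a
fixed edit count or a per-character mutation rate, with uniformly chosen
substitution/insertion/deletion operations (substitutions always change the
character; a deletion drawn on an empty string becomes an insertion).

What this does *not* model: real word-frequency and character-frequency
structure, correlated typos, homoglyph or phonetic confusions, and
sequencing-error profiles.  Passing tests on this generator demonstrate
algorithmic correctness and the qualitative skip-ratio trend, not
application-level accuracy on real dictionaries.

`oracle_distance` is an independent memoized recursion over prefix pairs,
sharing only the cost-model interface with the engines; it is guarded to
`len(X)·len(Y) ≤ 10,000` and serves as the ground truth in the equivalence
tests.

## Test problem sizes

The equivalence and soundness suites run 1,000 seeded pairs per cost model at
lengths ≤ 12 over 4- and 26-letter alphabets, 1,000 seeded `(X, Y, k)` triples
for pruning soundness and decision equivalence, 300 triples for the metric
axioms, and a fixed 1,000-pair set at dictionary-profile lengths for the
`k = 1..8` sweep.  These sizes keep the whole suite under a minute while
exercising every boundary case (empty strings, `k = 0`, single characters).

## Known limitations

* The register engines are exact only under the substitution ≤ indel
  condition above; otherwise decisions are conservative (one-sided).
* Pruning is one-sided by construction: only the left (low-column) region is
  ever skipped; over-threshold cells in the upper-right region are computed.
* No banded/bit-parallel algorithms, no transposition operator, no
  sliding-window scanning of long texts, and no wall-clock benchmarking —
  performance is reported as operation counts, which are hardware-independent.
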