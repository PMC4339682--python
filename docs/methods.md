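# Methods

## Model

`rkalign` aligns known RNA secondary structures that may contain
pseudoknots.  A structure is a sequence over {A, C, G, U, N} with a set of
disjoint base pairs `(i, j)`, `i < j`, 1-based; crossing pairs
(`i < u < j < v`) are allowed and are the point of the tool.  The alignment
unit is the *element*: a single unpaired base, or a whole base pair.  A
single base is never aligned with a base pair.  Reducing a structure to its
element sequence (pairs anchored at their right base for prefix-order
traversal, at their left base for suffix-order traversal) turns the
positional skipping rules of the dynamic programs — never visit a cell at
the non-anchor base of a pair — into a property of the sequence rather than
a per-cell special case.

### Partition functions

Alignments of two element sequences are weighted by
`exp(score/T)` per matched element and `exp(gap/T)` per gapped element.
Three log-space DPs share one engine:

* forward `Z[c,d]` over prefix element sequences;
* backward `Z'[c,d]` over suffix element sequences (left-anchored order —
  this is *not* the mirror image of the forward order when pairs are
  present, and the two orders give genuinely different restricted sums);
* inside `Z''` over the interior of an aligned pair anchor
  `((i,j),(p,q))`, excluding pairs whose partner leaves the interior.

Each cell is the sum of three states (match, gap-B, gap-A) whose recursions
each sum all three predecessor states.  The partition function is therefore
a sum over monotone edit paths of the element grid: two gap runs in
different interleavings are distinct paths and are counted as such.  The
brute-force oracle in the test suite enumerates exactly this path set, so
DP/oracle equivalence is well-posed.  Boundary cells are pure gap products
with `Z[0,0] = 1`; cells with no legal alignment carry log-weight `-inf`.

### Posteriors

The posterior of a same-kind element line is the product of the restricted
prefix, interior and suffix partition functions and the line's Boltzmann
weight, over `Z[m,n]`.  For single bases the interior factor is 1.  Two
consequences worth knowing:

* Crossing pairs excluded from a restricted region are neither matched nor
  gapped there; each gets its own posterior entry instead, so no same-kind
  element pair is missed.
* The values are **not** normalized: excluded elements (crossing pairs,
  and pairs enclosing a single-base line) remove weight from the numerator
  only, so absolute values shrink with structural depth and can also exceed
  1 in shallow self-comparisons.  No renormalization or clamping is
  applied; the decoder and the guide tree consume only the ranking, and the
  expected accuracy `sum(posteriors)/max{h,k}` is used comparatively.

### Decoding, metrics, multiple alignment

The greedy decoder sorts all candidate lines by (posterior desc, A-anchor
asc, B-anchor asc) — a total order, so output is deterministic — and
accepts a candidate iff its elements are unused and six non-crossing
biconditionals hold against every accepted line (singles as degenerate
pairs `i = j`).  The biconditionals permit interleaved pseudoknot
pair-lines; they are exactly equivalent to joint monotonicity of the
nucleotide-level endpoint matches, which the test suite verifies by
exhaustive enumeration of orderings.  Because accepted line sets are
monotone at nucleotide resolution, column layout is a plain monotone merge;
unmatched positions are emitted left-most, A-side before B-side, between
consecutive matches.  The layout rule affects gap placement but not which
elements are matched.

Base mismatch: percentage of columns (gap columns included in the
denominator) pairing a single base with a paired base or a nucleotide with
a gap.  A left base aligned with a right base of another pair is *not* a
base mismatch under this definition.  Stem mismatch: stems are maximal
stacked runs; a stem matches a partner iff the alignment connects the two
exclusively (neither touches a third stem) and pair-coherently (one base of
a pair aligned into a partner pair forces the partner bases to align).
Both members of a matched stem pair count toward the matched fraction, so
self-alignment scores 0%.

Multiple alignment is progressive over an average-linkage guide tree built
from pairwise expected accuracies (ties broken by smallest leaf index
pair).  A profile is a column structure; a profile element is a pair
element iff at least one member contributes a pair there, and a member
without a pair at a pair element contributes gaps in both of its columns.
Profile-element posteriors are member-level posteriors summed over the full
cluster-size product `|A'||B'|` (members with gaps contribute zero to the
sum but stay in the denominator).  Merged columns are never rearranged at
later merges ("once a gap, always a gap").

## Parameters

| parameter | default | meaning |
|---|---|---|
| `T` | 1.0 | temperature of the Boltzmann weights; with RIBOSUM log-odds scores, `T = 1` makes weights pure exponentials of log-odds.  Scaling all scores and `T` together is a no-op on posteriors. |
| `gap_base` | −2.0 | log-odds penalty for gapping a single base |
| `gap_pair` | −4.0 | penalty for gapping a whole pair; twice `gap_base` because a pair deletes two nucleotides |
| matrices | RIBOSUM85-60 | shipped as a plain-text file; `--matrix` substitutes any symmetric 4×4 + 16×16 table.  `N` scores as the uniform mean over concrete bases. |

Published uses of this posterior-decoding scheme do not disclose their `T`
or gap values; the defaults above are the package's own calibration and all
tested behavior (oracle equivalence, decoder sanity, metric values on
synthetic data) holds identically under rescaling.

## Synthetic data

The generator draws pseudoknot-free, H-type (two crossing stems, ABAB) and
recursive (H-type scaffold plus a nested hairpin inside the spanned region)
structures: stem sizes 3–6 pairs, lengths 30–70 nt (50–90 nt for recursive,
which needs room for the extra hairpin), minimum loop 3 nt, paired
positions filled with canonical/wobble dinucleotides.  Homologs mutate each
element at 10% with 70% of pair mutations compensatory.  These magnitudes
mirror small curated pseudoknots and covarying homologous families.  What
the generator does *not* emulate: thermodynamic plausibility of loop
sequences, family-specific conservation profiles, non-canonical pairs, and
length heterogeneity beyond the configured range — so passing tests
demonstrate algorithmic correctness and qualitative behavior (homologs
align far better than unrelated structures), not benchmark-level accuracy
on real databases.

## Numerical choices

* All partition arithmetic in log space with `logaddexp` over
  anti-diagonals (vectorized); verified finite for structures of 1,553 nt,
  the longest length exercised.
* DP/oracle agreement demanded at relative error ≤ 1e−9 on enumerable
  sizes; observed agreement is ~1e−15.
* The pseudoknot-type classifier calls a structure H-type iff exactly two
  stems participate in the crossing relation and no further stem nests
  strictly inside their spanned region; anything else crossing is
  recursive.  This is an operational definition chosen here; the
  literature's usage is informal.
* Complexity is measured in DP cell updates, not wall time.  On structures
  with a length-proportional number of pairs the log-log slope of updates
  versus length over 20–200 nt is ≈ 3.9, consistent with the `O(m²n²)`
  bound (the asymptote is 4; the O(mn) prefix/suffix tables still weigh in
  at the short end).

## Known limitations

* The decoder is a greedy heuristic: on adversarial posteriors it can fall
  short of the optimal expected accuracy (observed mean ≥ 0.99 of optimal
  on exhaustively solvable instances).
* Posterior magnitudes are comparative only (see above); do not read them
  as probabilities of correctness.
* Base triples and higher-order interactions are out of scope: a base
  belongs to at most one pair.
* Column layout between matched elements is a convention; gap counts in
  written alignments depend on it even when the matched element set is
  identical.
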