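# rkalign

Structural alignment of **pseudoknotted RNA secondary structures**.

Most RNA alignment tools either ignore pseudoknots or fold-and-align
sequences whose structures are unknown.  `rkalign` addresses the complementary
problem: two (or more) structures are already *known* — sequence plus base
pairs, with crossing pairs allowed — and the task is to align them with each
other, using both sequence and structure information.  Typical users are
people curating or querying pseudoknot databases who need pairwise or
multiple alignments of experimentally determined structures.

## Method

A structure is reduced to its **elements**: single (unpaired) bases and whole
base pairs.  Aligning a single base with a base pair is prohibited.  Element
matches are scored with the RIBOSUM85-60 log-odds matrices (4×4 for bases,
16×16 for ordered dinucleotides), so compensatory base changes in stems score
well; gaps cost `g_base` per single and `g_pair` per pair.

For structures *A* (length *m*) and *B* (length *n*), three partition
functions are computed by dynamic programming over element sequences, with
Boltzmann weights `e^{score/T}`:

* `Z_{c,d}` — over all alignments of the prefixes `A[1,c]`, `B[1,d]`
  (pairs visited at their right base);
* `Z'_{c,d}` — over suffix alignments (pairs visited at their left base);
* `Z''` — over the interiors of a fixed aligned pair `(i,j) ~ (p,q)`.

Each DP cell splits into match / gap-B / gap-A states and one table costs
*O(mn)* cell updates.  The posterior score of aligning element `(i,j)` of *A*
with `(p,q)` of *B* is

```
Prob((i,j) ~ (p,q)) = Z_{i-1,p-1} · Z''_{j-1,q-1} · Z'_{j+1,q+1} / Z_{m,n} · e^{score((i,j),(p,q))/T}
```

with the interior factor defined as 1 for single bases.  Base pairs that
cross out of a restricted region are excluded from that region's element
sequence; each still receives its own posterior entry, so crossing
(pseudoknotted) pairs are aligned on exactly the same footing as nested ones.
Computing all posteriors costs *O(m²n²)* time and *O(mn)* space.

The decoder greedily accepts alignment lines in descending posterior order,
subject to one-to-one use of elements and six non-crossing biconditionals
(which deliberately allow two pseudoknot pair-lines to interleave).  The
expected accuracy of an alignment is the sum of its line posteriors divided
by `max{h, k}`, the larger element count.  Multiple alignment is progressive:
pairwise expected accuracies drive an average-linkage guide tree, and
profiles are merged with the same decoder using member-averaged posteriors.

Alignment quality is reported as the **base_mismatch ratio** (percentage of
columns pairing a single base with a paired base, or a nucleotide with a
gap) and the **stem_mismatch ratio** (percentage of maximal stems without an
exclusive, pair-coherent partner stem).

## Worked example

Generate a small H-type pseudoknot, make a homolog, align:

```
$ rkalign synth --topology h-type --length 40 --seed 5 --out a.dbn
$ cat a.dbn
>synth_h-type_5
GGUGCAAAACCUGUAAUGCACCAGUGUAGGUAC
(((((...[[[[[[...)))))...]]]]]]..

$ rkalign pair a.dbn b.dbn --json
# STOCKHOLM 1.0
synth_h-type_5         GGUGCAAAACCUGUAAUGCACCAGUGUAGGUAC
#=GR synth_h-type_5 SS (((((...[[[[[[...)))))...]]]]]]..
synth_homolog          GGUGCAAAACCUGUAAUGCACCAGUGUGGGUAC
#=GR synth_homolog SS  (((((...[[[[[[...)))))...]]]]]]..
//
{
  "expected_accuracy": 0.09019364653282116,
  "base_mismatch_percent": 0.0,
  "stem_mismatch_percent": 0.0,
  "gaps": 0
}
```

Both bracket layers of the pseudoknot survive in the per-record Stockholm
`SS` lines.  The two stems and every loop base are aligned one-to-one:
no base mismatches, no stem mismatches, no gaps.  Expected-accuracy values
are comparative, not probabilities: restricted partition functions drop
pair elements that enclose or cross a line's region, so absolute magnitudes
shrink with structure depth while the *ranking* of candidate lines — which
is all the decoder and the guide tree use — is unaffected.

Other subcommands: `rkalign multi s1.dbn s2.dbn s3.dbn --dump-tree t.nwk`,
`rkalign metrics aln.sto`, `rkalign classify a.dbn` (prints `none`,
`H-type` or `recursive`).  Inputs may be extended dot-bracket, BPSEQ or CT;
`--temperature`, `--gap-base`, `--gap-pair` and `--matrix` override the
scoring model.

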