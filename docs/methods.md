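# Methods

## Representation and annotation

Structures enter as pseudoknot-free dot-brackets (`.dbn`), as bpRNA-style
`.st` files whose structure-array line is read directly, or as bare
structure-array strings. The annotator converts dot-brackets to structure
arrays by stack matching followed by standard loop decomposition: paired
positions become `L`/`R`; each maximal unpaired run is classified by its
nearest enclosing pair — no enclosing pair gives `E` at the termini and
`X` strictly between exterior helices; an enclosing loop with zero branch
helices gives `H`, one branch gives `B` (one unpaired side) or `I` (both
sides), and two or more branches give `M`.

Annotation corner cases were genuinely open and are resolved as follows:
lone pairs count as helices for branching (no minimum helix length);
no minimum hairpin size is enforced at annotation time (`()` yields a
zero-length hairpin run — plausibility constraints belong to input
producers); unenclosed runs can never be `M` because classification uses
the nearest enclosing pair only. Unknown structure codes are rejected,
never coerced: silent remapping would corrupt downstream k-mer statistics.
Error messages use 1-based coordinates.

Pseudoknots and G-quadruplexes are out of scope: they would require
additional structure codes and a recomputed k-mer neighborhood.

## Scoring

A comparison extracts all L − k + 1 overlapping k-mers from each array,
forms the union vocabulary of the pair, tallies both count vectors,
takes the cosine, and multiplies by (1 − D) with
D = 2|L1 − L2| / (L1 + L2). The vocabulary is scoped *per pair*: entries
outside the union are zero in both vectors and cannot affect the dot
product or the norms, so a dataset-wide vocabulary would change nothing
for the plain cosine. S is deliberately not clamped at zero (D > 1 when
the length ratio exceeds 3:1); passing negative similarities through
preserves the monotone ordering and affinity propagation accepts
arbitrary reals.

Defaults: k = 10 plain and k = 9 fuzzy, the sizes at which clustering
metrics peak for each mode. Structures shorter than k are skipped with a
warning in matrix runs rather than failing the whole job. All arithmetic
is double precision; tests compare at 1e-9 absolute tolerance or tighter.

## Fuzzy counting

Edit distance between k-mers is unit-cost Levenshtein (insertion =
deletion = mismatch = 1) computed by dynamic programming, with a banded
early-exit variant that abandons a pair once every entry of a DP row
exceeds the threshold. For the equal-length k-mers this tool compares,
the optimal unit-cost alignment is the same object an aligner's
insertion/deletion/mismatch count would produce; this stands documented
as an approximation for any substitution-matrix-weighted alignment.

Fuzzification adds, for each vocabulary k-mer u,
`sum_w counts[w] · e^(−d(u,w))` over vocabulary k-mers w within the
threshold (d(u,u) = 0, so original counts carry weight 1). Two
accumulation schemes are provided because the per-occurrence question is
genuinely open: the default `linear` scheme scales pseudo-counts with the
source k-mer's count (a neighbor-weighted linear smoothing — the simplest
scheme consistent with pseudo-counts reducing the zero-element count of
both vectors of a pair), and a `flat` scheme adds a single `e^(−d)` per
present neighbor regardless of multiplicity, available via
`--fuzzy-scheme flat` for sensitivity analysis. Pseudo-counts are
distributed only within the pair-union vocabulary, keeping dimensions
finite; with both vectors fuzzified identically, self-similarity remains
exactly 1. The default threshold is d ≤ 2 — at d ≤ 1 the k-mer network
leaves gaps between hairpin k-mers and other loop types, while d ≤ 3
connects so many pairs that structural categories blur — so 3 is allowed
but warned about. Neighbor tables are memoized per matrix run (keyed on
the k-mer pair), not cached on disk.

## k-mer space

The census counts occurrences of every distinct k-mer across a dataset
(bounded by 8^k; 8^10 ≈ 1.07 × 10^9 possible 10-mers). The network joins
k-mer pairs within the chosen edit distance; node attributes are
occurrence count, degree, and the dominant character (the code with the
highest multiplicity, ties broken by the fixed priority L, R, H, M, X, I,
B, E — the priority order is this package's convention). Two edge
enumeration strategies produce identical edge sets and are asserted
equivalent in tests: all-pairs banded DP, and a deletion-neighborhood
hash join (if lev(a,b) ≤ d the two share a string reachable by ≤ d
deletions from each, so the join is a complete candidate filter; DP
confirms candidates). Exports are a TSV edge list and GraphML; no
plotting is done in-package.

## Clustering and evaluation

Affinity propagation (scikit-learn, precomputed affinities) is used
because it consumes similarity scores directly, requires no preset
cluster count and no edge threshold. Defaults: preference = median of
off-diagonal similarities, damping 0.9, 1000 max iterations, 100-iteration
convergence window, seeded symmetry-breaking jitter. Items are processed
in id-sorted order internally so permuting the input permutes the labels
identically. Non-convergence returns singleton clusters flagged
`converged=False` with a warning.

Evaluation metrics for a clustering against true classes: purity
(majority-class fraction per cluster), pairwise co-clustering
precision/recall/accuracy over all item pairs (accuracy is the Rand
index; 0/0 ratios are taken as 1), and the average subclass split (mean
number of predicted clusters over which a class's members scatter).
Because accuracy/precision/recall for clusterings admit more than one
standard definition, a `--metric-style mapped` alternative computes
accuracy under the optimal one-to-one cluster-to-class assignment
(Hungarian algorithm); both styles are first-class.

## Synthetic data

The generator emulates families of related structures: a base structure
is built recursively — geometric-length helices (≥ 2 pairs at the root of
each stem), loops closing as hairpins (≥ `min_hairpin` = 3 unpaired),
continuing through bulges/internal loops, or branching into multiloops
with probability `branch_prob` = 0.25, with flanking end runs — and each
family member is the base after `mutation_ops` validity-preserving edits
(extend/shrink a helix by one pair, grow/shrink an unpaired run by one
position respecting the hairpin minimum, add/remove a short branch
helix). Impossible edits are resampled with bounded retries. Default
geometry is 5 families × 6 members, base lengths 60–140 nt, 4 edits per
member — small enough that a full matrix-plus-clustering run takes
seconds, while keeping intra-family similarity well above inter-family
similarity. All randomness flows through numpy's PCG64 generator with
explicit seeds, so datasets are bit-identical across runs and platforms.

What the generator does *not* emulate: thermodynamic plausibility,
nucleotide sequences, pseudoknots, and the long-tailed length and
composition heterogeneity of curated structure databases. Passing the
planted-recovery tests therefore demonstrates the pipeline's correctness
and its ability to separate topology families under controlled
perturbation — not database-scale benchmark performance.

## Problem sizes in tests and the acceptance script

Test and acceptance runs are sized for quick iteration: 500 random
structures for annotation invariants, 200 random 5-mers (all pairs) for
the edit-distance oracle, 1,000 random 9-mer triples for metric axioms,
vocabularies of ≤ 500 k-mers for edge-strategy equivalence, 5 × 6 planted
datasets over five seeds for cluster recovery, and 50 single-edit pairs
for the plain-vs-fuzzy comparison. The pairwise workload of a
database-scale census (41,555 unique 10-mers → ~863 million pairs) is
reported as arithmetic, not recomputed pair-by-pair.

## Known limitations

- Pseudoknots and G-quadruplexes are rejected, not annotated.
- The `.dbn` multi-record dialect (name line, optional sequence line,
  bracket line) is a convenience convention of this package.
- Unit-cost Levenshtein may differ from feature-weighted alignment
  distances for exotic substitution matrices.
- Affinity propagation can fail to converge on adversarial matrices; the
  result is then flagged rather than hidden.
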