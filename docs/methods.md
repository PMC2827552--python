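# Methods

## The embedding and its identities

Every aligned character is mapped to a probability quartet over (A, C, G, T)
in a fixed slot order. Canonical bases give unit basis quartets; each IUPAC
ambiguity code gives the uniform distribution over its compatible bases;
`N`, gaps (`-`, `.`) and `?` give (¼, ¼, ¼, ¼). Two properties are forced by
this choice and load-bear everything else:

* **Hamming preservation.** For unambiguous sequences the squared Euclidean
  distance between embedded vectors is exactly twice the Hamming distance,
  and the cosine between unit-normalized vectors is exactly 1 − D_H/n. Both
  are tested with *exact* (zero-tolerance) assertions; the identities hold
  in floating point because the arithmetic involves only 0, ±1 and sums of
  integers.
* **Quartet conservation.** Every quartet of every encoded sequence sums to
  one — including ambiguity codes, which is the reason gaps must receive
  the uniform quartet rather than zeros. This is what later guarantees that
  indicator vectors can be read as probabilities.

The slot order of the four bases is a pure convention: any permutation
leaves every distance and correlation unchanged (tested). The default
(A, C, G, T) is fixed so that probability outputs are interpretable.

Half the squared Euclidean distance is exposed as a *generalized Hamming
distance*: it coincides with the integer count on unambiguous pairs and
extends it fractionally to ambiguous characters, which the character-level
definition does not cover.

## Conserved-site masking

A column identical (and unambiguous) across the pooled dataset adds the
same constant to every inner product and carries no differential
information; such columns are removed before any correlation is formed.
The default rule is strict — any ambiguous character in a column blocks
conservation, conservatively retaining the column — with an
`"unambiguous"` variant that ignores ambiguity codes when judging
constancy. The mask is computed from the pooled data (training and test
together) by default, since conservation is a statement about the dataset,
not about the training draw; a `mask_scope="train"` option restricts it to
training members. The package bundles the conserved-position list for the
standard 501-bp COI barcode window (161 positions, stored in
original-alignment coordinates 100–600; the loader's `offset` argument maps
them window-relative). Masking the 2004-entry encoding of a 501-site
sequence with it leaves 1360 entries.

## The indicator eigenproblem

For group k with unit training vectors S_k (|S_k| = N for every group,
which weights taxa equally), the criterion

J(q) = mean_{S_k} (ŝ·q)² − (1/(G−1)) Σ_{m≠k} mean_{S_m} (ŝ·q)²

is a quadratic form qᵀ C_k q with
C_k = M_k − (1/(G−1)) Σ_{m≠k} M_m, M_m the mean outer product of group m.
Maximizing J over the unit sphere is therefore an eigenproblem, and the
indicator vector is the dominant eigenvector, its eigenvalue equaling J at
the optimum. Design notes:

* **Equal competitor weighting.** Each rival group enters with weight
  1/(G−1). When all groups share the same N this coincides with pooling
  all non-k training sequences, so the distinction is moot under the
  package's equal-N contract.
* **Sign convention.** Eigenvectors are sign-ambiguous; the sign is fixed
  so the group's own training sequences correlate positively with their
  indicator (fallback: first nonzero entry positive). This makes outputs
  deterministic and correlations interpretable.
* **Degeneracy.** A non-positive leading eigenvalue (e.g. two groups with
  identical data *and* no distinguishing direction, G=2) raises an error
  naming the group. With G = 1 the between-group term is defined as zero
  and the problem reduces to the group's own dominant eigenvector.
* **Solvers.** The default is a dense symmetric eigendecomposition of the
  d×d operator (d = 4 × kept sites; d ≈ 1360 for the barcode window is
  trivial). A matrix-free Lanczos variant applies the operator through the
  N×d data matrices for long alignments; tests check it agrees with the
  dense solver.
* **Conservation, inherited.** Applying C_k to any vector produces a
  vector whose quartet sums are all equal (each ŝ has constant quartet
  sums 1/‖s‖), so the eigenvector equation forces the indicator's quartet
  sums to be mutually equal. Dividing by the common sum yields the
  probability form, whose quartets sum to exactly one. Entries may be
  negative — C_k is a difference of positive semidefinite operators — and
  are reported signed rather than clipped; the probability reading applies
  to the typical dominantly-positive case.
* **Ties.** Groups trained on identical sequence sets get identical
  indicators; test sequences of such groups tie exactly. Ties are flagged
  (`ambiguous`), never silently broken: indistinguishable groups are a
  biological finding, not a numerical nuisance.

## Matrices, ordering, trees

The structure matrix is Q Qᵀ over unit indicators (unit diagonal,
symmetric). The diversity matrix is computed through group mean vectors —
entry (k,m) = m̄_k·m̄_m equals the mean over all N² ordered member pairs,
including i=j self-pairs on the diagonal by default (the exclusive variant,
differing by O(1/N), is available); a brute-force double loop serves as the
test oracle. Correlation-based group ordering sorts each block by
descending row sum of correlations to block-mates, the minimal rule
consistent with "most related first"; ties keep input order.

Distances are d = 1 − ρ, or n(1 − ρ) in average-substitution units when a
site count is supplied; entries above 1 + 1e-9 are a domain error and
smaller overshoots clip to zero. Neighbor joining is implemented directly
(Q-criterion, standard branch-length and reduction formulas) because its
determinism contract matters here: exact Q ties resolve to the
lexicographically smallest pair of cluster labels (a cluster is labeled by
its smallest tip), and negative branch lengths are clipped to zero for
display with raw values retained in `clipped_branches`. On additive
matrices the reconstruction is exact (patristic distances reproduce the
input within 1e-9 in tests), and topology agrees with scikit-bio's
independent NJ implementation (Robinson–Foulds 0 on random additive
matrices). The unrooted result is represented with a trifurcating root.
Leaf orderings for matrix rearrangement are circular depth-first
traversals anchored at a chosen leaf (default: lexicographic minimum);
the anchor is exposed because an unrooted tree has no canonical
linearization.

## Klee diagrams

Heatmaps with optional block outlines and a colorbar; per-panel value
ranges are honored so two panels can deliberately use different scales.
SVG output strips volatile metadata and is byte-stable under a fixed
`svg.hashsalt`. `block_detect` is a heuristic aid (the primary annotation
path is a taxonomy file): walking the diagonal, a block is closed when its
mean internal correlation exceeds its mean correlation to the next element
by more than the threshold. It recovers ground-truth boundaries on
constructed block matrices and on generator data with contrast ≥ 0.3.

## The synthetic generator

`datagen.simulate` draws a uniform root sequence, freezes a
`conserved_fraction` of sites, derives each group ancestor by mutating free
sites at `between_divergence` (uniform among the 3 alternative bases),
each member from its ancestor at `within_divergence`, and masks characters
to `N` at `ambiguous_rate`. Groups are star phylogenies: the method under
test uses only present-day correlations, and the star model yields closed
forms used as test oracles — two members of a group differ per free site
with probability 2μ(1−μ) + (2/3)μ², giving the expected within-group
Hamming distance and diversity-matrix diagonal checked in the tests.

Defaults (12 groups × 60 sequences, 501 sites, between 0.20, within 0.02,
no ambiguity) emulate a well-separated multi-taxon barcode compilation.
What the generator does *not* emulate: codon structure and COI base
composition, transition/transversion bias, rate heterogeneity across
sites, indels, and within-group genealogical correlation (coalescent
structure). Passing tests therefore demonstrate the algebraic and
algorithmic correctness of the pipeline and its behavior under clean
group structure — not robustness to the full messiness of real barcode
data, where group separation can be far weaker.

## Problem sizes and numerical choices

The classification benchmark uses 12 groups × 60 sequences at 250 sites
with N = 30 trained per group across 20 seeds — a scale chosen to exercise
the full pipeline (d ≈ 1000 eigenproblems) while keeping the whole suite
fast on a laptop. Conservation and optimality properties are checked
across 50 randomized datasets (G ∈ 2..12, N ∈ 3..50) at 60 sites, where
the identities are scale-free. Tolerances: quartet-sum equality 1e-8
(observed ~1e-15), criterion-vs-eigenvalue 1e-10 (observed ~1e-15),
law of cosines 1e-12, NJ additivity 1e-9; Hamming preservation is asserted
exactly. Probability normalization refuses quartet-sum spreads above a
relative 1e-6 and common sums below 1e-8 rather than rescaling garbage.

## Known limitations

* Requires a trusted input alignment of equal-length sequences; no
  alignment or fetching is performed.
* Groups below N members are excluded from training rather than
  reweighted; unequal-N weighting is deliberately unsupported.
* Indicator probabilities can carry negative entries (reported, not
  clipped); interpretation as probabilities is heuristic in that regime.
* Only the leading eigenvector is used per group; multi-eigenvector
  discriminants are out of scope.
* Evolutionary-model distances (K2P, HKY, ...) are out of scope by
  design: the framework is about present-state correlations, for which
  the Hamming metric is the natural choice.
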