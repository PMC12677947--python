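# Methods

## Match model

A query sequence is represented by the set *Q* of its distinct 8-mers;
reference *i* by K<sub>i</sub>. The similarity statistic is defined through
a thought experiment: draw a uniform random *multiset* S<sub>t</sub> of
size *t* from *Q* (all C(|Q|+t−1, t) multisets equiprobable) and count how
many draws land in the shared pool of size a<sub>i</sub> = |Q ∩
K<sub>i</sub>|. The count *m* then has PMF

    p_i(m) = C(a_i+m−1, m) · C(b_i+t−m−1, t−m) / C(|Q|+t−1, t)

with non-matching pool b<sub>i</sub> = |Q| − a<sub>i</sub>: the numerator
counts multisets splitting into *m* draws from the matching pool and t−m
from the rest, and the Vandermonde identity for multiset coefficients
makes the PMF sum to exactly 1. An alternative convention with
b<sub>i</sub> = |K<sub>i</sub>| − a<sub>i</sub> is exposed behind
`--pmf-pool reference`; under that reading the distribution only
normalizes when |K<sub>i</sub>| = |Q|, so it is not the default and not
used anywhere else.

The probability that reference *i* ties-or-beats every other candidate,

    P_i = Σ_{m≤t} p_i(m) · Π_{j≠i} CMF_j(m),

treats the per-reference match counts as independent given the sample
size; that independence approximation is part of the model, not something
the implementation tries to correct.

### Numerical evaluation

- The PMF is computed by the recurrence p(m+1) = p(m) · (a+m)/(m+1) ·
  (t−m)/(b+t−m−1), seeded with p(0) = Π_{j<t} (b+j)/(|Q|+j) — one
  multiplication and one division per binomial coefficient per step, never
  factorials. The boundary cases a = 0 (point mass at 0) and b = 0 (point
  mass at t) are handled explicitly because the generic recurrence would
  divide by zero or propagate a zero seed.
- The product over all candidate CMFs, C(m) = Π_j CMF_j(m), is accumulated
  as a sum of logarithms (log 0 = −∞ propagates to C(m) = 0), and each
  candidate's P_i = Σ_m p_i(m)·C(m)/CMF_i(m) divides out its own factor in
  log space. This prevents underflow when thousands of candidates carry
  small CMF values; the final L1 normalization absorbs any common scale. A
  term is taken as 0 whenever p_i(m) = 0, which also covers CMF_i(m) = 0.
- Only references with nonzero intersection are candidates. A
  zero-intersection reference has CMF ≡ 1 and contributes a unit factor to
  every C(m) — the restriction is exact for the product — and its own
  P_i is a point-mass-at-zero sum that the tool reports as 0.
- A rational-arithmetic twin of the recurrence (`match_pmf(..., exact=True)`)
  exists for testing against exhaustive multiset enumeration; the float
  path is the production path.
- The O(|D|²t) naive double loop is kept as
  `best_match_probabilities_naive`, a test oracle only; the suite checks
  the cached path against it to 1e-12 relative.

## Lineage aggregation

All reference lineages are merged into a multifurcating tree; leaves
(references) are laid out in post-order so every clade covers a contiguous
half-open interval (a, b) of leaf indices, with child intervals
partitioning the parent in order. Clade confidence L(B) is the prefix-sum
difference Ap[b] − Ap[a] of the L1-normalized per-reference confidences;
the half-open 0-based convention makes that identity exact. Depth-first
reporting stops at any node whose score falls below the prune threshold
(default 0.005, configurable); every maximal surviving path is reported,
and a path that ends above the reference level is marked truncated with a
trailing `*` token. Children are ordered by taxon name and leaves by
reference id, and ties in the output ordering are broken by lineage
string, so the output is invariant to reference input order. Lineages
with fewer ranks than the deepest one are attached at their last given
rank with a parse-stage warning.

## Uncertainty signals

The expectation for a query resembling nothing in particular is the
uniform vector P̄ = (1/n, …, 1/n), which induces clade expectations
L̄(B) = |B|/n (the clade's leaf share — this follows mechanically from
applying the clade sum to P̄). Two raw Euclidean distances are reported,
with no rescaling to [0, 1]:

- **global** s_g = ‖P − P̄‖₂ per query, evaluated in closed form over the
  sparse candidate set (the n − #candidates implicit zeros contribute
  (n − k)/n² inside the square root); maximized at √((n−1)/n) by a one-hot
  assignment and 0 when P = P̄;
- **local** s_l per reported lineage: the distance between the
  L1-normalized observed per-rank score vector and the L1-normalized
  vector of clade leaf shares along the same lineage, computed for every
  reported lineage, not only the top one.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 8 (fixed) | word size; one 8-mer per 16-bit code, 2 bits per base |
| t | 32 | k-mers sampled per query; matches the established sampling convention of SINTAX-style classifiers and satisfies t ≪ |D| |
| prune threshold | 0.005 | clade score below which lineages are not expanded |
| min-confidence | 0 | report-time filter on terminal confidence; never alters computed scores |
| pmf-pool | query | non-matching-pool convention (see above) |
| revcomp | off | additionally index/extract reverse-complement 8-mers; queries are otherwise assumed in reference orientation |

## Synthetic data generator

The generator emulates the conditions a barcode classifier faces: a
three-level taxonomy (8 families × 6 genera × 6 species by default) with
uneven clade sizes — an imbalance factor of 7 gives the first family 42
genera instead of 6, hence exactly 50% of the 504 references — one 300 bp
reference per species derived from a per-species random ancestor with 1%
within-species divergence, and queries that are copies of references with
2% per-base substitutions (indels available, default off). 300 bp is a
typical barcode amplicon length. Everything is deterministic under the
configured seed.

What it does **not** emulate: sequence similarity *between* species
(ancestors are drawn independently, so inter-species 8-mer overlap is at
the random background of |Q||K|/4⁸ ≈ 1–2 shared 8-mers), chimeras,
sequencing-quality error profiles, length variation, or real taxonomic
depth. Passing the recovery tests therefore demonstrates the machinery —
exact probabilities, aggregation, determinism — not classifier accuracy
on real, highly autocorrelated databases; the evaluation harness
(cross-validation splits + confidence-cutoff F1) is provided for running
such studies on real data.

The evaluation protocol labels every assignment below a confidence cutoff
(0–100 scale) as not classified; a wrong taxon at-or-above the cutoff
counts as misclassified and enters the recall denominator. Precision with
an empty classified set is reported as 0 and flagged rather than NaN. In
cross-validation, queries whose true taxon is absent from the fold's
reference can be excluded per rank via the `scorable` argument, to avoid
penalizing impossible calls.

## Index persistence

The reference index is query-independent and is stored in a small binary
format: magic bytes `KMTX`, a format version, little-endian fixed-width
integers, length-prefixed UTF-8 strings, and postings lists as
delta-encoded varints. Loading rebuilds the lineage tree from the stored
lineages — the tree construction is deterministic, so the rebuilt tree is
structurally identical — and verifies magic, version, and payload length,
refusing truncated or foreign files.

## Design choices and limitations

- Classification of a query with an empty k-mer set or no candidate
  reference yields a single `unclassified` row (global signal 0) rather
  than an error.
- Parallelism is over queries; results are collected in input order, so
  output is byte-identical for any worker count.
- Scores are printed with fixed 4-decimal notation; `--percent` switches
  to the 0–100 scale used by the cutoff protocol.
- Test problem sizes (≤ ~1000 references, ≤ 300 bp, ≤ 100 queries) were
  chosen so the full suite exercises every path, including the 1000-
  reference persistence round trip, in well under a minute each; the
  method itself has no intrinsic size limit beyond memory for the 65 536
  postings lists.
- No minimizer/sketching, no arbitrary k, no strand canonicalization by
  default, no paired-end handling, and no reconciliation against external
  taxonomies.
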