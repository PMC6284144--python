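# Methods

## Model and procedure

`hiertweet` clusters a nonnegative term-document matrix
`A ∈ R^{m×n}_{≥0}` into a binary topic tree by recursive rank-2
nonnegative matrix factorization.  At a node holding document set `S`,
the submatrix `A_S` is factored as `A_S ≈ W H` with `W ∈ R^{m×2}_{≥0}`
(unit-norm columns) and `H ∈ R^{2×|S|}_{≥0}` by block coordinate descent,
where each half-step is solved *exactly*: for a two-column design the
nonnegative least-squares problem `min_{h≥0} ‖Wh − a‖₂` has only three
candidate active sets — the unconstrained 2×2 normal-equation solution
(accepted when nonnegative) or the better of the two single-column
projections `h_j = max(0, wⱼᵀa/‖wⱼ‖²)`.  Because every half-step attains
the subproblem optimum, the squared Frobenius objective is monotonically
non-increasing; the recorded trace is asserted to within 1e-8 relative
slack to absorb floating-point evaluation of the trace-expansion
objective `‖A‖² − 2·tr(HᵀWᵀA) + tr((WᵀW)(HHᵀ))`.

Documents go to the left child when their first `H` row dominates (ties
left).  Which frontier leaf to split next is decided by a
well-separatedness score in [0, 1]: for each child's ranked top-term
list, a modified NDCG assigns gain 0 to terms present in the sibling's
list and gain 1 otherwise, discounted by `1/log₂(i+1)` at rank `i`, and
the two mNDCG values are multiplied.  Disjoint lists score exactly 1,
identical lists exactly 0.  The highest-scoring leaf is split (ties to
the smaller node id); a trial split that would produce a child with fewer
than `min_node_docs` documents marks the leaf permanent.  Construction
stops at `max_leaves` leaves or when no splittable leaf remains, so trees
need not be balanced.  Depth is reported as the *degree level* with the
root at 1, matching how published World AIDS Day hierarchies are indexed.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `ngram_min..ngram_max` | 1..2 | unigrams + bigrams; bigrams capture phrases like "aids free" without exploding the vocabulary |
| `min_term_docfreq` | 3 | prune hapax/near-hapax terms before weighting |
| `weighting`, `normalize_docs` | tf-idf, unit ℓ₂ columns | the standard vectorization for NMF document clustering; comparable column scales are needed for balanced splits |
| `tol`, `max_iter` | 1e-4, 200 | relative objective decrease stopping rule per NMF run |
| `n_restarts` | 3 | best-of-k seeded initializations per factorization (see below) |
| `min_node_docs` | 5 | smallest admissible leaf; smaller children veto a split |
| `m_top` | 10 | ranked terms reported per node |
| `m_score` | 20 | ranked terms compared by the split score (see below) |
| `min_count` | 35 | frequency-table threshold, tweets per topic |
| `stable_band` | 0.25 | fractional band around equality separating increase/decrease from stable |
| `mode` | normalized | trend comparison on rates per 10,000 unique tweets, because the two corpora being compared can differ severalfold in size; `raw` compares counts directly |

Initialization draws two distinct document columns (seeded) perturbed by
1e-6 uniform noise.  Alternating NMF only finds local optima, and an
initialization that draws both documents from the same latent topic can
converge to a poor within-topic split; `rank2_nmf` therefore runs
`n_restarts = 3` seeded initializations and keeps the lowest final
objective.  All per-node seeds fan out deterministically from the
top-level seed through `SeedSequence`, so identical inputs and seed give
byte-identical trees.

Two separate top-term lengths exist deliberately.  Reported node
summaries use `m_top = 10`.  The split score, however, compares
`m_score = 20` terms: with 10-term lists a rank-2 factorization *within*
one coherent topic can still produce disjoint top-10 lists (the two
factors latch onto complementary halves of the topic vocabulary) and
score 1.0, indistinguishable from a genuine two-topic separation; over
~20 terms the two halves of a single topic share much of their
vocabulary and the score collapses (≈0.2–0.35 in our planted-topic
experiments) while true separations stay near 1.0.

## Codebook matching

The packaged codebook encodes the 19 published World AIDS Day themes,
each with stemmed example keywords, one UNAIDS core action and one
commitment area.  A node is assigned the theme with the largest
keyword/top-term overlap, provided the overlap reaches `min_overlap = 2`;
ties are left unassigned and flagged for manual review.  Matching
operates on the component words of each top term, comparing a word
directly against the (stemmed) keyword set before falling back to its
stem — the Porter mapping is not idempotent ("diseas" would re-stem to
"disea"), so already-stemmed pipeline terms must never be stemmed twice.
Expert qualitative coding is explicitly *not* automated: the codebook
reproduces a fixed published framework deterministically.

In the theme-depth comparison `delta = depth_b − depth_a`; positive delta
means the theme moved deeper, i.e. became less prominent by that many
degree levels.

## Stemming

The Porter affix-removal stemmer is implemented in-package (no suitable
library is bundled with the environment): the classic 1980 five-step
procedure including the author's later minor revisions (`bli→ble`,
`logi→log`) applied by the widely distributed reference implementation.
Conformance is pinned by 71 word/stem pairs from the published reference
vocabulary, each traced through the full pipeline.  Note the stemmer maps
"day"→"dai" and "today"→"todai" (y→i after a vowel-bearing stem); hand
counts in tests use the stemmed forms.

## What the synthetic generator emulates — and what it does not

Each unique document draws `doc_length ∈ [8, 20]` tokens from the mixture
`(1 − background_mix)·topic + background_mix·background` with
`background_mix = 0.2` by default; leaf topics carry 2 anchor words (16%
of topic-token mass, ≥10× more probable than under any other topic), 20
topic words, and 10 branch words shared with the sibling topic, over a
150-word Zipfian (exponent 1.1) background containing hashtag-like terms.
Retweets (`retweet_rate = 0.4`, i.e. 0.4·n_docs duplicates) copy an
existing document verbatim behind an `RT @user:` prefix.  Follower counts
are discretized log-normal (μ=6, σ=2.5), heavy-tailed enough that modest
corpora accumulate reach orders of magnitude above their size, as real
World AIDS Day corpora do; timestamps are uniform over one day.

Not emulated: multilingual text, follower-graph diffusion, topic drift
within the day, misspellings, emoji, and the collector's sampling
artifacts.  Passing the planted-recovery tests therefore shows the
pipeline separates mixture-generated topics with anchor structure — it
does not certify recovery on real tweet streams, where topics overlap
more heavily and label ground truth does not exist.

## Numerical choices and degenerate inputs

- NNLS ties between the two single-column projections go to the first
  column; an all-zero design raises a degenerate-input error.
- A submatrix with fewer than 2 documents or fewer than 2 nonzero term
  rows cannot be split; the node becomes a permanent leaf.
- A Gram determinant below `1e-14·max(g₁₁,g₂₂)²` (collinear columns) is
  treated as singular and resolved through the single-column candidates.
- Term ties in ranked lists break by vocabulary (alphabetical) order;
  document assignment ties go left; split-score ties between leaves go to
  the smaller node id.
- tf-idf uses `c·log(n/df)`; a term present in every document weights to
  zero and is pruned, and documents whose columns become all-zero are
  dropped and reported.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
oracle comparisons on 200 random 6×2 systems, monotonicity on 50 random
50×40 matrices, planted recovery on 1,200-document corpora with 4 topics,
and a two-timepoint demo at 1,000 + 2,000 documents.  At these sizes the
whole suite completes in a few seconds.

## Known limitations

- The published hierarchies were produced by a specific original
  implementation whose exact splitting score and outlier handling live in
  its own algorithm papers; the mNDCG schedule here (binary gains, log₂
  discount, `m_score = 20`) is this package's concrete choice and may
  rank borderline splits differently.
- Strict permutation equivariance of `hier_cluster` under column
  permutation does not hold with seeded random document-pair
  initialization (the sampled columns differ); on well-separated data the
  recovered partition is initialization-independent and equivariance is
  tested there.
- Unique-tweet identification defaults to canonical-text first-seen
  (retweet prefix stripped, whitespace-normalized, case-folded) because
  collector flags are inconsistent in practice; flag-based dedup is
  available but not the default.
- The codebook covers only the published example keywords; clusters whose
  vocabulary falls outside them remain unassigned rather than guessed.
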