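# Methods

## Measurement model

The unit of analysis is a focal article in a citation network. Citations are
stored directed (citing → cited) but analyzed as undirected connections by
default; the `citing` and `cited` direction modes restrict the neighborhood
to in-edges (articles citing the focal) or out-edges (the focal's reference
list). Second-degree neighborhoods contain everything within two undirected
steps, first-degree neighbors included, and are computed lazily per focal
article with a depth-limited traversal — at bibliographic scale the
second-degree pair set is orders of magnitude larger than the edge list and
must never be materialized corpus-wide.

For a focal article with annotation set *A* and unique neighborhood
annotation set *U* (union over annotated neighbors), recall is |A∩U|/|A| and
precision |A∩U|/|U|. Neighborhood annotations are ranked by document
frequency — the number of *distinct* annotated neighbors carrying the
annotation; annotation sets are sets, so no within-article multiplicity
exists — and average precision is computed over that full ranking with *A*
as the relevant set. The recall denominator of AP is |A|, not the
recoverable subset: annotations absent from the entire neighborhood penalize
AP, so AP ≤ recall and AP = 1 only when the top of the ranking is exactly
*A*. Rank ties are broken lexicographically for reproducibility; an
expected-AP mode averages over tie-group permutations instead (exhaustively
for groups of ≤ 6, by seeded Monte-Carlo above that).

Articles with no annotations of their own, or no annotated neighbors, carry
no signal for these ratios. They are excluded and counted, never scored; the
full-recall fraction therefore uses the evaluated records as its denominator
(a whole-corpus denominator is a one-line division by the caller's target
count). Corpus-wide recall is annotation-weighted: recovered annotation
instances over all annotation instances, not a mean of per-article recalls.

Neighborhood annotations and target annotations may come from different
stores (cross-source evaluation, e.g. a small gold standard scored against a
large database); annotation guidelines then differ between sources, which
depresses measured overlap relative to single-source evaluation.

## Null model

The randomized network permutes the multiset of citing-side identifiers
across all pairs, leaving cited-side identifiers in place. Marginal counts
are preserved; topical structure is destroyed. The shuffle acts on the raw
pair list; self-loops and duplicate pairs created by the shuffle are then
dropped/collapsed exactly as in normal graph construction, and the attrition
is recorded in the run metadata (whether to clean before or after shuffling
is a genuine convention choice; cleaning after matches treating the shuffle
as acting on raw citation records). A single shuffle with a recorded seed is
the default; variance estimates can repeat it with different seeds.

The closed-form yardstick for "no topical signal" is
`expected_null_recall(V, m̄, k) = 1 − (1 − m̄/V)^k`: the probability that a
focal annotation appears in at least one of k annotated neighbors, each
carrying on average m̄ annotations drawn uniformly from a vocabulary of size
V. When the generator draws annotations uniformly this is exact (a uniform
without-replacement draw of m tokens contains a given token with probability
m/V); for Zipf-weighted corpora it is a lower bound, since popular tokens
match more often.

## Sigmoid recall extrapolation

Per-article recall saturates as the annotated neighborhood grows, so the
recall–vs–annotated-neighbor-count relation is summarized with a bounded
monotone curve, recall(x) = L/(1+exp(−k(x−x₀))): L is the recall ceiling
(constrained to [0, 1]), k the growth steepness, x₀ the midpoint
(recall = L/2). Fitting uses nonlinear least squares (trust-region, SciPy)
initialized at L = max(y), k = 1, x₀ = median(x). The default fits the raw
per-record points; `binned=True` fits per-count mean recalls instead — the
two answer slightly different questions (per-record fits weight bins by how
many articles they contain; binned fits treat each neighbor count equally)
and both conventions appear in recall-saturation analyses, so both exist. R²
is 1 − SS_res/SS_tot on whatever points were fitted; per-record R² is low
even for a strong mean trend, because individual recalls are ratios of small
integers with large dispersion.

Uncertainty comes from a seeded parametric bootstrap: the response is
regenerated as fitted-curve + Gaussian noise at the residual SD (n_boot =
200 by default) and refitted. Parameter intervals use the basic (pivot)
construction 2θ̂ − q by default rather than raw percentiles: in coverage
simulations at the package's test conditions (σ = 0.1, n = 500) the
percentile interval undercovers the steepness k (≈ 0.90 at nominal 0.95)
because the k estimate is biased, while the pivot interval reflects the
bootstrap distribution around the estimate and reaches ≈ 0.93. Prediction
bands are percentile envelopes of the bootstrap curves, and predictions are
clipped to [0, 1]. A constant response (SS_tot = 0) and non-convergence
raise a dedicated error carrying the initialization and residual scale;
bootstrap replicates that fail to converge (rare) are dropped.

## Synthetic corpus generator

The generator emulates the features of a bibliographic corpus that drive
annotation sharing, and only those:

- **Topics.** Each article gets a uniform topic; each article cites
  d ~ Poisson(`mean_citations`) earlier-indexed articles (publication order;
  the graph is acyclic, invisible to undirected analysis but keeping the
  direction modes meaningful). Each citation targets the article's own topic
  with probability `p_within` (uniformly among earlier same-topic articles),
  otherwise a uniform earlier article. A within-topic draw that finds no
  earlier same-topic article is dropped, not redirected, so `p_within = 1`
  structurally guarantees zero cross-topic edges.
- **Annotations.** A fraction `annot_frac` of articles receives
  m ~ 1 + Poisson(`mean_annots` − 1) distinct annotations (every annotated
  article has ≥ 1) sampled without replacement from its topic's vocabulary
  with Zipf(1) weights — real annotation usage is heavy-tailed, and
  vocabulary size must modulate overlap the way it does across real
  databases (a vocabulary of hundreds of thousands of variant IDs overlaps
  far less than tens of thousands of gene IDs). A `weighting="uniform"`
  switch exists for null calibration. Each topic ranks its vocabulary by an
  independent seeded permutation before Zipf weighting; without this, the
  tokens shared across topics (`shared_vocab_frac`) would occupy the top
  Zipf ranks in every topic and soak up most annotation mass corpus-wide,
  erasing the topical structure the generator exists to produce.
- **Defaults** (chosen once as a plausibly clustered mid-size literature and
  used as the package's standard study conditions): 2,000 articles, 10
  topics, `p_within` 0.9, mean out-degree 5, mean 4 annotations per article,
  80-token topic vocabularies with 10% shared, 80% of articles annotated.

All randomness flows from one seeded generator; identical config + seed
yields byte-identical corpora. Truth metadata (topic assignments,
vocabularies, raw pairs) is always emitted. The generator writes the same
TSV dialects the ingest readers parse, so synthetic corpora exercise the
real I/O path.

What the generator does **not** emulate: real degree distributions (no
preferential attachment; Poisson out-degree has no heavy tail), citation
practice biases, annotation guideline drift between databases, or time- and
field-dependent annotation density. Tests passing on synthetic corpora
therefore show the pipeline measures what it claims under known structure —
not that real corpora have any particular overlap level.

## Numerical and convention choices

- Identifier normalization: DOIs are case-folded (DOIs are
  case-insensitive), PMIDs kept verbatim; prevents silent join misses when
  mapping citation pairs.
- Column selection by name with a positional fallback flag, because the
  column order of citation and mapping dumps varies across releases.
- Gene-dialect taxon filter defaults to human (9606), overridable.
- Gold standards read as headerless two-column TSV; multiple files merge by
  per-article set union (the defensible convention when the same abstract
  appears in several splits).
- Full recall is the exact integer identity n_shared = |A| — no float
  tolerance, since recall is a ratio of small integers.
- Curve stratification bins on the exact annotated-neighbor count 1..20 by
  default; everything above pools into a terminal open-ended bin that is
  reported but excluded from curve plots. For degree-2 curves the bin counts
  annotated neighbors of the combined first+second-degree neighborhood.
- Evaluation iterates targets in sorted order, making every output
  byte-reproducible for fixed inputs.
- Every reader and every CLI command emits row-attrition counts (read /
  kept / skipped by reason); at bibliographic scale mapping loss is material
  and must be auditable.

## Problem sizes

The test suite and the acceptance script run on generated corpora of
2,000–5,000 articles (≈ 10⁴ citation pairs), sizes at which the per-bin
curve statistics have enough records per bin (tens to hundreds) for the
trend checks while the full pipeline stays in the seconds-to-minutes range.
Null-agreement checks use 5,000 articles with a 2,000-token uniform
vocabulary; sigmoid coverage checks use 50 replicates of 500 points with 200
bootstrap refits each.

## Known limitations

- The ingest path expects pre-extracted delimited tables; native XML/flat
  dump formats of the large bibliographic databases are out of scope.
- The null model is the citing-side shuffle only — no degree-preserving
  rewiring or configuration-model nulls.
- The full ranking is evaluated; no thresholded prediction set is produced.
- Coverage and second-degree queries are exact but per-article; corpus-wide
  coverage on very large graphs is O(nodes × neighborhood size).
- The sigmoid is the only growth model offered; it is a summary device, not
  a mechanistic claim.
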