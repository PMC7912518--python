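# citeshare

Biomedical articles tend to share database annotations — gene links, MeSH
descriptors, variant references — with the articles they are connected to by
citations. `citeshare` measures that sharing on a citation network and
evaluates how well an article's own annotations can be predicted from its
neighborhood, for curators and literature-mining developers who want to use
citation context as an annotation signal.

## What it computes

Articles are nodes of a network whose edges are citations, treated as
undirected connections unless a direction mode is chosen (articles *citing*
the focal article vs. the focal article's *cited* references). For a focal
article with annotation set *A* and a neighborhood whose annotated neighbors
collectively carry the unique annotation set *U*:

- **recall** = |A ∩ U| / |A| — fraction of the article's annotations found in
  at least one neighbor;
- **precision** = |A ∩ U| / |U| — fraction of the unique neighborhood
  annotations the article itself carries;
- **average precision** AP = Σₖ P(k)·ΔR(k), where the neighborhood annotations
  are ranked by document frequency (number of distinct annotated neighbors
  carrying each annotation), P(k) is the precision of the top k ranks and
  ΔR(k) the recall gained at rank k, with the article's own annotations as
  the relevant set. MAP is AP averaged over articles: MAP = 1 means the most
  frequent neighborhood annotations are exactly the article's annotations.

Around these per-article statistics the package provides: first- and
second-degree neighborhoods (second degree includes the first), direction
modes, an edge-shuffle null model (the multiset of citing-side identifiers is
permuted, destroying topical structure while preserving marginal counts),
curve stratification by annotated-neighbor count, annotation-weighted
corpus-wide recall, coverage statistics (what fraction of a corpus has enough
annotated neighbors to be scorable at all), and a sigmoidal recall-saturation
fit *recall(x) = L / (1 + exp(−k(x − x₀)))* with seeded bootstrap confidence
intervals, used to extrapolate recall to better-connected corpora.

Because real bibliographic inputs are enormous, the package ships a synthetic
corpus generator (`citeshare.synthetic`) producing annotated citation
networks with tunable topic clustering, vocabulary sizes and Zipf-weighted
annotation sampling, emitting the same delimited formats the ingest readers
accept.

## Worked example

```python
import citeshare as cs

corpus = cs.generate(cs.SyntheticConfig(seed=1))
result = cs.evaluate_corpus(corpus.graph, corpus.store, corpus.store)
print(f"scored {len(result.records)} articles; excluded {result.exclusions()}")

for point in cs.stratify(result.records, max_bin=5):
    if not point.open_ended:
        print(f"bin {point.bin:2d}: n={point.n_records:3d} "
              f"recall={point.mean_recall:.3f} "
              f"precision={point.mean_precision:.3f} MAP={point.map:.3f}")

print(f"corpus-wide recall: {cs.corpus_recall(result.records):.3f}")

fit = cs.fit_sigmoid([r.n_annotated_neighbors for r in result.records],
                     [r.recall for r in result.records], seed=0)
print(fit.summary())
est, lo, hi = fit.predict(5.0, ci=True)
print(f"extrapolated recall at 5 annotated neighbors: "
      f"{float(est):.3f} [{float(lo):.3f}, {float(hi):.3f}]")
```

Output:

```
scored 1572 articles; excluded {'no_annotated_neighbors': 2, 'no_own_annotations': 0}
bin  1: n= 28 recall=0.171 precision=0.175 MAP=0.108
bin  2: n= 62 recall=0.350 precision=0.155 MAP=0.174
bin  3: n=113 recall=0.381 precision=0.151 MAP=0.198
bin  4: n=161 recall=0.481 precision=0.152 MAP=0.257
bin  5: n=186 recall=0.449 precision=0.122 MAP=0.208
corpus-wide recall: 0.531
Sigmoid recall fit: recall(x) = L / (1 + exp(-k (x - x0)))
  n_obs      1572
  R-squared  0.1450
  residual sd 0.2609
  param   estimate   95% CI
  L          0.7035   [0.6407, 0.7505]
  k          0.2838   [0.2005, 0.3599]
  x0         2.3826   [1.7751, 3.0261]
extrapolated recall at 5 annotated neighbors: 0.477 [0.460, 0.496]
```

Reading it: with 3 annotated neighbors an article's annotations are on
average 38% recoverable from the neighborhood; recall rises and precision
falls as neighborhoods grow (neighbors bring the article's annotations plus
a diversity of others); corpus-wide, 53% of all annotation instances appear
in at least one neighbor. The sigmoid fit extrapolates per-article recall to
a hypothetical corpus where every article had exactly five annotated
neighbors (47.7%). Per-record recall is noisy, so R² is modest even when the
mean trend is strong.

The same pipeline is available from the shell:

```bash
citeshare simulate --n-articles 2000 --seed 1 --out-dir corpus/
citeshare evaluate --citations corpus/citations.tsv \
    --neighbor-annotations corpus/annotations.tsv --out records.tsv
citeshare curve --records records.tsv --out curve.tsv --fit-out fit.json
citeshare randomize --citations corpus/citations.tsv \
    --neighbor-annotations corpus/annotations.tsv --seed 7 --out null.tsv
```

Real data enter through the same readers: COCI-style citation pairs (with
optional DOI→PMID mapping tables), `gene2pubmed`-style gene annotation
tables (taxon-filtered, human by default), MeSH tables with a major-topic
flag, generic two-column article→annotation tables, and BC2GN-style gold
standards — see `citeshare ingest --help`.

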