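# Methods

## Problem and model

Given a set of publications matched by a PubMed-style query, which genes
do those publications describe, and which of them are *specifically*
relevant to the query rather than merely well studied?  litrank answers
this with the curated gene-to-publication link table (the NCBI
`gene2pubmed` dialect) as its universe.  For a query Q and a gene G,
write

* `m` — distinct publications in the link table,
* `n` — query-relevant publications: retrieved PMIDs that occur in the table,
* `j` — publications linked to G anywhere in the table,
* `k` — query-relevant publications linked to G.

Under the null hypothesis that G is unrelated to Q, the number of
query-relevant publications among G's `j` follows a hypergeometric
distribution (drawing `n` publications from `m` with `j` "successes").
The gene's score is the negative log of the upper tail,

    S_G = -log10 f(m, n, j, k),
    f(m, n, j, k) = sum_{i=k}^{min(n,j)} C(j,i) C(m-j, n-i) / C(m,n),

the probability of observing `k` or more query-relevant publications by
chance.  A large score means the query literature cites G far more often
than G's overall publication volume predicts; this corrects the bias of
raw counts toward heavily studied genes.  The count-based method
(score = `j`) is retained for comparison, as it is the convention of
several other literature-mining tools; a switch scores by `k` instead,
since the published wording for count-based ranking is ambiguous between
the two and other tools differ.

Assumptions worth stating: publications are exchangeable draws (no
publication-date or journal weighting); gene-publication links are taken
at face value from the curated table; and the query's PMID set is
treated as exact (a truncated retrieval is flagged, not repaired).

## Pipeline and parameters

1. **Link table** (`linktable`): read the TSV, optionally restrict to a
   species (`tax_filter`, e.g. 9606), then remove publications linked to
   more than `cap` distinct genes (default **500**, strict inequality:
   degree exactly 500 is kept).  Such promiscuous publications —
   genome-scale surveys — lack specificity and would contaminate every
   query.  Species restriction happens before the promiscuity filter so
   degrees reflect the search space actually used.
2. **Query set** (`retrieval`): a saved eSearch XML response or a plain
   PMID list; no network code in the core.  A `PublicationSource`
   protocol defines the contract a live client would satisfy.
3. **Scoring** (`prioritize`): only genes with `k >= 1` are ranked.
   Ties break by descending score, then descending `k`, then ascending
   gene ID, making output order deterministic.  The default threshold
   keeps scores `>= 2`, i.e. p `<= 0.01`; the boundary value survives
   because removal targets score < 2 strictly.
4. **Gold standards** (`goldstd`): GO term gene sets are the annotation
   closure over the term and all its descendants (the true-path rule).
   Both `is_a` and `part_of` edges propagate by default — GO's own rule —
   with an `is_a`-only switch, since curated pipelines differ on
   `part_of`.  OMIM gold standards map a user-chosen MIM-ID set through
   `mim2gene` (title matching against OMIM is input, not computation,
   because it requires the OMIM full-text database).  GAD-style plain
   gene lists merge with OMIM lists by set union.
5. **Evaluation** (`evalmetrics`): set-level precision/recall/F, and
   rank-level AP, precision at k and the PR curve.

## Numerical choices

* The tail is summed in log space: log-binomials from `gammaln`,
  combined with a max-shifted log-sum-exp.  Direct binomials overflow
  near real table sizes (`m ~ 6.5e5`).  Relative accuracy is ~1e-10
  against exact rational enumeration for `m <= 60` (tested), and the
  same construction is cross-checked against an independent library
  survival function.
* The overlap cannot fall below `max(0, n + j - m)`; for `k` at or below
  that bound the tail is returned as exactly 1 rather than summed, which
  keeps `f(m, n, j, 0) = 1` exact.
* `-log10 p` is unbounded, so p-values under `1e-308` (the edge of
  double-precision normals) are clamped, capping scores at a
  configurable 308.
* Tails for consecutive `k` whose pmf difference is below ~1e-13 of the
  tail are equal (or very rarely inverted) in doubles; monotonicity in
  `k` holds exactly in the mathematics and to the stated accuracy in
  floats.
* Average precision divides by the full gold-standard size, so relevant
  genes missing from a ranking count against it; precision at k keeps
  denominator k for rankings shorter than k (a `length` convention is
  available), keeping methods of different list length comparable.
  Zero-denominator set metrics return 0 with a `degenerate` flag instead
  of NaN.

## Synthetic corpora

`synthdata.generate_corpus` builds a miniature literature from a single
seed: gene IDs `1..n_genes`, consecutive PMIDs, each publication citing
`1 + Poisson(mean - 1)` genes (so every publication cites at least one;
the shifted Poisson is a free modelling choice for sparse link data).  A
planted gene set of size `n_planted` is the gold standard; publications
belonging to the query cite planted genes with probability scaled by an
`enrichment` factor, which directly controls the `k/n` versus `j/m`
contrast the hypergeometric test detects.  `enrichment = 1` is the null:
the planted label carries no signal.  Optional deliberately over-linked
publications (degree above the 500 cap) exercise the promiscuity filter;
ordinary publications are capped at degree 500 so the filter removes
exactly the over-linked ones.

Default study conditions, used by the tests and the acceptance script:
200 genes, 1000 publications, 100 query publications, 20 planted genes,
mean 5 genes per publication, enrichment 8, averaged over 20 seeds.
These sizes keep a full multi-seed experiment in seconds while leaving
the planted signal statistically comfortable rather than trivial: at
enrichment 8 a planted gene's expected `k` is ~12 of `n = 100` against
an expected background of ~2.4.

What the generator does *not* emulate: MEDLINE text and MeSH indexing,
publication dates beyond PMID ordering, species mixtures, the heavy
right tail of real gene publication counts, and correlated annotation
(co-citation structure).  Passing the synthetic recovery tests therefore
shows the statistic and its implementation behave as designed, not that
real queries achieve any particular precision.

## Known limitations

* Count-method scoring by `j` ranks well-studied genes first by design;
  it is kept for comparison, not recommendation.
* The published per-query scores and list sizes depend on a 2011 NCBI
  snapshot and are not reproducible offline; the package reproduces the
  published evaluation *arithmetic* exactly and the thresholding
  *property* on synthetic corpora.
* No eSummary annotation (gene symbols, publication titles): output
  carries Entrez-Gene IDs and PMIDs only.
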