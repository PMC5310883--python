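# Methods

## Model

`exprgo` treats GO enrichment as a weighted sum over the whole
transcriptome rather than a count over a significance-filtered gene list.
With N genes and K samples in experiment order, the enrichment score of
term *t* in sample *s* is

    ES(t,s) = Σᵢ log2(e(i,s) + 1) · I(i,t)

in abundance mode (e = RPKM/FPKM ≥ 0), or

    ES(t,s) = Σᵢ log2(2^e(i,s) + 1) · I(i,t)

in log-fold-change mode (e = microarray log2 ratio, any sign).  The +1
keeps silent genes at zero contribution in abundance mode; in
log-fold-change mode an unchanged gene (e = 0) contributes exactly one
unit, so term scores reflect annotated gene counts shifted by expression
change.  Both transforms are strictly increasing in e, but they are not
interchangeable re-parameterisations of each other.  The annotation
indicator I(i,t) applies in both modes — without it every term would
receive the same score.

Derived statistics per term: stepwise fold changes
F(t,s) = ES(t,s+1)/ES(t,s); their geometric mean
F(t) = (Π F(t,s))^(1/(K−1)) and its log2 form; enrichment proportions
EP(t,s) = ES(t,s)/Σ ES(·,s) normalised within a GO level (a pie-chart
share among equally specific terms); monotone-trend flags with non-strict
inequalities (a constant trajectory is both non-decreasing and
non-increasing).  The geometric mean telescopes to
(ES(t,K)/ES(t,1))^(1/(K−1)): permuting interior samples leaves it
unchanged, while swapping the first and last samples negates the log2
form — the statistic is deliberately sensitive to sample order, which is
what makes it meaningful for time series.

### Assumptions

* Inputs are already normalised (RPKM/FPKM or log-ratios); no
  count-level normalisation is performed.
* mRNA level is used as a proxy for functional activity; the weighting
  is linear in log-abundance.
* Sample order is the experimental order; the user, not the tool,
  asserts it.

## Ontology handling

* Levels are shortest-path distances from a term to its namespace root
  over a configurable relation set (`is_a` + `part_of` by default;
  `regulates`-type edges excluded).  Shortest-path is the convention of
  mainstream GO browsers and makes "the deepest level" well defined.
* Each namespace is analysed independently; cross-namespace edges are
  ignored.
* Obsolete terms are excluded from levels, scoring and reports;
  annotations to them are remapped through `alt_id`/`replaced_by` when
  possible, otherwise dropped with a logged count.
* Annotations follow the true-path rule by default (`propagate=True`);
  direct-only scoring is available (`--no-propagate`).  Under
  propagation ES(parent) ≥ ES(child) holds edge-wise in every sample,
  because the parent's annotated gene set is a superset.
* GAF rows with a `NOT` qualifier are dropped; all evidence codes are
  accepted unless an exclusion list is supplied.

## Outlier search

Within one level, the log2 average fold changes of the included terms are
screened with a two-sided Grubbs test: G = max|x − mean|/sd against the
exact critical value ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n)
quantile of Student's t with n−2 df.  The search starts at the deepest
annotated level and walks toward the root, stopping at the first level
with at least one outlier; levels with fewer than 3 included terms, or
zero spread, are recorded as skipped.  No multiple-testing correction is
applied across the visited levels: the search stops at the first hit, and
its purpose is candidate generation, not family-wise error control.

Defaults: two-sided, α = 0.05, **single pass**.  Grubbs is formally a
one-outlier test; sequential re-testing after removal spends a further
~α of type-I probability per pass and is known to mis-state its nominal
level.  Sequential removal is still available (`iterative=True`,
CLI `--iterative`) for surfacing several candidate terms, with that caveat
documented; values tied at the maximal deviation are always flagged
together.  Terms with a zero score in any sample cannot enter the fold
statistics (division by zero, log of zero); they are flagged and excluded
rather than patched with a pseudocount, which would manufacture fold
changes with no definition behind them.

## Two-sample comparison

* Chi-square homogeneity on a 2×m table, one GO term per bin, the
  real-valued enrichment scores used directly as bin counts; df = m−1.
  Because scores are not integer counts, the statistic scales linearly
  with the overall score magnitude — doubling both samples doubles the
  statistic — and a warning is emitted whenever any expected value falls
  below 5.  Bins scoring zero in both samples are dropped.
* Two-sample Kolmogorov–Smirnov on the two per-term score lists
  (asymptotic p).  KS has no paired form; the per-term pairing is kept
  only in the report's bin listing.

## Synthetic scenarios

`ScenarioSpec` defaults describe the study conditions used throughout the
tests: a layered DAG with 1 root, 3 mid-level and 9 deepest terms (every
non-root term has an `is_a` parent in the layer above and a 30% chance of
an extra `part_of` parent), 200 genes of which 9 × 20 are annotated (one
disjoint block per deepest term), K = 3 ordered samples, a log-normal
abundance baseline (median 10 RPKM, ln-sd 1.5 — the dynamic range of a
typical RPKM table), per-step noise of sd 0.1 on log2(e+1)
(multiplicative on e+1), and a planted fold of 4 on the first deepest
term.

The planted signal is geometric in log2(e+1) space: each step maps
y → fold·y for the planted term's genes.  This makes the term's score obey
ES(t,s+1) = fold·ES(t,s) exactly, so the recovered average fold change
equals the planted fold in the noiseless limit and ground truth is closed
form.  (Multiplying e+1 itself by the fold would shift ES *additively* —
by log2(fold) per gene — and admit no exact closed-form fold target.)
Negative abundances produced by noise are clipped at zero with a logged
count.

What the generator does **not** emulate: correlated expression between
genes of different terms, genes annotated to several terms, overlapping
annotation blocks, heavy-tailed or zero-inflated counts, and realistic GO
topology (term fan-in, multiple namespaces).  Passing the planted-recovery
tests therefore demonstrates correctness of the statistics and the search
machinery, not power on real annotation structure.

## Numerical choices

* Identity checks (EP column sums, telescoping, exp2 consistency) are
  asserted at relative 1e-9.
* Report TSVs serialise every number with 12 significant digits and a
  fully specified sort order (level descending, |log2 fold| descending,
  term id), so reruns are byte-identical.
* Excluded terms carry NaN ("NA" in TSV), never silent zeros.
* Duplicate gene ids in an expression table are a fatal validation error
  (the score of a duplicated gene would be ambiguous), not silently
  aggregated.
* Expressed-but-unannotated genes contribute to no term and are counted
  in the log; annotated-but-unexpressed genes contribute nothing.

## Problem sizes

The test-suite and acceptance-script scenarios use the default fixture
(13 terms, 200 genes, 3 samples) with 100–1000 replicates per property and
10,000 Monte-Carlo draws for the Grubbs type-I calibration; these sizes
give stable estimates (3-standard-error tolerances) while keeping a full
run in seconds.

## Known limitations

* The chi-square comparison inherits the scale sensitivity of using
  real-valued scores as counts; its p-values should be read
  comparatively, not as calibrated error rates.
* The level-wise Grubbs screen assumes approximate normality of log2
  average folds within a level; heavy-tailed fold distributions will
  inflate detections.
* With fewer than 3 included terms at every level the search cannot run
  and reports `level_found = None` with diagnostics.
* Case-study-scale inputs (tens of thousands of genes, full GO) stream
  through the same code paths but term scoring is dense per term; very
  large term sets trade memory for simplicity.
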