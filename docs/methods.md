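# Methods

## Problem and scope

`gnibench` measures how the *preprocessing* of an RNA-seq count matrix —
rather than the inference algorithm itself — changes the quality of an
inferred gene regulatory network. A preprocessing *combination* is one cell
of the cross product

* **data type** (6): raw counts, counts-per-million (CPM), transcripts-per-
  million (TPM), and the log2 of each;
* **normalization** (5): TMM, RLE (median-of-ratios), VST, quantile
  normalization (QN), or none;
* **copula transform** (2): per-gene rank scaling on or off;
* **association estimator** (5): Pearson (PCC), Spearman (SCC),
  Pearson-based Gaussian MI (PBG), B-spline MI, Chao-Shen MI;

300 combinations in all, 192 once CS and QN are excluded. Each processed
matrix feeds one of three inference algorithms (RELNET, C3NET, ARACNE), and
each predicted network is scored against a reference interaction set by
precision, TP/(TP+FP). Because reference interaction databases are far from
complete, absent edges carry no information: true/false *negatives* are not
defined, so recall-type metrics are deliberately not reported by default
(recall is available for synthetic runs where the ground truth is
complete). Overlap significance is the upper-tail hypergeometric
probability of at least the achieved overlap when drawing the predicted
number of pairs from all C(n_genes, 2) candidate pairs; Fisher's one-sided
exact test is provided as an equivalent alternative.

## Pipeline order and the pseudocount

Filtering operates on **raw** counts: a gene is removed when its CPM is
≤ 0.1 in at least 20% of samples, or its maximum CPM is ≤ 0.7, or its mean
CPM is < 0.35 (all four thresholds configurable). The thresholds only make
sense on raw counts (0.1 CPM ≈ 2 counts at 20 M depth), so the add-one
pseudocount is applied *after* filtering, exactly once, before the
data-type transform; every later stage sees the pseudocounted matrix. Rule
one is implemented in its literal reading ("remove when at/below the
threshold in at least the fraction"); the conventional keep-side reading is
reachable through the thresholds.

Unannotated rows (literal `NA`/empty symbols) are dropped first; duplicated
symbols collapse to the row with the highest raw-count variance (ties keep
the first occurrence). The optional variance filter removes the
floor(1/5 × n_genes) lowest-variance genes, with variance computed on the
CPM scale so sequencing depth does not confound the cross-gene comparison.

## Normalization details

* **TMM** — reference sample is the one whose 75th-percentile count
  fraction is closest to the mean of those. Per sample, the per-gene log2
  expression ratios M against the reference (library-size adjusted, genes
  expressed in both) are doubly trimmed — 30% of the M extremes and 5% of
  the A extremes on each side, the cited method's defaults — and the factor
  is 2 to the inverse-asymptotic-variance-weighted mean of the survivors.
* **RLE** — per-sample median ratio to the geometric-mean pseudo-reference,
  computed over genes with nonzero counts in every sample.
* Both factor sets are standardized to product 1, and both are estimated on
  the (pseudocounted) counts regardless of the data type being normalized;
  the factors then rescale the data-type matrix column-wise. The
  alternative composition (normalizing the transformed matrix directly) is
  not meaningful for count-based factor estimators.
* **VST** — per-gene method-of-moments dispersions α_g = max(0, (s²−μ)/μ²)
  on RLE-normalized counts; the trend α(μ) = a0 + a1/μ is fit by
  iteratively reweighted least squares with two rounds of outlier
  down-weighting (deterministic, no seed). The closed-form monotone map

      vst(x) = log2( (1 + a1 + 2·a0·x + 2·√(a0·x·(1 + a1 + a0·x))) / (4·a0) )

  approaches log2(x) for large x (slope within 1% at x = 10⁴). With fewer
  than 10 positive-dispersion genes the fit is declared degenerate and
  log2(x+1) is used, with a logged warning. When VST is selected the
  transformed counts *replace* the data-type matrix — the stabilized scale
  is the point of the method — while the data-type tag is kept for
  bookkeeping.
* **QN** — each column's values are replaced by the across-column mean of
  order statistics at its ranks; ties receive the mean of the implied
  values, which makes the map deterministic, symmetric and idempotent.

## Association estimators

The copula transform replaces each gene's values by average ranks divided
by (n+1), keeping outputs strictly inside (0, 1). PCC/SCC store |r| as the
edge strength with the sign kept as an edge attribute (relevance networks
rank by strength; the sign distinguishes activation from repression).
PBG = −½ ln(1 − r²), in nats, strictly increasing in |r|.

The B-spline estimator spreads each observation fractionally over B = 10
bins using B-spline basis functions of order k = 2 (memberships sum to 1
per observation) and takes the plug-in MI of the weighted joint histogram;
k = 1 reduces exactly to hard equal-width binning. The Chao-Shen estimator
discretizes into B = 10 equal-width bins and computes
MI = Ĥ(X) + Ĥ(Y) − Ĥ(X,Y) with each entropy coverage-adjusted
(C = 1 − f₁/n, p̃ = C·p̂, Horvitz–Thompson inclusion correction). All MI is
in nats; small negative plug-in estimates are clamped to 0. B = 10 is the
common default for histogram MI at these sample sizes and is configurable.

## Inference and thresholding

RELNET keeps every pair scoring at or above the threshold. C3NET keeps, per
gene, only its single strongest above-threshold edge (ties break to the
lexicographically smallest partner for determinism). ARACNE applies the
data processing inequality to the relevance network: an edge is removed
when some third gene closes a triangle in which it is strictly weakest by
more than ε (default ε = 0, the setting under which the DPI removes the
weakest edge of every triangle). Removal decisions are evaluated
*simultaneously* against the pre-pruning edge set, so the result is
independent of traversal order. At equal threshold the outputs nest:
C3NET ⊆ ARACNE(ε = 0) ⊆ RELNET, because a gene's maximal edge can never be
the strict minimum of a triangle.

Three threshold modes are provided since no single convention is canonical:
a **permutation** null (each gene's samples shuffled independently, the
association matrix recomputed per permutation, threshold at the (1−α)
quantile of pooled off-diagonal null scores), a **top-k** order statistic
to target a given prediction count, and a user-supplied **absolute** value.
The pooled permutation null is a *per-pair* level: with P candidate pairs
an α of 0.01 admits ≈ 0.01·P background pairs. Recovery analyses on the
synthetic fixture therefore use the multiplicity-aware α = 10⁻⁴ ≈ 2/P for
its ~2×10⁴ pairs, with 25 permutations so the extreme quantile rests on
~5×10⁵ pooled null draws.

## Rank aggregation and studies

Per dataset (and per inference algorithm), combinations are ranked by
descending precision, ties sharing the minimum rank; combinations are then
compared by the median (plus mean/best/worst) of their ranks across
datasets, sorted by median with mean rank and label as deterministic
tie-breaks. Sample-size curves subsample columns without replacement using
nested draws — each replicate fixes one random ordering and each size takes
its prefix — so adjacent sizes differ by sampling noise as little as
possible; the default is 3 replicates (5 in the recovery analyses). The
variance-filtering study reruns the grid on each dataset with and without
the bottom-fifth variance filter, labeling the filtered variant `…HV`.

## The synthetic generator

The generator emulates the benchmark's target data: negative-binomial
counts (variance μ + φμ², so variance grows with the mean as in real
RNA-seq), a hub-shaped ground-truth network, uneven library sizes, and an
incomplete reference. Defaults: 200 genes × 100 samples; 5 hub regulators
with 10 targets each (hub topology deliberately exercises the
hub-domination failure mode and DPI behavior on stars); latent signal 0.9
(target latent = 0.9·hub + √(1−0.81)·noise); dispersion φ = 0.05, a typical
bulk asymptotic dispersion; library sizes uniform in 0.5–2 million —
scaled down from real tens-of-millions depths in total count only;
log-normal gene lengths around 1.5 kb; per-gene baseline abundances
log-normal (σ = 1.5 on the log scale) mapped through an exponential link
with latent scale 0.7, so expression spans several orders of magnitude.
The reference keeps 60% of true edges and adds 50 decoys by default,
mimicking an incomplete literature database (coverage 1 with no decoys is
used where a complete truth is needed).

What the generator does **not** model: compositional library effects beyond
those induced by the planted signal itself, batch effects, isoform-level
length variation, zero inflation, and correlated background modules.
Passing tests therefore show that the pipeline machinery is correct and
that the estimators/algorithms behave as designed under NB noise — not that
any particular combination is best on real tissue data, which is exactly
why the grid-and-rank machinery exists.

One real-data phenomenon the generator *does* reproduce: per-sample
scaling (CPM) of a matrix dominated by a few co-varying hubs induces weak
positive correlations among background genes (closure effect), which can
raise the predicted-edge count under permissive thresholds. This is the
main source of run-to-run variation in the recovery precision.

## Problem sizes and numerical choices

The bundled analyses run at desk scale: recovery and sample-size analyses
on the 200×100 default fixture; grid record-count verifications on a
30 genes × 30 samples fixture with top-k thresholding (k = 30), where a
900-record grid takes seconds. Determinism: every stochastic stage takes an
explicit seed (`numpy.random.default_rng`); permutation thresholds, random
networks, subsample draws and the generator are all reproducible bit for
bit. Numerical guards: correlations clamped to |r| ≤ 1 − 10⁻¹² before the
PBG log; constant expression rows score 0 by convention; factor
standardization holds to 10⁻¹⁰ relative; DPI uses an additive tolerance
(at ε = 0 additive and multiplicative coincide).

## Known limitations

* The permutation null pools all pairs, ignoring the dependence among pairs
  sharing a gene; it is a pragmatic null, adequate for thresholding but not
  for per-edge p-values.
* The VST trend fit is a lightweight robust regression, not a gamma-family
  GLM; on data with very few genes or near-Poisson dispersion it falls back
  to log2(x+1).
* TPM uses a single length per gene symbol (no effective-length or isoform
  model).
* `run_grid` recomputes the association matrix per inference algorithm;
  records are independent tasks and may be parallelized externally
  (outputs are append-only and resumable), but no scheduler is bundled.
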