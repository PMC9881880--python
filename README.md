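# gnibench

Benchmarking RNA-seq preprocessing for gene network inference.

Gene network inference (GNI) algorithms were mostly designed for microarray
data, and RNA-seq counts — heteroscedastic, skewed, depth-confounded —
violate their assumptions in ways that depend heavily on how the counts are
preprocessed. `gnibench` is a toolkit for answering, on *your* dataset,
which preprocessing to use before inferring a gene regulatory network: it
enumerates every combination of

* **data type** — raw, CPM, TPM, and their log2 variants (6),
* **normalization** — TMM, RLE, VST, quantile, or none (5),
* **copula transform** — per-gene rank scaling, on/off (2),
* **association estimator** — Pearson (PCC), Spearman (SCC), Pearson-based
  Gaussian MI (PBG = −½ ln(1 − r²)), B-spline MI, Chao-Shen MI (5),

300 combinations in all (192 after excluding CS and QN), runs each through
RELNET, C3NET and/or ARACNE (DPI pruning, ε = 0), and scores every
predicted network against a reference interaction set by

    precision = TP / (TP + FP)

with overlap significance from the upper-tail hypergeometric test over all
C(n_genes, 2) candidate pairs. Because interaction databases are
incomplete, negatives are uninformative and recall-type metrics are
deliberately omitted. Combinations are compared across datasets by the
median of their per-dataset precision ranks (minimum rank on ties). The
package also includes a random-network baseline, sample-size curves by
nested subsampling, a variance-filtering comparison, and a synthetic
negative-binomial generator with a planted hub network so everything is
testable without downloading any data.

## Worked example

Generate a planted-network dataset (200 genes × 100 samples, 5 hubs with 10
targets each at latent correlation 0.9), run one preprocessing combination
end to end, and compare against the random baseline:

```python
import gnibench as gb
from gnibench.benchmark import PreprocessingCombo, run_combo
from gnibench.gni import GniConfig
from gnibench.evaluation import Universe

cfg = gb.SyntheticConfig(seed=1, reference_coverage=1.0, reference_noise_edges=0)
counts, lengths, truth = gb.generate_planted_dataset(cfg)
ref = gb.degrade_reference(truth, cfg)
universe = Universe.from_genes(counts.index, ref)

combo = PreprocessingCombo(
    datatype=gb.DataType.L2CPM,
    normalization=gb.NormalizationMethod.NONORM,
    ct=False,
    estimator_cfg=gb.EstimatorConfig(estimator="PCC"),
)
gcfg = GniConfig(algorithm="c3net", threshold_mode="permutation",
                 n_permutations=25, alpha=1e-4, seed=2)
rec = run_combo(counts, combo, gcfg, ref, universe, lengths=lengths, dataset="sim")
print(f"{rec.gni}.{rec.combination}: precision={rec.precision:.3f} "
      f"tp={rec.tp} predicted={rec.predicted} p={rec.p_value:.2e}")

mean_p, _, _ = gb.random_baseline(list(counts.index), rec.predicted, ref,
                                  universe, n_networks=100, seed=3)
print(f"random baseline precision: {mean_p:.4f} "
      f"({rec.precision / mean_p:.0f}x below the pipeline)")
```

prints

```
c3.PCC_noCT_NoNorm_l2cpm: precision=0.750 tp=39 predicted=52 p=1.10e-99
random baseline precision: 0.0027 (279x below the pipeline)
```

C3NET with Pearson correlation on log2 CPM predicts 52 edges of which 39
are planted regulator–target pairs — precision 0.75, about 280 times the
precision of size-matched random networks, with an overlap that could not
plausibly arise by chance. The record label reads
`{gni}.{estimator}_{CT|noCT}_{normalization}_{datatype}`.

The same pipeline is available from the shell:

```
gnibench simulate --genes 200 --samples 100 --seed 42 --out-prefix sim/
gnibench filter --counts sim/counts.tsv --out sim/filtered.tsv
gnibench grid --counts sim/filtered.tsv --reference sim/reference.tsv \
    --lengths sim/lengths.tsv --exclude-estimators CS \
    --exclude-normalizations QN --out records.tsv
gnibench rank --records records.tsv --out ranks.tsv
```

`rank` emits one row per combination with its median, mean, best and worst
precision rank across datasets, sorted by median rank.

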