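# maci

Multi-source co-adaptation classifier: jointly learns one kernelized model
per labeled source domain against a shared unlabeled target, combining

- a robust `l2,1` regression loss against a nonnegative soft-label matrix,
- marginal + class-conditional MMD alignment of each source to the target
  (class-conditional terms use pseudo-labels from a base classifier),
- graph-Laplacian label smoothing over class-aware k-NN affinity graphs,
- an `l2,1` row-sparsity penalty (joint feature selection),
- a model-alignment regularizer tying every source model to a learned
  reference model, with learned source weights, and
- a trace-norm coupling across the stacked source models.

The objective is minimized by alternating iteratively-reweighted least
squares with closed-form simplex updates for the source weights; the exact
objective trace is monotonically non-increasing by construction and a
window-based criterion stops the sweeps. Prediction is a weighted vote of
the per-source models in their empirical kernel maps.

## Python API

```python
from maci import SyntheticConfig, generate, ProblemConfig, fit_maci, predict

sources, target, truth = generate(SyntheticConfig(S=3, c=3, d=5,
                                                  n_per_class=15, seed=0))
model = fit_maci(sources, target, ProblemConfig(seed=0))
labels, scores = predict(model, target.features)
```

Key modules:

- `maci.datasets_io` — delimited feature tables, label codebooks, configs
- `maci.kernels` — kernel families (gaussian / laplacian / inverse
  (square) distance / linear), empirical kernel maps, multi-kernel stacking
- `maci.graphs` — class-aware k-NN affinity graphs and Laplacians
- `maci.distribution_alignment` — MMD coefficient matrices, the combined
  alignment operator, and model-discrepancy metrics
- `maci.solver` — the alternating IRLS optimizer
- `maci.model` — pseudo-labeling, end-to-end fit, ensemble prediction, row
  ranking (feature/prototype selection), empirical chance levels
- `maci.synth` — seeded synthetic multi-source benchmarks

## CLI

```sh
maci simulate --config synth.yaml --out-dir data/
maci fit --sources data/source_0.csv data/source_1.csv \
         --target data/target.csv --config cfg.yaml --out model.bin
maci predict --model model.bin --input data/target.csv --out labels.csv
maci chance-level --labels labels.csv --reps 100
```

Exit codes: 0 ok, 2 validation/parse error, 3 numerical failure.

Feature tables are plain CSV/TSV, one sample per row, labels (if any) in
the trailing column. Configs are YAML files whose keys mirror
`ProblemConfig` / `SyntheticConfig`.

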