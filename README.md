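# cobind

Discovery of combinatorial regulatory codes from ChIP-seq co-binding: the
package scores gene–factor association with exponential distance decay,
clusters genes into five named binding classes, builds merged genomic
islands ("neighborhoods") from peaks of each cluster's main factors of
interest, scans them for cofactor motif sites against a first-order Markov
background with matched-control-calibrated thresholds, screens TF-combination
features (0–2 main factors + one cofactor motif) for differential behavior
between ES-up and ES-down genes under BH FDR control, selects features with a
naive Bayes classifier over a (k1, k2) cross-validation grid, and predicts
and validates per-feature target genes by leave-one-feature-out perturbation
of the classifier's probability ratio.

A first-class synthetic-data module generates every input the pipeline reads
(soft-masked genome FASTA, TSS annotation, per-factor peak tables, PWMs,
two-stage expression, an independent validation expression set) with planted
cluster structure, planted cofactor co-binding and a ground-truth manifest,
so the whole analysis is testable end to end without external data.

## Test

```sh
python -m pytest -q tests/
```

The suite includes per-module unit tests with independent brute-force
oracles, property tests (merge order-independence, strand symmetry,
monotonicity), and `tests/test_acceptance.py`, which implements the
acceptance criteria (feature-count combinatorics, grid structure, oracle
equivalence, motif-scan calibration, planted-feature recovery over 10 seeds,
null FDR control over 20 seeds, classification gain, and target-validation
behavior). The simulation-backed criteria run on reduced bundles so the full
suite completes in a few minutes on one CPU.

## Command line

```sh
# generate a synthetic input bundle with its ground-truth manifest
cobind synth --seed 1 --outdir out/inputs

# full pipeline on a synthetic bundle (default) or on real inputs via config
cobind run --seed 1 --outdir out/run
cobind run --config my.yaml --seed 1 --outdir out/run

# stage-subset reruns against a cached run directory
cobind test-features --seed 1 --outdir out/run
cobind classify      --seed 1 --outdir out/run
cobind targets       --seed 1 --outdir out/run
```

The YAML config may override any pipeline constant (`d0`, `assoc_window`,
`extend`, `merge_dist`, `min_peaks`, `n_controls`, `motif_p`, `fc_threshold`,
`alpha`, `fdr_q`, `kmax`, `folds`, `kmeans_k`, …), supply explicit input
paths (`genome_path`, `genes_path`, `peak_paths`, `pwms_path`,
`expression_path`, `validation_path`), or carry a `synthetic:` block with
generator settings. Every constant defaults to the reference value
(d0 = 5000 bp, 1 Mb association window, ±500 bp extension and merge distance,
≥2 peaks per neighborhood, 20 matched controls, motif P-value cutoff
9.09e-5, fold-change threshold 2 at α = 0.05, FDR 10%, k1, k2 ≤ 20, ten-fold
CV, k-means k = 5).

A run directory contains: association score matrices (raw and
log/quantile-normalized), cluster assignments, ES gene calls, per-cluster
neighborhood BED + membership tables, motif-site BED + calibrated thresholds,
gene × feature log-score matrices (`NA` = no supporting neighborhood), the
significant-feature table with reasoned cofactor roles, CV report and
selected features, predicted targets ranked by probability-ratio fold change,
a validation summary (N_b, N_e, Pc, fold-change quartiles), and a
`manifest.json` with the config hash and seeds.

## Library use

```python
from cobind.synth import SyntheticConfig, generate_bundle
from cobind.pipeline import analyze_bundle

bundle = generate_bundle(SyntheticConfig(seed=1))
result = analyze_bundle(bundle)
result.clusters["Oct4"].labels          # feature direction labels
result.clusters["Oct4"].selection       # (k1, k2) CV selection
```
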