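# cellens

Ensemble exploration of growth–division dynamical models under discrete
phenotype constraints, with downstream robustness, abundance-variability and
network-module-classification analyses.

The package implements:

* **model_core** — fixed-step Euler simulation of a growth–division model
  (division detection, daughter-cell following), phenotype classification
  (0 = multiply periodic, 1 = viable, 2 = inviable via size cap / arrest /
  blow-up) and time-averaged abundances.
* **toy_model** — a synthetic three-module (START, S/G2/M, EXIT) relaxation
  oscillator with a calibrated reference parameter vector, strain-panel
  combinatorics (single/double/triple rate eliminations), a screened
  reference ensemble generator, and a module-structured synthetic feature
  table for the classifier.
* **explore** — Latin hypercube screening and a modified differential
  evolution whose selection is gated by pluggable feasibility criteria:
  FC1 (training phenotypes captured, judged on 32-bit-truncated vectors),
  FC2 (strict expansion of the parent population's estimated volume), and
  FC3 (novel prediction vector over the prediction panel). Includes biased
  initial-population selection (volume-greedy and
  one-representative-per-prediction-vector modes).
* **ensemble_metrics** — prediction matrices, prediction range S(P),
  sampling/feasibility efficiencies, log bounding-box volume, parameter
  range ratios.
* **robustness** — one-at-a-time perturbation grid (±20/40/60/80% plus
  set-to-zero) with indicator tensors and the R̂ / R̃ / R̄ / Ř aggregates,
  plus pairwise ensemble comparison.
* **abundance_stats** — relative-abundance CV statistics across ensembles,
  per-mutant and per-protein variability scores with ranks, percentiles and
  high/low categories, orientation-correlation checks, and per-process
  aggregation.
* **module_classifier** — a hand-rolled random forest (bootstrap per tree,
  out-of-bag vote fractions) with one-vs-rest ROC AUC, repeated evaluation,
  one-sided Z-tests against chance, and a label-permutation null.
* **cli** — a data-driven scheme registry (ids 1–8), end-to-end pipeline,
  and plain-text (TSV/YAML) artifacts stamped with a config hash.

## Command line

```sh
cellens fixture --out fixture/            # toy model config, panels, maps
cellens explore --scheme 8 --generations 100 --seed 1 --out run/
cellens predict --ensemble run/ensemble.tsv --panel run/panel.tsv
cellens robustness --ensemble run/ensemble.tsv --params mu,ks_A1,ki_E,theta
cellens stats --records run/abundance_records.tsv --out stats/
cellens classify --records records.tsv --annotation annotation.tsv --permute
cellens pipeline --scheme 8 --seed 1 --out pipeline/
```

Scheme ids: 1 = LHS screen, 2 = jittered-reference screen, 3 = DE with a
random initial population (FC1 only), 4/5 = volume-biased initialisation on
critical axes (FC1 / FC1+FC2), 6 = volume-biased on all axes (FC1+FC2),
7 = prediction-diverse + volume-biased initialisation with FC1+FC2+FC3,
8 = the same initialisation with FC1+FC3.

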