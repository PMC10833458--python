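# autonomy

Composite gene-signature scoring with StepMiner thresholds, for
transcriptomic cohorts where a directional signature (for example, one
derived from a growth-signaling-autonomy knockout comparison in breast
cancer cells) must be scored across samples, used to classify conditions,
and tied to outcome.

The package implements the full analysis chain as a library plus numbered
analysis drivers:

1. **Step-function fitting.** For each gene, sort its values and fit a
   one-step function by choosing the split *k* that minimises the residual
   sum of squares; the regression statistic
   F = [Σ(x̂ᵢ − x̄)²/(m − 1)] / [Σ(xᵢ − x̂ᵢ)²/(n − m)] (m = 3) measures step
   sharpness, and the threshold SThr = (μ_L + μ_R)/2 separates low from
   high expression. `binarize` turns a matrix into high/low calls.
2. **Composite scoring.** Per-gene modified Z-score
   z = (expr − SThr)/(3·sd); the signature score of a sample sums z over
   up-genes minus down-genes. Group separation is reported as ROC-AUC
   (Mann–Whitney U / n₁n₂, ties ½) with Welch's unequal-variance t-test.
3. **Signature derivation.** Per-gene Welch test on log2 values,
   Benjamini–Hochberg FDR, and a |logFC|/adjusted-p filter producing a
   directional signature; generic hypergeometric over-representation
   against GMT gene sets.
4. **PPI hubs.** Induced subgraph of an edge list on filtered proteins
   (ratio ≥ 2, significance ≥ 20); degree z-score
   Z_d = (deg − mean)/sd_pop; hubs at Z_d ≥ 3.
5. **Survival.** Kaplan–Meier curves of cohorts split high/low at the
   StepMiner threshold of their composite scores; two-group log-rank test.
6. **Synthetic data.** Seeded generators for step-structured expression
   with a planted 29-up/3-down signature, score-linked exponential
   survival, and hub-planted interaction graphs — so the whole chain is
   testable without external downloads.

See `docs/methods.md` for the model details and design choices.

## Worked example

The numbered scripts under `analysis/` run the chain on a simulated cohort
(500 genes × 40 samples, 20 "autonomous" vs 20 "control"; planted
29-up/3-down signature with a 2.0 log2-unit effect):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_threshold_and_binarize.py
python analysis/03_derive_signature.py
python analysis/04_score_and_classify.py
python analysis/05_ppi_hubs.py
python analysis/06_survival_stratification.py
```

which prints, among other lines:

```
DEG filter (|logFC| > 1.0, padj < 0.01): 29 up / 3 down
overlap with planted truth: 32/32 genes
ROC-AUC = 1.0000 (positive class: autonomous, direction up)
Welch's t = 74.33, p = 3.331e-41
hubs (Z_d >= 3): ['HUB04', 'HUB03', 'HUB01', 'HUB02', 'HUB05']
planted hub recovery: 5/5, 0 false positives
log-rank chi2 = 178.32, p = 1.129e-40
```

The derivation stage recovers exactly the planted signature (29 up,
3 down); its composite score separates the two conditions perfectly
(AUC = 1.0); all five planted hubs — and nothing else — exceed the degree
z-score cut; and splitting a 200-subject score-linked cohort at the
StepMiner threshold of its scores yields strongly separated survival
curves. Outputs (thresholds, DEG table, score report, KM curves, plots)
land under `results/`.

The same stages are available as a CLI (`autonomy thresholds|binarize|
score|deg|ppi|survival|simulate|run`); `autonomy run --config run.yaml`
executes the configured stages end-to-end and writes a checksummed run
manifest.

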