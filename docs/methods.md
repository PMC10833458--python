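# Methods

## The step-fit model

Each gene's expression across a cohort is modelled as a one-step function:
when the values are sorted ascending, the first *k* belong to a "low"
segment with mean μ_L and the remaining *n − k* to a "high" segment with
mean μ_R. The fit evaluates every split position *k* ∈ {1, …, n − 1} and
keeps the one minimising the residual sum of squares, which is equivalent
to maximising the between-segment sum of squares — the implementation uses
the cumulative-sum identity for the latter and then recomputes the SSE of
the chosen split directly, so the reported SSE is numerically identical to
an explicit residual computation. The regression statistic is

    F = [ Σ (x̂ᵢ − x̄)² / (m − 1) ] / [ Σ (xᵢ − x̂ᵢ)² / (n − m) ]

with *m* = 3 model degrees of freedom (two segment means plus the step
position). F is reported as a descriptive sharpness measure only; no
p-value is attached to it. The per-gene threshold is the midpoint
SThr = (μ_L + μ_R)/2.

Numerical choices:

* **Ties between equal-SSE splits** break toward the smallest *k* (the
  first maximum of the between-segment sum), so fits are reproducible.
* **Zero-variance series** are flagged `no_step`; the threshold defaults to
  the constant value and F is undefined (NaN).
* **Values are sorted before fitting.** The step model is a time-series
  construction, but cohort samples are unordered; sorting is the one
  ordering under which a per-gene threshold is well defined, and it makes
  the threshold invariant to sample permutation by construction.
* **Ties at the threshold call low** everywhere the threshold is used —
  binarization and survival stratification share the rule `high ⇔ value >
  SThr`. With a positive `margin`, values within ±margin of SThr are called
  intermediate (NaN); the margin default is 0 (strictly binary output).

## Composite signature scoring

A signature is a list of genes with directions ±1. Each gene is normalised
to a modified Z-score centred on its step threshold,

    z(g, s) = (expr(g, s) − SThr(g)) / (3 · sd(g)),

where sd(g) is the gene's sample standard deviation (ddof = 1) across
**all** samples of the dataset. We read the scaling as division by three
standard deviations — roughly the half-width of the expression range under
a Gaussian model, so z ≈ ±1 at the extremes; the alternative reading
(multiplying by sd/3) would make scores grow with per-gene noise and defeat
the normalisation, so it is not offered. The composite score of sample *s*
is

    score(s) = Σ_up z(g, s) − Σ_down z(g, s)       (mode "signed", default)

or the plain sum over all signature genes (mode `sum_all`, kept for
reproduction studies that want the literal summed-normalised-values
definition). Genes missing from a dataset are dropped with a logged list —
the realistic behaviour when one signature is scored across many platforms
— and zero-variance genes are excluded with a warning; scoring fails only
when no usable gene remains.

Group separation is summarised by ROC-AUC (probability that a random
positive-group sample outscores a random negative-group sample; computed
as the Mann–Whitney U statistic normalised by n₁·n₂, ties counted ½) and
Welch's two-sample t-test (unpaired, unequal variances, Satterthwaite
degrees of freedom). AUC is invariant under any strictly increasing
transform of the scores, so no rescaling is applied before classification.

## Signature derivation from differential expression

Matrices are assumed to be log2-scale (log-CPM with pseudocount 1.0 for
count input; each column scaled to 10⁶ before the log). The per-gene test
is Welch's t on the log2 values with logFC the difference of group means
(first-listed group minus second); count-level dispersion models are
deliberately out of scope since every downstream stage consumes log-scale
values. Benjamini–Hochberg step-up adjustment controls FDR across genes.
The filter stage keeps genes with |logFC| above a cut and adjusted p below
a cut (defaults 5 and 0.01 — appropriate for strongly separated real
conditions) and assigns directions by the sign of logFC. Degenerate genes
that are constant within both groups are given p = 1 when the means agree
and p = 0 when they differ, rather than NaN.

Over-representation of a gene set uses the one-sided hypergeometric upper
tail P(overlap ≥ observed) with the universe defaulting to the genes
present in the matrix — the only universe the data can support — and BH
adjustment across sets.

## PPI hubs

Proteins passing an enrichment filter (intensity ratio ≥ 2 and
significance score ≥ 20 by default; both inclusive) induce a subgraph of an
undirected interaction edge list. Self-loops are dropped, duplicate and
reversed edges merged, and isolated proteins retained. The degree z-score
is Z_d(v) = (deg(v) − mean)/sd with the **population** standard deviation
(ddof = 0) — the conventional z-score, and the choice under which the
5-node star gives the clean values Z_d(centre) = 2, Z_d(leaf) = −0.5. A
constant-degree graph gets Z_d ≡ 0 by convention. Hubs are nodes with
Z_d ≥ 3 (Z_d ≥ 1 marks "connected" nodes), ranked by degree with ties
broken by node id. Confidence scores in STRING-style edge lists can gate
edges at load but are never used as weights; only degree is analysed.

## Survival stratification

Cohort scores are split into high/low by fitting the same one-step model to
the sorted scores and cutting at SThr (ties low, as above). Survival curves
are Kaplan–Meier product-limit estimates; group comparison is the standard
two-group log-rank test (1 df, two-sided). Events are processed before
censored subjects at tied times. Subjects must arrive pre-aggregated, one
row per subject; when several samples per subject exist upstream, the
caller decides how to collapse them (mean aggregation is a reasonable
utility, not a claim of this package). Hazard-ratio estimation and
multivariable models are out of scope; only the log-rank comparison is
reported.

## What the synthetic generator emulates

`simulate_expression` produces a two-condition log2 matrix: the planted
signature genes (29 up / 3 down by default, mirroring the shape of a
knockout-derived autonomy signature) sit at the mid-baseline (4.0) in the
control group and are shifted by ±2.0 log2 units in the "autonomous" group;
30 % of background genes are bimodal between the low/high mode centres
(2.0 / 6.0) **independently of condition** — the high/low step structure
the threshold model assumes — and the rest sit at a flat per-gene baseline.
Gaussian noise (sd 0.5) is added throughout. Defaults of 20 samples per
group reflect a well-powered two-condition comparison. Because background
genes carry no group information by construction, their per-gene p-values
are uniform, which the tests verify.

`simulate_survival` draws exponential event times with rate
h₀·exp(β·z-score) (h₀ = 0.1, β = 1.5) and independent exponential censoring
(rate 0.02, ≈ 15–20 % censored) — a proportional-hazards world in which a
score-linked prognosis exists to be found. `simulate_graph` overlays
5 planted hubs (≈ 60 connections each) on a 200-node Erdős–Rényi background
(edge probability 0.05, mean degree ≈ 10); at these densities the expected
maximum background degree z-score is ≈ 2.8, so planted hubs separate
cleanly at the Z_d ≥ 3 cut while an occasional hub-free graph can still
brush 3 — the tests treat that as the typical case, not a guarantee.

The generator is Gaussian on the log scale rather than a count model:
every consumer (step fitting, z-scores, Welch tests) operates on log
values, so that is the level at which the statistical structure must be
controlled. A Poisson count mode exists purely to exercise the log-CPM
input path. Consequences for interpretation: passing tests demonstrate
correctness of the machinery and its behaviour under the assumed
structure; they do not establish robustness to heavy-tailed counts,
batch effects, or cross-platform normalisation differences, which real
cohorts exhibit and this generator deliberately omits.

## Pipeline

The orchestrator runs stages single-process in dependency order
(simulate → deg → score → survival → ppi); every stage writes plain TSV
with a provenance header (tool version, config hash, seed), and a JSON
manifest records SHA-256 checksums of all products, so identical
config + seed reproduce byte-identical manifests. The output directory is
excluded from the config hash — it is a location, not an analysis
parameter. Config validation fills defaults, rejects unknown keys, and
checks referenced files before any stage runs.

The synthetic preset derives its signature at |logFC| > effect/2 (1.0 at
the default planted effect of 2.0) rather than the real-data default of 5:
the filter cut must sit below the planted effect for the derivation stage
to be exercised, and half the effect is the natural midpoint between
signal and the null logFC distribution. Problem sizes throughout the test
and acceptance runs (500-gene discovery matrices, 100-per-arm survival
cohorts, 100-seed repetition counts) are chosen so each stage's behaviour
is measured with comfortable statistical margin while a full run stays in
the seconds-to-minutes range.

## Known limitations

* No probe-to-gene collapsing, symbol aliasing, or cross-platform
  normalisation; gene identifiers are opaque strings.
* The per-gene DE test is a location test on log values; datasets with few
  samples or strong mean–variance coupling would be better served by a
  count model upstream.
* Multiclass (> 2 group) AUC, Cox models and multi-step fits are out of
  scope by design.
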