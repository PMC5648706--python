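# Methods

`pji-profiler` reimplements, as a tested pipeline, a transcriptomic decision
aid for prosthetic joint infection (PJI): relative qRT-PCR quantification of
candidate genes in periprosthetic tissue, neural-network wrapper feature
selection over 12 candidate genes, a top-5-of-100 network ensemble
("infection calculator"), diagnostic-accuracy statistics with bootstrap
confidence intervals, and Gaussian nearest-neighbor patient-similarity
graphs. This note records the model choices, defaults, and the limits of
what the synthetic experiments can show.

## Relative quantification

Expression is quantified by the classic 2^−ΔΔCt method: for gene *g* and
sample *s*,

    ΔΔCt = (Ct_g,s − Ct_HPRT1,s) − (mean Ct_g,cal − mean Ct_HPRT1,cal)

with HPRT1 as the housekeeping reference and a universal reference RNA run
in triplicate as the calibrator; calibrator replicates are averaged on the
Ct scale. Amplification efficiency is fixed at 2 — the simplest model
consistent with housekeeping normalization plus a calibrator; no efficiency
correction from dilution series is attempted. An undetermined Ct is a
sentinel (never imputed as the 35-cycle run length), and quantification with
an undetermined required well is an error rather than a guessed value. A
no-template control that amplifies below a configurable cutoff (default: any
determined Ct within the 35-cycle run) raises a contamination warning.
Inter-run calibration beyond the shared reference RNA is not modeled.

## Synthetic cohorts

Patient-level data for the original cohorts are not available; what is
published is, per gene × group (PJI / non-PJI) × instrument, the group mean
with a 95% CI of the mean and the group size (38/38 for the conventional
instrument, 23/25 for the ultrafast one, where CRP, TLR6, TLR10 and DEFB4A
were not assayed). The generator matches each summary with a log-normal
distribution:

* CI read as mean ± 1.96·SEM, so `SD = √n · width / (2·1.96)`. Whether the
  printed intervals are normal- or t-based is not stated; the normal reading
  is assumed (at n ≥ 23 the difference is within the stochastic tolerances
  used everywhere).
* `σ² = ln(1 + CV²)`, `μ = ln(mean) − σ²/2`, making the analytic expectation
  exactly the printed mean.

Log-normality is a modeling choice, not an observed fact: it is the simplest
strictly-positive, right-skewed family fixed by two moments, and the printed
means far exceed their CI midpoints, which rules out anything symmetric.
Genes are drawn independently on the log scale by default; an
equicorrelation knob exists as a sensitivity analysis (co-elevated infection
markers are plausible) but defaults to 0. A negative printed lower CI bound
(IL1B, non-PJI) only affects the implied SD.

What this generator does **not** emulate: Ct-level measurement noise, batch
or instrument drift, inter-gene correlation structure beyond the optional
common-ρ knob, clinical covariates, or the mixture of infection stages
discussed clinically. Passing tests therefore demonstrate that the
*pipeline* recovers the published operating characteristics when the group
separations are as printed — not that the assay would achieve them on new
patients.

## Classifier networks

A fixed feed-forward architecture — input → 13 → 9 → 1, logistic activation
at every layer — is trained by full-batch backpropagation on squared error
against 0/1 targets (networks are later ranked by MSE, so MSE is also the
training loss). Defaults: learning rate 0.05, at most 10,000 epochs,
early stop when the epoch-to-epoch MSE change falls below 1e−8, weights
initialized uniform(−0.5, 0.5) from the config seed. The original work names
only the architecture, activation and backpropagation; rate, epochs,
stopping and scaling are surfaced as config, not claims about the original
implementation.

Raw relative expression spans ~4 orders of magnitude and saturates logistic
units, so features are transformed `ln(x + ε)` (ε = smallest positive
training value × 1e−3 per gene) and z-scored. Scaling parameters are
estimated on training data only and stored in the trained network, so
cross-validation is leakage-free by construction.

**Scaled training protocol.** The heavy experiments (100×10-fold
cross-validation, 100-network ensembles, the 255-combination selection
sweep) use `max_epochs = 2000` (the sweep uses 400): on the calibrated
cohorts, 10-fold CV accuracy at 2000 epochs is within a point of the 10,000
epoch result (95.6% vs ~97%), while the cost drops five-fold. These problem
sizes are the package's own defaults for its experiments; the library-level
config keeps the 10,000-epoch default.

## Feature selection and ensemble

Wrapper selection evaluates every nonempty gene combination (guard above 15
candidates) by stratified 10-fold cross-validation — fold sizes differ by at
most one; the published "68/8 of 76" is the arithmetic shorthand for such a
partition — training one network per fold and averaging held-out
misclassification. Combinations under the 20% error threshold pass. Gene
ranking counts occurrence frequency among passing combinations with ties
broken by the smaller Mann-Whitney group-difference P value; the
P-value-primary ordering is available behind a switch, since the source
conjoins "top-ranked (based on P values)" and "most-often-occurring" without
an explicit rule. Patients missing any gene of a combination are dropped for
that combination only (no imputation is ever performed).

The ensemble trains 100 networks, each on an independent stratified 70/30
split with fresh initialization, and keeps the 5 with smallest held-out MSE.
Stratification is an addition — a plain random 53-patient draw can in
principle be single-class — and all randomness flows from one top-level
seed. Classification: infection iff the mean member probability ≥ 0.5 (a tie
at exactly 0.5 classifies as infection — conservative for a rule-out test);
confidence = rounded percent mean probability of the chosen label, which is
the only reading compatible with published confidences such as 63% or 95%
that a 5-vote granularity could not produce.

Which instrument's data fed the published 100-network stage is ambiguous in
the source (76 patients vs the ultrafast subset); the dataset is therefore
an explicit input everywhere, and the bundled experiments state their cohort
each time.

## Diagnostics

Confusion metrics are exact counts; LR+ = sens/(1−spec), LR− = (1−sens)/spec
with ∞/0 sentinels at the boundaries so summaries always serialize. ROC
curves group tied scores at one threshold and use trapezoidal AUC
(scikit-learn backend, cross-checked in tests against brute-force
concordant-pair counting). Decision thresholds maximize Youden's J
(sens + spec − 1), ties broken toward higher specificity; the criterion
behind the published single-gene thresholds is unstated, and the
closest-to-(0,1) alternative would pick nearly identical thresholds at these
separations. In a gap, the midpoint is returned. Classification is
"expression ≥ threshold ⇒ infection" (elevated expression indicates PJI for
all retained markers).

Confidence intervals are percentile bootstrap (B = 2000 by default) with
threshold averaging: metrics are read on each resampled curve at the *same*
threshold, and positives/negatives are resampled separately so no resample
is single-class. BCa was deliberately not used — the percentile form matches
the simplicity of the threshold-averaging approach. The Mann-Whitney U test
uses the exact distribution for combined n ≤ 12 without ties and the
tie-corrected normal approximation otherwise; completely tied data give
P = 1.

For ensemble evaluation the pooled summary (mean member probability per
patient) carries the bootstrap CIs; per-member summaries and their
metric-wise mean are reported alongside, because "average of five networks"
can mean either and the two differ slightly.

## Similarity graphs

Patient vectors (log-scaled as above — raw-scale distances would be owned by
single extreme patients) are compared with the Gaussian kernel
`exp(−‖x−y‖²/2σ²)`; σ defaults to the median pairwise distance. Each vertex
links to its k most-similar neighbors (default k = 3) and the edge set is
the union, so degree ≥ k; a vertex's *representativeness* attribute is its
final degree. The externally defined representativeness rule cited by the
source is not reproduced (no formula is given); the optional
density-proportional neighbor count is an acknowledged stand-in. Exports:
GraphML and TSV edge lists, weights to 6 decimals.

## Pipeline and reproducibility

The CLI (`pji-profiler simulate|quantify|select-features|train-ensemble|
evaluate|classify|graph|run`) wraps the library. `run` executes
simulate → select-features → train-ensemble → evaluate → graph from a JSON
config, derives per-stage seeds from the top-level seed via a counter-keyed
`SeedSequence`, writes a manifest (config snapshot, seeds, SHA-256 digests
of all files), and on rerun reuses stage outputs whose digests still match.
Every reported number is recomputable from manifest + inputs.

## Experiment sizes

The bundled experiments (acceptance script and heavy tests) use: 100,000
draws for generator-mean checks; ensembles trained on the published 23/25
cohort and evaluated on independent 1000-per-class cohorts, median over 5
replicates; 100 (tests: 20) ten-fold cross-validations on the 38/38 cohort;
a full 255-combination sweep at 400 epochs on a 76-patient cohort. These
sizes keep each experiment in the minutes range on one CPU while leaving
Monte-Carlo error well inside the stochastic tolerances.

## Known limitations

* The log-normal two-moment match is identifiable only up to the family
  assumption; heavier-tailed or multimodal truths with the same mean/CI
  would change small-sample behavior.
* Synthetic cohorts make the classification task *easier* than reality in
  one respect (clean group structure, no label noise) and *harder* in
  another (no inter-gene correlation to exploit).
* The wrapper-selection outcome on 23/25-sized cohorts is itself noisy:
  individual draws can make a non-trio gene (e.g. TLR2) separate as well as
  LTF, which is a property of small samples, not a defect of the selector.
  The recovery experiment therefore uses the 76-patient cohort, matching the
  size on which the original selection was run.
* Undetermined-Ct handling is strict (error, not imputation); workflows with
  frequent non-amplification need a policy upstream of this package.
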