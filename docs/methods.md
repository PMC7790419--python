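# Methods

This note documents the models and procedures `pefrisk` implements, the
defaults it ships, and the design choices made where the protocol was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort generator

The generator replaces a non-public 25-patient clinical cohort (15 women,
10 men, 51–200 daily observations each). One observation per patient-day
carries PEFR (L/min) and four indoor air-quality covariates: daily-mean
PM2.5 (µg/m³), CO2 (ppm), temperature (°C), relative humidity (%).

**Exposures.** PM2.5 and CO2 are log-normal (nonnegative, right-skewed);
temperature and RH are normal, RH clipped to [0, 100]. Parameters are
fitted per sex to published cohort summaries by matching the median and
interquartile range: for a log-normal, `mu = ln(median)` and
`sigma = ln(p75/p25) / (2 * 0.6745)`; for a normal, the analogous moment
match. Defaults encode, e.g., women's PM2.5 41.1 (28.5–54.7) µg/m³ and CO2
1018.5 (847.8–1268.7) ppm against men's 31.8 µg/m³ and 926.2 ppm.

**PEFR process.** Flow follows a first-order autoregression around a
patient-specific baseline with additive linear exposure effects:

    pefr_t = b + phi * (pefr_{t-1} - b)
             + sum_v beta_v * (x_{v,t} - median_v(sex)) + eps_t

with `phi = 0.5`, `eps_t ~ N(0, 18)` L/min, `beta_pm25 = -0.35` L/min per
µg/m³ and `beta_co2 = -0.02` L/min per ppm (temperature and RH effects
default to zero). The AR(1) form is the simplest process with the lag-1
dependence the classifiers exploit; centring the exposure terms at the
sex median keeps the marginal PEFR median at its calibration target. The
effect sizes are invented plumbing — chosen so that exposure explains a
meaningful but not dominant share of day-to-day variance (roughly 10
L/min of effect spread against 18 L/min of noise); nothing downstream
asserts their literal magnitude, only their sign.

**Between- vs within-patient variance.** The published PEFR IQR pools
both sources. The generator draws baselines `b` from a sex-stratified
normal whose SD is the residual after removing the process's stationary
within-patient variance from the pooled variance (floored at a quarter of
the pooled SD). For men (median 470, IQR 400–600) the between-patient SD
is large (~146 L/min); a finite simulated cohort's sample median of PEFR
therefore carries noticeable sampling error, which is why calibration
checks simulate hundreds of patients per sex (≥10,000 patient-days).
Sample medians land within 5% of the calibration targets; a small
systematic shift of ~2% remains because the centred log-normal exposure
effects have a negative mean (mean exceeds median) that the AR recursion
amplifies by `1/(1 - phi)`.

**What the generator does not emulate.** Sensor error and calibration
drift, intra-day dynamics (the clinical protocol measured PEFR twice
daily; one daily value is emitted), activity patterns, seasonality,
medication effects, and missing days. Passing directional tests on this
synthetic cohort therefore demonstrates that the pipeline's machinery
behaves as designed under the assumed structure — not that the same
effect sizes would be observed on real patients.

Values are rounded to 4 decimals at generation (below any sensor
resolution) so cohort CSVs round-trip bit-exactly.

## Personalized zoning

The red-zone cutoff is the empirical 20th percentile (configurable) of
the patient's PEFR history, computed with linear interpolation between
order statistics; the method name is recorded in the zoning report so
alternative conventions remain comparable. The boundary rule is
`pefr <= cutoff -> red`. Within every cross-validation fold the cutoff is
refitted on the training split only: labels derived from the full series
would leak test-set information into training. Fold *assignment* uses
provisional whole-history labels purely for stratification; the trained
models never see them.

## Imbalanced sampling

The rebalancing transform is implemented literally: the minority pool is
rebuilt as exactly `n_major` draws with replacement (the minority set is
built from scratch, not topped up), then every tuple of the balanced set
is duplicated exactly once. Output size is always `4 * n_major` with
exact class balance, and every output row is a copy of an input row — no
synthetic interpolation (no SMOTE). If a training split happens to have
the red class in the majority, the roles are swapped so the minority is
always the class up-sampled. The transform is applied to training splits
only.

## Conventional classifier harness

All nine schemes use scikit-learn defaults with fixed seeds; no
hyperparameter tuning. Scale-sensitive schemes (SVM, KNN, LR, NN) are
wrapped with a standardizer fitted on the training split. Folds are
stratified and shuffled (falling back to plain K-fold when the minority
class has fewer members than folds); a fold whose training split ends up
single-class after the cutoff refit is skipped with a logged warning, and
reported fold counts reflect evaluated folds. Probabilistic schemes use
the 0.5 decision threshold. Exposure features are taken same-day with the
predicted PEFR (forecasting today's zone from yesterday's flow and
today's environment); `lag_exposure` switches to previous-day exposures.

A consequence of the defaults worth knowing: unpruned decision trees grow
to leaf purity, and a pure-leaf partition on distinct-row data is
invariant to tuple multiplicities — duplication-based rebalancing
therefore cannot systematically raise DT-G/DT-E sensitivity on the
continuous-feature synthetic cohorts, while all margin-, distance- and
likelihood-based schemes gain substantially. The acceptance suite
reflects this honestly.

## Neural networks and transfer learning

**Trainer.** The networks (one or two hidden layers of 32 ReLU units,
one sigmoid output read as P(red)) are implemented directly in numpy:
seeded uniform fan-in initialization `U(±1/sqrt(fan_in))` with zero
biases, full-batch Adam (lr 1e-3, β₁ 0.9, β₂ 0.999) on binary
cross-entropy with probability clipping at 1e-7. At ≤1,377 weights a
vectorized numpy pass outperforms framework overhead, and freezing needs
direct weight access. Backpropagation is verified against a central
finite-difference oracle to 1e-4 relative error in the test suite.

**Phases.** The source model trains on the pooled labelled examples of
every patient except the target (each labelled by their own full-history
cutoff), with IS applied; a diagnostic k-fold validation pass over the
source pool is available (`validation_folds`, default 5 in
`train_source`) but skipped by default in the per-patient orchestration,
since its metrics never feed model selection and it multiplies source
cost six-fold. After validation the source is retrained on the full
pool. The target model copies *all* source weights, then fine-tunes the
unfrozen layers on the IS-resampled target training split; frozen layers
remain bit-identical to the source. Default epochs are 1000 (source) and
100 (target), both overridable.

**Architectures.** `NN_IS`: 1 hidden layer, random init, target data
only. `TL1_IS`: 1 hidden layer, hidden frozen (33 of 321 weights
trainable, 10.3%). `TL2_IS`: 2 hidden layers, first frozen (1,089 of
1,377 trainable, 79.1%). Those counts hold at input width 8; the raw
feature encoding has 5 inputs (yesterday's PEFR + four exposures), and an
optional expanded 8-feature encoding (squared lagged PEFR plus two
exposure interactions) exists so the audit can be run at either width.
Unfrozen ratios are printed to one decimal, rounded half away from zero.

**Feature scaling (a genuinely open design point).** Transfer across
patients only works if the source task and the target task are the same
task. With raw or pooled-scaled inputs they are not: between-patient
baselines dominate the PEFR feature, so a population model learns "is
this flow low in absolute terms?", which is the wrong question for any
individual. The default is therefore per-patient standardization — every
patient's features are z-scored with their own statistics
(training-split statistics on the target side) — putting all patients in
relative coordinates, in the same spirit as the personalized cutoffs.
The `scaling="pooled"` alternative is retained; with it the transfer
advantage over the target-only baseline disappears on synthetic cohorts.

**Protocol.** Each target patient is evaluated with stratified 3-fold CV
(2/3 train, 1/3 test); a 25-patient cohort yields exactly 75 trained
target models per architecture, which the pipeline manifest records.

## Evaluation

Red zone (label 0) is the positive class. Zero-denominator metrics are
flagged undefined (NaN) rather than imputed as 0, excluded from
aggregation, and counted. Cohort summaries are medians with 25th/75th
percentiles, computed with the same linear-interpolation quantile as the
zoning module; paired with/without-IS runs are summarized as per-patient
after/before ratios.

## Reproducibility

All randomness flows from one root seed through named substreams (cohort,
folds, resampling, initialization), so any component reruns identically
in isolation. The pipeline writes a manifest with the configuration
snapshot, derived substream seeds, library versions and per-module
conventions; rerunning from the same configuration reproduces the results
bundle byte-for-byte.

## Problem sizes used in the checks

Replicated stochastic checks (IS and TL direction) use 8-patient cohorts
with 60–160-day series per replicate, ten replicates, with epochs reduced
to 200/50; the protocol-count check runs the full 25-patient cohort at
reduced epochs (60/30), the model count being a structural property
independent of training length. Generator calibration simulates 500
patients per sex (≥60,000 patient-days). `scripts/acceptance.py` uses
3–5 replicates of 6-patient cohorts for the directional summaries.

## Known limitations

- Linear, additive, instantaneous exposure effects; no lagged cumulative
  exposure beyond the AR(1) carry-over.
- The per-patient scaling default means deployment on a new patient
  requires enough history to estimate feature means/SDs (and a cutoff)
  before prediction.
- Undefined-metric exclusion slightly biases cohort medians for
  degenerate predictors (documented counts in the summaries).
- Duplication-based rebalancing is a no-op in expectation for
  duplication-invariant learners (unpruned trees); see above.
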