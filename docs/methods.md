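# Methods

This note documents the models implemented in `speechtrack`, the
assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the
numerical decisions a user should know before trusting a result.

## The encoding model

A temporal response function (TRF) is a linear kernel
`w(τ, p, c)` mapping stimulus predictor `p` to EEG channel `c` across
lags `τ`: the predicted response at time `t` sums `w(τ, p, c)·x_p(t−τ)`
over all lags and predictors. Lags cover −100…800 ms; at the 128 Hz
analysis rate that is the integer sample grid −13…102 (116 lags per
predictor, edges rounded to the nearest sample). The model assumes
linearity and time invariance within an epoch, and treats the two
streams' predictors as separate columns of one design.

Estimation is penalized least squares on column-centered data,

    (XᵀX + λ·m·I) W = XᵀY,   m = mean diag(XᵀX),

an identity-penalty ridge whose `λ` is comparable across designs of
different scale because of `m`. `λ = 0` on a singular design falls
back to the pseudo-inverse with a warning. Presets follow the analysis
protocol: `λ = 0.1` for acoustic models and `λ = 1e−7` for linguistic
models fitted on residualized EEG, shared across participants and the
correct/incorrect model variants; `tune_lambda` can refit the scalar on
a grid by cross-validated score when a user prefers data-driven
selection.

Model quality is the per-channel Pearson correlation between predicted
and observed EEG. Because linguistic predictors are sparse impulse
trains, their models are evaluated only on samples 0–800 ms after an
event onset (and always within the target-sentence span). Trial-wise
correlations are kept (not pooled) because the neuro-behavioral
linking model needs one standardized fit per trial; standardization is
a z-score across trials within participant and model variant.

Cross-validation follows the cross-participant scheme: 50 random folds,
each holding out 8 participants whose data never enter that fold's
training; one model per condition variant (correct/incorrect) per fold;
each held-out trial's score is averaged over the folds in which its
participant was tested. `make_fold_plan` resamples the plan (with a
warning) until every participant is tested at least once — at small
participant counts uncovered participants are otherwise common.

### A small-sample caveat of cross-participant validation

Under a global null (EEG independent of the features), the
trial-averaged scores of *different participants* are positively
correlated whenever participants rotate between training and test
roles: participant A's EEG shapes the model that scores participant B
and vice versa, and because Pearson correlation is scale-invariant,
ridge shrinkage does not remove the coupling. We measured an
equicorrelation of ρ ≈ 0.07 across participants in reduced simulations
(12 participants, 6–20 trials of 2.5–5 s), insensitive to trial count,
epoch length, lag count, λ, and evaluation masks; with a disjoint
training pool the correlation vanishes (ρ ≈ 0.001). Correlated
participant deltas violate the independence assumption of sign-flip
inference and inflate its type-I error badly at this scale (~30%
observed). The coupling scales with the ratio of design columns to
per-participant training samples, so it is negligible at full study
scale (hundreds of trials, tens of participants), but any reduced-scale
calibration must avoid it. The package therefore also provides
`within_participant_scores` — trial-wise cross-validation with
participant-specific models — whose scores are independent across
participants by construction; the shuffle-null calibration test uses
it, and we recommend it whenever participant counts are small.

## Residualization

Linguistic predictors covary with acoustics, so all linguistic models
are fitted on residualized EEG: one nuisance TRF (envelopes, acoustic
onsets, word/phoneme/initial onsets, F0 track, and constant
speaker-characteristic regressors placed at word onsets, per stream)
is fitted over all trials without cross-validation, and its predictions
are subtracted. At `λ → 0` the training-data residuals are orthogonal
to the nuisance design; residual variance never exceeds the original.
F0 enters as a consumed per-stream track (voiced gaps as zeros); the
synthetic generator produces a sinusoid-plus-drift stand-in. Speaker
ratings are consumed as constants per (characteristic, stream); they
are min–max normalized together with everything else, which is one of
the points where the original analysis is underspecified.

## Shuffling nulls and TFCE

Significance of a feature group's tracking is assessed against
refitted models with shuffled features, keeping dimensionality fixed.
Groups and shuffle modes: acoustic (envelope + acoustic onsets) and
onsets (word + phoneme onsets) shuffle the pairing between the group's
feature columns and EEG trials; word-linguistic (surprisal +
frequency) and phoneme-linguistic (phoneme surprisal + cohort entropy)
permute event *values* globally across sentences, separately per
feature, with onsets fixed. The default is 50 iterations per variant;
shuffled columns are re-rasterized with the original global
normalization bounds so only values move.

Per participant and channel, the statistic is observed minus
mean-shuffled fit. Channel-wise one-sample t-values are enhanced with
TFCE, `TFCE(c) = Σ_h extent(c,h)^E · h^H · dh` over the grid
`h = dh, 2dh, …, max|t|` with the field-standard `E = 0.5, H = 2,
dh = 0.1`; two-tailed inference runs on |t|. Corrected p-values come
from the max-TFCE distribution under participant sign flips (1024 by
default; full enumeration available, where the test is
permutation-exact). Channel adjacency is Delaunay triangulation of
2-D projected sensor positions (an explicit edge list can be supplied);
ROI candidates (fronto-central, temporal, centro-parietal) are
name-defined sets for the 63-channel 10–20 layout, and the ROI is the
candidate with the highest model fit in the held-out control
condition, ties going to the first declared with a warning.

## Glimpse-rate audibility

A word's glimpse rate is the fraction of spectrogram cells
(band × frame) within its interval where target level exceeds
distractor level by more than −5 dB. All cells count — no energy floor
gate (configurable, off by default; whether the original computation
gated near-silent cells is unknown). Combined audibility is the
z-scored glimpse rate plus the trial's T/D condition. The audibility
split divides each condition's scored words at the median combined
audibility (ties to the low half), computes prediction correlations
separately on each half's pooled samples, and compares halves with
paired t-tests across participants, reporting uncorrected and BH-FDR
p-values (the analysis is exploratory).

## The comprehension model

Word-by-word accuracy (scored by longest-common-subsequence alignment
of normalized tokens — NFC, casefold, punctuation stripped; exact
matching, no morphological fuzziness, which is stricter than human
scoring) is modelled as

    accuracy ~ Bernoulli( logit⁻¹( Xβ + u_subject + u_sentence ) )

with standardized fixed effects: audibility, surprisal, their
interaction, T/D, word frequency, word order, sentence length,
control-condition accuracy, speech reception threshold, and the eight
standardized trial-wise TRF fits ({acoustic, onsets, word-linguistic,
phoneme-linguistic} × {target, distractor}).

Estimation is Laplace/MAP with weak Gaussian priors
(`BinomialBayesMixedGLM`: prior sd 3 on fixed effects, 2 on log
random-effect sds) — a Bayesian-posterior-mode engine that handles
crossed random intercepts directly; the contract is the model, not the
engine, and a cross-engine test verifies agreement with lme4's Laplace
glmer on the same data to ±0.03. When a random-intercept variance sits
on the zero boundary (tiny group counts) the fit is retried with a
tighter variance prior and flagged with a warning. Diagnostics include
variance inflation factors (`1/(1−R²_j)`, interaction as its own
column) and latent-scale pseudo-R²:
`fixed = var(Xβ̂) / (var(Xβ̂) + Σσ²_re + π²/3)`, with the total adding
`Σσ²_re` to the numerator. FDR correction (Benjamini–Hochberg) spans
the fixed-effect p-values; the intercept is not corrected.

## The synthetic-data generator

The generator is the package's ground truth and defines the study
conditions every verification runs under.

- **Lexicon**: random phoneme strings (lengths 2–6 over a 16-symbol
  inventory, so prefixes collide and cohorts are non-trivial) with
  Zipf frequencies `f(rank) ∝ rank^(−s)`, `s = 1` by default, scaled to
  per-million units.
- **Stimuli**: per trial, a target sentence of 5–7 words lasting 2–4 s
  and a distractor of 7–10 words lasting 3–5 s that starts 0.5 s
  earlier and outlasts the target by ≥ 0.3 s. Word durations are
  log-normal (median 0.45 s target / 0.42 s distractor, σ = 0.25 log
  units), rescaled into the sentence-duration window; phoneme
  intervals are nested log-normal subdivisions. T/D conditions cycle
  through (−2, −1, 0, 1, 2, 10) dB; 10 dB trials are flagged as the
  control condition and excluded from main fits. "Audio" is generated
  directly as dB spectrogram fields (32 log-spaced bands at 128 Hz):
  per-word base level = T/D plus Gaussian jitter (sd 2 dB — the
  distribution of word-level masking fluctuation is not documented
  anywhere, so this is a free parameter), a raised-cosine temporal
  envelope, a per-stream spectral bump, and smoothed 1 dB field noise.
  Envelopes are channel means of the spectrograms by construction.
- **EEG**: channels are sums over predictors of feature-kernel
  convolutions (direct convolution, an independent code path from the
  estimator's lagged design) plus 1/f^1 noise generated in the
  frequency domain and band-limited to 0.5–15 Hz to mirror
  preprocessing, scaled to a target sample SD. Ground-truth kernels
  are sums of Gabor atoms concentrated at 50–400 ms with random
  channel topographies. With zero noise the output is exactly the
  convolution.
- **Behavior**: word accuracies are Bernoulli draws from the logistic
  mixed model above. The packaged `"paper"` preset uses the published
  fixed-effect estimates as generating truth. The published table
  reports no intercept and no random-intercept variances; the
  random-effect variances are back-derived from the published
  variance-explained pair (15.9% fixed-only, 50.8% total on the latent
  scale): total RE variance `= 0.349/0.492 · π²/3 ≈ 2.33`, split
  equally between subject and sentence intercepts (sd ≈ 1.08 each),
  and the intercept is set to 1.0 (≈70% marginal accuracy, plausible
  for an SRT-centered design).
- **Staircase**: 1-down/1-up (down after a fully correct repetition),
  start 5 dB, initial step 6 dB, step ×0.85 after each turning point;
  the estimate is the mean T/D at the final 5 turning points; runs stop
  after 14 turning points or 60 trials (with a warning and the best
  available estimate).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: realistic speech acoustics (no harmonic
or formant structure, no coarticulation; glimpse rates are therefore
compressed toward the ceiling relative to real competing speech, which
has much deeper spectro-temporal masking valleys), head geometry and
volume conduction (channel topographies are random, not dipolar),
artifacts (no eye movements or muscle; the ICA step of real
preprocessing is accepted as already done), non-linear or adaptive
neural responses, and any dependence of the EEG on attention or
comprehension beyond what the user wires in through the kernels.

## Problem sizes used in verification

The suite verifies each stage at the largest scale that keeps the
whole run desk-sized: solver exactness on 50–500-sample designs
(tolerance 1e−10); kernel recovery with 63 channels × 40 trials × 4 s
at 0 dB SNR (threshold r ≥ 0.9); shuffle-null calibration with 200
replicates of 12 participants × 8 trials × 2.5 s, 10 channels, 10
shuffle iterations, 256 sign flips (acceptance band 1–7.5% at
α = 0.05), using within-participant fits for the reason given above;
TFCE enumeration on 5–10-node graphs (1e−9); GLMM recovery with 20
replicates of 40 subjects × 200 sentences × 4 scored words (±0.05 on
the mean); staircase convergence over 100 runs; residualization with
15 trials × 5 s × 8 channels. `scripts/acceptance.py` reruns the GLMM
recovery harness from scratch and writes the mean recovered
coefficients.

## Known limitations

- The exact inferential recipe of the original analysis cannot be
  fully recovered: a "cluster-forming threshold" is quoted alongside
  TFCE, which needs none; we interpret it as the significance level of
  the corrected map and use the field-standard TFCE parameters.
- Whether trial-wise correlations were averaged across folds or
  channels first is not documented; this implementation averages
  across folds per trial, then across channels of the selected
  cluster.
- Exact token matching under-scores morphological variants relative to
  human scoring.
- Cross-participant sign-flip inference is anticonservative for small
  participant counts (see above); results from the rotating scheme at
  N ≲ 20 should be treated with caution.
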