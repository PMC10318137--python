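# Methods

## Analysis model

The unit of analysis is the song. Per-participant 1 Hz immersion traces are
averaged across the participants who reported being unfamiliar with the song
(familiarity confounds self-reported liking, and the filtering rule removes
that endogeneity channel from the neural averages as well). From the
averaged series v̄ₜ, t = 0…T−1, three statistics are computed:

- average immersion, mean(v̄ₜ), in immersion units;
- peak immersion, Σₜ v̄ₜ·1[v̄ₜ > M] / Im with M = median(v̄) + s and
  Im = Σₜ v̄ₜ, where s is the sample SD (ddof = 1) over *all*
  participant-second samples of the song;
- retreat, the sum of the k = max(1, ⌊0.2T⌋) smallest v̄ₜ divided by Im.

Two readings of the peak integrand are defensible: summing the
above-threshold *values* (default) or counting above-threshold *seconds*
(`integrand="indicator"`). The value reading is the default because only a
sum of values forms a dimensionless fraction of total immersion; the
indicator variant remains available. The threshold uses a strict
inequality, so a constant series has peak 0. Retreat is normalized by Im by
default (`normalized=False` gives the raw lowest-quintile sum): on the raw
scale the statistic is ~30 unit-seconds and its logistic odds ratios become
astronomically large, whereas the normalized fraction lives on (0, 0.2] for
T ≥ 5. Ties in the retreat sort are broken by time order (stable sort);
traces of unequal length within a song are truncated to the shortest common
length so the cross-participant average is defined at every retained second.
Songs with fewer than `min_participants` (default 2) unfamiliar listeners
are dropped with a logged warning.

## Synthetic cohort generator

The generator emulates the study conditions: 33 participants (47% female;
ages from a truncated normal with parent mean 24.25, SD 10.47 on [18, 57]),
24 songs (13 hits with >700,000 streams, 11 flops), 180 s songs at 1 Hz,
post-song surveys with familiarity ~ Bernoulli(0.25), and hit/flop
separation calibrated to song-level Cohen's d ≈ −0.95 for average immersion
(flop-minus-hit convention, means ≈ 4.17 vs 4.10) and ≈ +0.82 for retreat.

A trace is

    value_t = max(0, base + class_shift·1[hit] + u_p + w_s
                     + age_slope·(age_p − 24.25) + gender_offset·1[female]
                     + ε_t + surge′_t − dip′_t)

with ε a stationary AR(1) (φ = 0.6, SD 0.6), participant and song offsets
u_p ~ N(0, 0.5²), w_s ~ N(0, 0.067²), age slope −0.016 units/year
(reproducing an observation-level age correlation of about −0.3) and a
+0.14 female offset. Dip and surge episodes arrive as Poisson processes
whose *times are shared across participants within a song* — only shared
structure survives cross-participant averaging — while per-participant
depths are exponential (dips: mean 0.8, 5 s; surges: mean 1.2, 5 s, rate
1/min for both classes). The primes denote per-trace mean-centering of the
episode contribution: episodes shape the tails of the averaged series
without moving song means, so the mean separation is governed by
class_shift (0.07) and song_sd alone, and the retreat separation by the
dip-rate contrast alone.

Two calibration choices deserve emphasis:

- Surges exist so that *peak immersion is non-degenerate*: with only iid
  participant noise, the averaged series (SD ~ within_sd/√P) never exceeds
  the median-plus-all-sample-SD threshold and peak would be identically 0.
  Surges are class-neutral, consistent with the near-zero peak effect the
  design targets.
- Hits receive *more* dip episodes than flops (1.0 vs 0.5 per minute).
  Retreat is the lowest-quintile mass as a fraction of total immersion, so
  deeper valleys *lower* it; flops — flatter songs — sit nearer the 0.2
  ceiling and end up with the higher retreat, which is the direction of the
  target effect.

The dip-rate/song-SD defaults were fixed once by a coarse grid search
(`scripts/calibrate_generator.py`) at the 200-songs × 100-participants
estimation scale and are not revisited. Values are clamped at zero
(immersion is a magnitude), which slightly biases means upward at high
noise or deep dips. The generator does not model PPG waveforms, audio
content, playlist dynamics, or any dependence of surveys on the traces;
passing tests therefore demonstrate the pipeline's statistical behavior
under this generative family, not the validity of immersion measurements on
real listeners.

## Synthetic augmentation

Columns are synthesized in the order (label, avg_immersion, retreat,
peak_immersion): the class label first so both classes appear in their
source proportions. The first column is bootstrapped from its marginal;
each later column is modelled by a CART tree (min_leaf = 2) on the
previously synthesized columns and sampled by uniform donor draw within the
leaf, so every synthetic value occurs in the source (donor closure) and
observed dependencies are preserved. A linear-Gaussian fallback covers
sources too small to grow trees. Fidelity is assessed as effect-size
tolerances — |Δmean|/SD ≤ 0.25, |ΔSD|/SD ≤ 0.25, |Δr| ≤ 0.15 — rather than
hypothesis tests, which at n = 10,000 reject trivial differences.

A consequence worth knowing: donor sampling repeats the 24 observed feature
values thousands of times, so a 3-NN classifier can nearly memorize the
synthetic table. This is why the k-NN learner absorbs almost all the
ensemble weight and why held-out synthetic accuracy approaches 100%; the
same mechanism (and the same k-NN dominance) operates in analyses of this
design on real data.

## Super learner

Candidate learners and grids: logistic (cost 1/10/100; L2 penalty 1/cost),
k-NN (k 3/5/8/10), SVM (cost 1/10/100 × radial/polynomial/tanh kernel) and
a one-hidden-layer ANN (activation linear/softmax × size 1/5/10 × decay
0/1/10). Learners are sklearn estimators; k-NN/SVM/ANN see z-scored
features (constants learned on the training half) because average immersion
(~4.1) and retreat (~0.17) differ by an order of magnitude. The SVM's tanh
kernel yields an indefinite Gram matrix, which libsvm tolerates; its
probabilities are Platt-calibrated. The ANN grid's activation names map to
hidden activations (linear → identity, softmax → logistic) since the output
activation of a probabilistic classifier is fixed; decay maps to the L2
penalty `alpha`, with 0 replaced by 1e−8 to keep the optimizer well-posed.
Training runs at most 500 epochs from a seeded initialization.

Tuning minimizes stratified 5-fold cross-validated squared error of
predicted probabilities (the super-learner default risk; an accuracy
criterion would be a step function with massive ties), ties broken by grid
order. When tuning is disabled the selected settings are logit C = 1, k-NN
k = 3, SVM C = 10 tanh, ANN softmax/size 5/decay 1. For speed, tuning may
run on a stratified subsample (default 1,200 rows) while final fits always
use the full training half.

Weights: out-of-fold class-1 probabilities Z (every row predicted by a
model that never saw it; stratified folds, redrawn under degeneracy) enter
min_{β≥0} ‖y − Zβ‖². NNLS-then-normalize is the textbook recipe, but
normalization rescales the solution off its own optimum and can leave the
ensemble risk slightly above the best single learner; a short SLSQP polish
of the simplex-constrained problem (vertices checked as candidates)
restores the dominance guarantee. An all-zero NNLS solution falls back to
uniform weights. Prediction is Σβⱼpⱼ, classified as a hit when ≥ 0.5 — the
tie goes to "hit" so the decision rule is a closed upper set.

## Evaluation

- Exact binomial test: the full upper-tail sum P(X ≥ s) under
  Binomial(n, p0); for very large n and extreme s the p-value underflows to
  0.0 in double precision. The default base rate is the observed hit
  fraction of the evaluated set (54% for the 13/24 design), overridable.
- Bootstrap comparison: each of B iterations draws train and test sets with
  replacement from the synthetic pool, refits *both* models and records
  overall/hit/flop accuracies; 95% percentile CIs per model and a pooled
  two-sample t across iterations with df = 2B − 2, sign = (first model −
  second model).
- K-fold overfitting check: per fold, the refit pipeline's accuracy on its
  own training part, the held-out fold and the observed song table; the
  consistency flag requires the three means within a configurable band
  (default 0.05).
- Logistic baselines: Model 1 (immersion), Model 2 (immersion + retreat) by
  maximum likelihood, with a small-L2 ridge fallback (GLM elastic net,
  L1_wt = 0, α = 1e−3) under separation or non-convergence, logged. The
  overall test is a likelihood-ratio chi-square against the intercept-only
  model — the standard overall test for a logistic fit. VIF is computed
  from the predictor cross-regression R²; with two predictors correlated at
  r this is exactly 1/(1 − r²).
- Effect statistics: pooled-variance Student t (df = n₁+n₂−2) and Cohen's d
  with groups ordered (flop, hit); zero pooled variance with unequal means
  is flagged as an infinite statistic rather than an error.

## Problem sizes and numerical choices

The test suite runs every stage at full fidelity where that is cheap
(synthesis fidelity uses 10,000-row tables; effect-size recovery uses 50
replicates of 200 songs × 100 participants) and at reduced size where the
full chain must be replicated many times: the ensemble-vs-logistic
directional check runs 100 complete simulate→featurize→synthesize→train→
evaluate chains at 1,000 synthetic rows with the selected hyperparameters —
the directional claim does not depend on the table size. The acceptance
script uses the full 10,000-row synthesis with grid tuning for the main
analysis, the selected settings for the first-minute variant, a 100-
iteration bootstrap at 800-row draws, and a 10-fold check on a 1,000-row
subsample of the training half. Stage seeds derive from the top-level seed
by hashing (seed, stage name), so adding a stage never perturbs earlier
stages' randomness and a fixed seed reproduces every number exactly.

## Known limitations

- The generator's trace model is a stylization; nothing in it validates the
  inference of immersion from cardiac data, and survey responses are
  independent of the traces.
- Donor-based synthesis cannot extrapolate beyond the convex hull of the 24
  observed songs, and its repetition of donor values flatters
  nearest-neighbor learners (see above).
- The paper-style first-minute variant truncates before averaging but after
  familiarity filtering; with 60 s of data the retreat quintile holds only
  12 s, so the statistic is noticeably noisier.
- The bootstrap refits both models per iteration; with the super learner in
  the loop this is expensive, which is why the default iteration counts are
  modest. Increase them for publication-grade intervals.
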