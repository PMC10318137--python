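# neurohit

Neuroforecasting hit songs from 1 Hz neurophysiologic immersion traces.

## The problem

Predicting which new songs will become hits ("Hit Song Science") is
notoriously hard: self-reported liking barely predicts streaming outcomes,
partly because liking is confounded with familiarity. An alternative is to
measure a small listening panel's *neurophysiologic immersion* — a
second-by-second index of attention and emotional resonance inferred from
cardiac activity — and ask whether the panel's aggregate neural response
classifies hits (>700,000 streams) against flops. `neurohit` implements that
analysis end to end as a tested, reusable pipeline, together with a seeded
synthetic-cohort generator so every stage runs without any proprietary data.

## The statistics at its core

For song *i*, let v̄ᵢₜ be immersion averaged over the participants who did
**not** already know the song (familiar listeners are excluded), t = 0…T−1 at
1 Hz, and Imᵢ = Σₜ v̄ᵢₜ the total immersion. Three song-level features are
derived:

- **average immersion** — mean of v̄ᵢₜ;
- **peak immersion** — Σₜ v̄ᵢₜ·1[v̄ᵢₜ > Mᵢ] / Imᵢ, where the threshold
  Mᵢ = median(v̄ᵢ) + SD of all participant-second samples of song *i*: the
  share of total immersion contributed by the song's highest moments;
- **retreat** — (Σ of the k = max(1, ⌊0.2T⌋) smallest v̄ᵢₜ) / Imᵢ: the mass
  of the lowest quintile, a measure of disengagement. A flat song sits near
  the 0.2 ceiling; a dynamic song with deep valleys falls below it.

Because 24 songs cannot support nonlinear classifiers, the feature table is
inflated to 10,000 rows by sequential conditional synthesis (bootstrap of
the first column, then recursive-partitioning trees with uniform donor
sampling per leaf, column by column). A **super learner** is trained on one
half: four candidate learners (logistic regression, k-NN, kernel SVM,
one-hidden-layer ANN) are tuned by stratified 5-fold cross-validation, their
out-of-fold class probabilities Ŷᵢⱼ collected, and simplex weights βⱼ
estimated by non-negative least squares so that the ensemble prediction is

  Ŷᵢ = Σⱼ βⱼ Ŷᵢⱼ,  βⱼ ≥ 0, Σⱼ βⱼ = 1,

minimizing cross-validated squared-error risk. Evaluation covers accuracy /
sensitivity / specificity, exact binomial tests against the 54% base rate
(13 hits of 24 songs), a bootstrap comparison against the logistic baseline,
and a k-fold overfitting check comparing train / held-out / observed-data
accuracy.

## Worked example

```python
from neurohit import (
    CohortConfig, simulate_cohort, featurize_cohort,
    SynthesisConfig, synthesize_table, split_half,
    SuperLearner, confusion_metrics, exact_binomial_test, effect_stats,
)
from neurohit.ensemble import encode_labels

cohort = simulate_cohort(CohortConfig(seed=1))      # 33 listeners, 24 songs
features = featurize_cohort(cohort)                 # song-level features

d_imm = effect_stats(features, "avg_immersion")
d_ret = effect_stats(features, "retreat")
print(f"immersion: hits {d_imm.mean_hit:.2f} vs flops {d_imm.mean_flop:.2f} (d = {d_imm.d:.2f})")
print(f"retreat:   hits {d_ret.mean_hit:.3f} vs flops {d_ret.mean_flop:.3f} (d = {d_ret.d:.2f})")

synthetic = synthesize_table(features, SynthesisConfig(n_rows=10_000, seed=2)).table
train, test = split_half(synthetic, seed=3)
results = SuperLearner.from_dataframe(train, seed=4).fit()
print(results.summary())

y_test = encode_labels(test["label"])
conf = confusion_metrics(y_test, results.predict_frame(test))
p = exact_binomial_test(conf.tp + conf.tn, len(y_test), 0.54).p_value
print(f"held-out synthetic accuracy: {conf.accuracy:.1%} "
      f"(hits {conf.sensitivity:.1%}, flops {conf.specificity:.1%}; p = {p:.1e} vs 54% base rate)")
```

prints

```
immersion: hits 4.16 vs flops 4.01 (d = -1.67)
retreat:   hits 0.180 vs flops 0.182 (d = 0.35)
Super-learner ensemble (hit vs flop)
  rows: 5000   folds: 5   threshold: 0.5
  ensemble CV risk (squared error): 0.0000
  learner      weight   cv risk  params
  logistic     0.0000    0.1280  {'cost': 1}
  knn          1.0000    0.0000  {'k': 3}
  svm          0.0000    0.1926  {'cost': 10, 'kernel': 'tanh'}
  ann          0.0000    0.1254  {'activation': 'softmax', 'size': 5, 'decay': 1}
held-out synthetic accuracy: 100.0% (hits 100.0%, flops 100.0%; p = 0.0e+00 vs 54% base rate)
```

The effect sizes are noisy at 24 songs (the generator is calibrated to
d ≈ −0.95 for immersion and +0.82 for retreat in expectation, with the
flop-minus-hit sign convention). The k-nearest-neighbor learner absorbs all
the ensemble weight: donor-based synthesis repeats observed feature pairs,
which a 3-NN memorizes almost perfectly — the same dominance the super
learner exhibits on this design with real data. The logistic baseline on the
same features reaches only ~70% accuracy, so the ensemble's gain comes from
the nonlinearity, not from extra inputs.

There is also a CLI mirroring the stages:

```
neurohit simulate --out cohort/ --seed 1
neurohit featurize --traces cohort/traces.csv --surveys cohort/surveys.csv \
    --songs cohort/songs.csv --out features.csv
neurohit synthesize --features features.csv --n 10000 --seed 2 --out synthetic.csv
neurohit train --data synthetic.csv --seed 3 --out model.json
neurohit run --out results/ --seed 1          # the whole pipeline at once
```

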