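# grazemetrics

Sensor analytics for grazing beef cattle: from raw tri-axial accelerometer
streams to behavior classification, intake ethograms and performance
forecasting.

## The problem

Underjaw-mounted tri-axial accelerometers record an animal's head movement
every 6 s (≈0.167 Hz) around the clock. From those records one can recognise
the six mutually exclusive ingestive behaviors of the standard ethogram —
grazing, ruminating, lying-standing, drinking, eating (supplement) and other
— and, from the recognised behaviors, derive the **frequency of food intake**
(minutes per hour spent grazing + eating). Feeding that intake frequency,
together with forage covariates (CP, NDF, ADF, forage mass, %Leaf, %Stem),
supplement level and genetic group, into a multiple linear regression yields
a forecast of the **intermediate average daily gain** (iADG, kg day⁻¹,
measured every 28 days from non-fasted weights). This machine-learning →
mechanistic-model chain is often called *hybridization*.

`grazemetrics` implements that full chain as a tested, reusable pipeline.
Because field datasets of this kind are rarely public, the package ships a
first-class synthetic herd generator with known ground truth for every
stage: a semi-Markov behavior schedule (lognormal bouts, circadian entry
intensities, Table-style class imbalance of 28.9/9.8/51.0/1.4/6.0/2.9 % for
grazing/ruminating/lying-standing/drinking/eating/other), a per-behavior
signal model in ɡ units, 10-min scan-sampled observations (06:00–18:00,
73 scans per animal-day), telemetry dropouts, and a known linear model
generating observed iADG.

## What is computed

* **Features** (per record, from axes X, Y, Z in ɡ):
  SMA = |X|+|Y|+|Z|, SVM = √(X²+Y²+Z²), movement variation
  |ΔX|+|ΔY|+|ΔZ| to the next record, energy = SVM⁴,
  entropy = (1+(X+Y+Z))²·ln(1+(X+Y+Z)²), and the orientation angles pitch,
  roll and inclination (two-argument arctangent conventions).
* **Quality control**: a new record sequence starts whenever successive
  records are more than 60 s apart (strictly greater).
* **Classifiers**: random forest (500 trees), a dense 24/12/6
  relu/relu/softmax network (adam, batch 128, ≤500 epochs, 0.2 validation
  split), and linear discriminant analysis, on a 70/30 stratified split.
* **Evaluation**: per-class sensitivity TP/(TP+FN), specificity
  TN/(TN+FP), precision TP/(TP+FP) with typed NA when a denominator is 0;
  accuracy = trace/total; Cohen's unweighted κ with Landis–Koch banding
  (κ = 0.704 → "substantial").
* **Ethogram**: behavior time budgets (% of the total observation record)
  and intake frequency in min h⁻¹ / h day⁻¹ (20.35 min h⁻¹ ≡ 8.14 h day⁻¹).
* **Forecast**: OLS multiple linear regression of iADG, scored by Pearson r
  and MSE, overall and per genetic group.
* **Multivariate validation**: PCA on the correlation matrix of the final
  animal-period dataset, variance split over PC1/PC2, and a silhouette
  statistic for the three-group cluster structure.

## Worked example

```python
import grazemetrics as gm
from grazemetrics.classify import SplitSpec, split_dataset
from grazemetrics.pipeline import run_behavior_experiment

bundle = gm.generate_study(seed=1)   # 22 animals, known ground truth

res = run_behavior_experiment(
    bundle, {"forest": gm.ClassifierConfig(kind="forest", seed=3)},
    split_seed=2, max_rows=20_000,
)
s = res["forest"]
print(f"random forest: accuracy {s.accuracy:.3f}, kappa {s.kappa:.3f} ({s.kappa_band})")

budget = gm.time_budget(bundle.observations)[0]
print(f"grazing share of the observation record: {budget.percentages['grazing']:.1f}%")

train, val = split_dataset(bundle.performance, SplitSpec(seed=2, strategy="random"))
model = gm.fit_mlr(train)
ev = gm.evaluate_forecast(val["iadg_observed"], gm.predict_iadg(model, val))
print(f"iADG forecast: r = {ev.pearson_r:.3f}, MSE = {ev.mse:.3f}")

pca = gm.run_pca(bundle.performance)
sil = gm.group_separation(pca.scores, bundle.performance["genetic_group"].to_numpy())
print(f"PC1+PC2 variability: {gm.two_component_variability(pca):.1f}%, group silhouette {sil:.2f}")
```

prints

```
random forest: accuracy 0.904, kappa 0.849 (almost_perfect)
grazing share of the observation record: 39.6%
iADG forecast: r = 0.971, MSE = 0.005
PC1+PC2 variability: 85.7%, group silhouette 0.63
```

The classifier recovers the simulated behaviors far above chance (κ in the
almost-perfect band at this noise level); grazing dominates the daytime
observation record; the regression forecast tracks observed gain closely
because the generator's noise is small; and the PCA scores separate the
three animal groups (silhouette 0.63 > 0.5), mirroring the cluster
validation step of the analysis.

The same stages are available from the shell:

```bash
grazemetrics simulate --scenario scenario.yaml --seed 1 --out run/
grazemetrics featurize --records run/records.csv --obs run/observations.csv --out features.csv
grazemetrics train --features features.csv --model forest --seed 1 --out model.pkl
grazemetrics run --config run.yaml --seed 1     # full pipeline + manifest
```

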