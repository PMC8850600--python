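# Methods

This note records the models, conventions and defaults behind
`grazemetrics`, and what results on the synthetic herd do and do not say
about field data.

## Behavior schedule model

Each animal's day is a piecewise-constant path over the six-class ethogram,
generated by a semi-Markov renewal process. At each renewal the next
behavior *b* is drawn with probability proportional to

    w_b(t) = (p_b / E[D_b]) · c_b · m_b(t)

where `p_b` is the target long-run time share, `D_b` the lognormal bout
duration (median/log-sd parameterisation; the lognormal is the simplest
positive, right-skewed, two-parameter law and no bout statistics are
published for this setting), `m_b(t)` the circadian multiplier at the clock
time of entry, and `c_b` a fixed entry correction. Self-transitions are
allowed and merge into longer bouts, so by the renewal-reward theorem the
long-run time share of *b* converges to `p_b` when the multipliers average
to one. Circadian gating biases this convergence slightly (entries compete
within windows); the corrections `c_b` were calibrated once so the default
schedule lands within ±2 percentage points of its targets, and they ship as
documented constants.

Default targets are the overall observed composition of the study design
the package emulates: grazing 28.9 %, ruminating 9.8 %, lying-standing
51.0 %, drinking 1.4 %, eating 6.0 %, other 2.9 %. Default circadian
structure: supplement eating is confined to three one-hour trough windows
around 10:00, 12:00 and 16:00 (multiplier 8, baseline 0); grazing is
favoured 06:00–09:00 and 15:00–18:00 (×1.6); lying-standing is favoured at
night (×1.4). Each profile's time-average multiplier is 1.

One consequence worth stating: the *daytime* (06:00–18:00) observation
record over-represents grazing and under-represents lying-standing relative
to the 24-h targets, because the circadian profiles shift grazing into the
observed window. Time budgets computed from scan observations therefore
differ from the 24-h composition by design, exactly as a daytime observer
in the field would see.

## Signal model

A record is taken every `sampling_period_s` (default 6 s, ≈0.167 Hz). Each
axis value is

    behavior mean + amplitude · sin(2π t / period + bout phase) + N(0, σ)

with per-bout random phases. Per-behavior means, amplitudes, periods and
noise levels are documented constants chosen to satisfy one structural
constraint taken from the observed signal pattern: resting
(lying-standing) has strictly smaller amplitude + noise than every other
behavior on all three axes, and the smallest mean vector norm. The
constraint is validated at configuration time. No published per-behavior
signal distributions exist for this device, so these are declared
assumptions, not estimates — classifier metrics on the synthetic herd
measure pipeline correctness and relative model ordering, not absolute
field performance.

Raw integer counts convert to ɡ units (ɡ = 9.81 m s⁻²) only through an
explicit per-axis linear scale `(raw − offset) × gain`; no hardware default
is silently assumed.

## Observation and alignment

Scan sampling records each animal's instantaneous behavior every 10 min
between 06:00 and 18:00, both endpoints included — 73 scans per animal-day.
Night behavior is simulated but unobserved. Label-to-record alignment
defaults to `forward_fill`: a scan's label covers records from its instant
up to the next scan (at most one interval), the convention under which a
scan represents its interval. A `nearest` policy (within half an interval,
ties to the earlier scan) is available. Records outside coverage stay
unlabeled and are excluded from modeling tables.

Quality control starts a new record sequence whenever the gap between
successive records is strictly greater than 60 s; a gap of exactly 60 s
does not split. Cross-record features never straddle a sequence boundary.

## Features

The eight derived variables follow the standard accelerometry definitions
(see README). Conventions: angles use the two-argument arctangent, so pitch
at Y=Z=0 is ±90° by the sign of −X, inclination at Z=0 is +90° (0 at the
origin), and roll lies in (−180°, 180°] (the signed-zero edge maps −180° to
+180°). "Entropy" keeps its conventional name although it is not an
information entropy; it depends on the axes only through their sum and is
zero when that sum is 0 or −1. Movement variation is attached to the
earlier record of each consecutive pair; each sequence's last record
therefore lacks it and is dropped from modeling tables rather than imputed
(the simplest defensible filter; row accounting is asserted in tests).

## Classifiers

* **Random forest** — 500 trees, all other structural controls at library
  defaults; seeded.
* **Dense network** — the per-record feature vector passes through a
  standardizing scaler into layers of 24 and 12 relu units and a 6-unit
  softmax output, trained with adam, batch size 128, for up to 500 epochs
  while a 0.2 validation split is monitored for early stopping. No
  convolutional windowing is imposed: kernel sizes and input sequence
  lengths are not recoverable for this setting, so nothing is invented.
* **Linear discriminant analysis** — no tunables.

Model inputs are the eight derived variables, hour/minute/second, and
reference-coded genetic-group indicators. Sensor identity is excluded by
default to avoid identity leakage; day and month are carried as bookkeeping
and can be enabled as inputs. The 70/30 split is stratified by label by
default; a grouped-by-animal strategy exists because per-animal leakage is
the realistic generalisation concern.

## Metrics

Per-class sensitivity, specificity and precision are one-vs-rest reductions
of the 6×6 confusion matrix; a metric whose defining denominator is zero is
*not available* and propagates as a typed missing value, never as zero.
Accuracy is trace/total. Kappa is Cohen's unweighted multi-class form;
κ = 1 only for a perfect diagonal, and κ is NA when expected agreement is 1.
The Landis–Koch cut points are implemented as contiguous half-open bands
(−∞,0) poor, [0,0.2] slight, (0.2,0.4] fair, (0.4,0.6] moderate, (0.6,0.8]
substantial, (0.8,1] almost perfect, so every κ ≤ 1 receives a band;
published boundary values (e.g. 0.704 → substantial) are unaffected by the
boundary convention.

## Ethogram and intake

Each record contributes exactly its sampling period of behavior time — the
only self-consistent accounting at 0.167 Hz. Food intake is grazing ∪
eating. Intake frequency is reported in min h⁻¹ over a caller-chosen window
(the averaging window is a parameter precisely because daytime and 24-h
averages differ); h day⁻¹ = min h⁻¹ × 24/60, display-rounded to two
decimals.

## Performance generation and forecast

Observed iADG is generated as a linear predictor over intake frequency,
supplement level, day index, forage covariates and genetic-group offsets,
plus N(0, 0.05 kg) noise, clipped to a plausibility band of [0, 2] kg
day⁻¹ that brackets reported field ranges. Default coefficients are chosen
so typical covariate profiles produce gains near 1 kg day⁻¹. Forage
defaults are the two seasons' printed descriptors (dry: 5020 kg ha⁻¹ FM,
16.5 % CP, 51.5 % NDF, 24.9 % ADF, 14.5 % leaf, leaf:stem 1.6; wet:
7900 kg ha⁻¹, 15.6 % CP, 61.3 % NDF, 30.2 % ADF, 30.7 % leaf, leaf:stem
1.0), jittered ±5 % per group-period and ±3 % per animal-period (forage is
sampled at paddock level, and this also keeps the regression design full
rank — with identical covariates inside each group the supplement level
would be an exact linear function of the group indicators). Realised
supplement level drifts ±7 % across periods for the same reason: it is
offered as a percentage of current body weight.

The forecast itself is ordinary least squares (statsmodels), genetic group
dummy-coded against the Nellore-dry reference, day carried as a numeric
index; rank deficiency and constant predictors raise errors naming the
offending columns. Evaluation uses the sample Pearson correlation and the
plain 1/n mean squared error, overall and per genetic group.

## Multivariate validation

PCA acts on the correlation matrix of the standardized animal-period
dataset (intake frequency, iADG, supplement level, forage covariates, and
genetic group as reference-coded indicators for the levels present).
Loadings use a deterministic sign convention — each component's
largest-magnitude loading is positive. Cluster presence is quantified as
the mean silhouette of the group labels in PC1/PC2 space; this statistic is
an extension chosen to make a visual cluster claim testable, not part of
the emulated analysis itself.

## Problem sizes and determinism

Package defaults keep a full study desk-scale: 22 animals × 1 simulated
day (316 800 records), three 28-day performance periods (66 animal-period
rows), and a 60 000-row cap (seeded subsample) on classifier training
tables. All stages draw from named integer seeds; identical configuration
and seeds reproduce byte-identical studies and identical metric reports.

## Known limitations

* The signal model is sinusoid-plus-noise, not a biomechanical jaw-motion
  model; absolute classifier metrics on synthetic data are optimistic.
* Bout-duration and signal parameters are declared assumptions; no public
  data exist to estimate them for this device and setting.
* The forecast operates on tens of animal-periods, mirroring the small-n
  reality of such studies; per-group correlations are volatile at n ≤ 10,
  and the PC1/PC2 group silhouette of a 66-row study varies noticeably
  across seeds (roughly 0.4–0.65 under the default scenario).
* Season-transfer experiments are supported as a configuration
  (`evaluate_transfer`) but no fixed transfer numbers are asserted, since
  they depend strongly on the constructed domain shift.
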