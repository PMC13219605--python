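# Methods

## Problem and model

`lethalheat` treats heatwave lethality as an imbalanced binary
classification problem. A heatwave is a maximal run of at least
`min_duration` consecutive days (default 2) whose daily maximum
temperature strictly exceeds the city's historical 90th percentile,
computed over the full available record. Roughly 0.78% of events are
lethal, so assessment centres on precision, recall and F1 rather than
accuracy (predicting "nonlethal" everywhere already scores ≈ 0.992
accuracy at that prevalence).

Conceptually, the lethal impact *H* of an event is modelled as a function
*f*(ρ, c, h) of population health ρ (mean BMI, population-pyramid
compressions, Socio-Demographic Index), antecedent climate c (the
thermo-temporal differentials and adaptive means), and the event's own
conditions h (maximum temperature, mean humidity, mean windspeed). The 15
predictors, in canonical order:

| group | features |
|---|---|
| absolute conditions | `max_temp` (°C), `mean_humid` (%), `mean_wind` (m/s) |
| population health | `mean_bmi` (kg/m²), `mean_age` (y), `age_gradient`, `mean_sdi` |
| temperature acclimation | `dT30`, `dT90`, `dT180` (°C), `adaptive_temp` (°C) |
| humidity acclimation | `dH30`, `dH90`, `dH180` (%), `adaptive_humid` (%) |

ΔT_n is the event maximum temperature minus the mean daily maximum over
the n calendar days strictly before the event start; ΔH_n likewise with
the event mean humidity. The adaptive temperature is the mean of the
daily maximum over the same n-day pre-event window in the event year and
the m − 1 preceding years (default m = 10, n = 30): a late-January event
averages that January and the previous nine. When fewer than m years
exist the mean truncates to all complete years, erroring below three.
The window length n for the adaptive variables is not pinned down by the
underlying study design; 30 days (a month, matching the worked
January example) is the package default and is configurable.

The age gradient compresses the population pyramid by the regression
slope with y = bracket midpoint age and x = bracket proportion, i.e.
cov(x, y)/var(x). Note the unusual orientation (age regressed on
proportion): a bottom-heavy (young) pyramid gives a negative gradient, an
ageing one a positive gradient, and a perfectly uniform pyramid has no
defined slope. Bracket midpoints are lower bound + 2.5 years, including
the open-ended top bracket.

Wet-bulb temperature uses Stull's one-equation empirical fit, valid for
roughly −20…50 °C and RH ≥ 5% (the cold-and-dry corner of that rectangle
is outside the fit's true, curved validity region, where the formula is
non-monotone in humidity; `stull_validity_mask` flags inputs).

## Classifier

A bootstrap-bagged random forest (default 500 trees, unlimited depth,
√p features per split) votes on each event; the raw score is the
fraction of trees voting lethal (hard votes, not averaged leaf
probabilities). Platt scaling — a maximum-likelihood logistic fit of
held-out labels on raw scores — maps scores to calibrated probabilities.
It is fitted on the validation partition: fitting on training data would
bias calibration because the forest is near-perfect on its own training
set. The decision rule is lethal iff calibrated probability ≥ 0.6, with
ties classified lethal (under-prediction is the more damaging outcome for
a warning system). Class imbalance is handled by resampling the training
partition, not by class weights.

## Splitting and resampling

To avoid temporal leakage while preserving geographic balance, the most
recent ⌈10%⌉ of events within each region (default region = city) form
the test set; a seeded unstratified 1/9 sample of the remainder forms the
validation set, giving an 80/10/10 split overall. Regions with fewer than
3 events go wholly to training with a warning.

Resampling applies to the training partition only; validation and test
class ratios are never altered. SMOTE (the default, to a 1:1
minority:majority ratio, k = 5) synthesises minority points
x_new = x_i + u·(x_nn − x_i) with u ~ U(0, 1) and x_nn one of the k
nearest minority neighbours. Because features mix °C, % and kg/m², the
neighbour search runs in per-feature standardized space; the convex
interpolation commutes with that affine map, so synthetic points are
valid feature vectors (and lie in the minority convex hull). When
retraining on a feature subset (dropout importance, forward selection),
SMOTE neighbours are re-fit in the active subspace. Random majority
downsampling is available as an alternative strategy.

## Sensitivity analysis and selection

Permutation importance: mean (and sd) over 10 seeded repeats of the F1
decrease when one feature column at a time is shuffled on the test
partition. Drop-column importance retrains the full recipe without each
feature. The two disagree in a characteristic way: permutation shares
importance across correlated features, while dropping one of a correlated
pair costs almost nothing. Both behaviours are asserted in the tests.

Greedy forward selection adds, at each step, the remaining candidate with
the highest validation F1 (ties break by canonical feature order); the
ladder's reported metrics are computed on the test set, which never
guides the choice.

Zero-denominator metrics are reported as 0 with an `undefined` flag
rather than NaN so selection ladders stay totally ordered.

## Synthetic data generator

The generator emulates the statistical shape of the real inputs, not the
physics. Daily maximum temperature is
mean + A·sin(2π(t − φ)/365.25) + AR(1) noise (A = 10 °C, φ = 110 d,
lag-one coefficient 0.7, innovation sd 2.5 °C), with each city's annual
mean drawn from 8–24 °C. Humidity is a counter-phased seasonal cycle
(mean 60%, amplitude 10%) plus −2.0 × the temperature anomaly plus noise,
clipped to [1, 100] — hot anomalies are dry, giving the negative
temperature–humidity correlation characteristic of temperate-skewed
records. These values were fixed so the corpus reproduces the reference
wet-bulb geometry: no events above 35 °C WBT, ≈ 1% above 30 °C, and a
conditional lethality rate below 6% for events at or above 25 °C WBT.
Windspeed is uncorrelated noise. All randomness derives from one root
seed through named substreams (weather / demographics / labels), so a
corpus is byte-identical given its configuration.

Demographic tables use exponential-shape pyramids over 19 five-year
brackets whose decay rates straddle zero (so age gradients of both signs
occur), a slow ageing drift, mean BMI in [20, 35] with a mild secular
rise, and SDI in [0, 1].

Lethal labels come from a two-mechanism model. An event whose wet-bulb
temperature exceeds `threshold_wbt` (default 35 °C) is lethal outright
("threshold" mechanism — heat dissipation failure). All other events
draw a Bernoulli label with logistic probability σ(b + w·z) on the
standardized drivers (ΔT_180, ΔT_30, mean BMI, age gradient, SDI) — the
"shock" mechanism. The intercept b is tuned by bisection (±10% relative
tolerance, ≤ 60 iterations) so the expected lethal fraction matches the
target prevalence (default 0.78%); the realised fraction then
concentrates around the target by binomial convergence. The default
weights make ΔT_180 and mean BMI co-dominant drivers:
w = (10.0, 0.8, 16.0, 0.8, −0.8). Their sharpness matters: much weaker
weights make lethality so stochastic that even the Bayes-optimal
calibrated classifier assigns essentially no event a probability above
the 0.6 decision threshold, which is inconsistent with the operating
point the method is known to achieve on real labels. The chosen weights
give Bayes-attainable precision ≈ 0.9 and recall ≈ 0.75 at the 0.6
threshold — the weakest signal consistent with that operating point.
Each lethal event carries its generating mechanism tag so taxonomy
recovery is testable.

What the generator does **not** emulate: spatial correlation between
cities, urban heat islands, trends in the climate itself, reporting and
misdiagnosis noise in the labels, or any real geography. Passing tests
on this corpus therefore show that the pipeline recovers structure *of
the planted kind* under realistic prevalence and correlation geometry —
not that the model is correct for any particular real dataset.

## Taxonomy

Lethal events with wet-bulb temperature below the shock cutoff (default
25 °C) are labelled Shock, the rest Threshold; nonlethal events are
NotLethal (an addition for completeness — the taxonomy originally applies
only to lethal events). Between 25 and 35 °C the rule is less certain, so
an optional indeterminate band can be configured. Agreement with planted
mechanisms is checked with the cutoff aligned to the generator's
threshold; shock events with WBT in between the default cutoff and the
generator threshold are the irreducible disagreement of the 25 °C rule.

## Problem sizes and numerical choices

Desk-scale defaults keep every run single-core and reproducible:

- Unit and property tests use corpora of ~1–2k events (24 cities × 22
  years) and forests of 40–80 trees.
- The headline benchmark (`lethalheat.experiments`) uses a 240-city ×
  40-year corpus (~52k events, ~430 lethal) with a 200-tree forest for
  the baseline-dominance comparison, and 20 re-plantings of the label
  model on a 30k-event subsample with 40-tree forests considering all
  features at every split for driver recovery (restricting split
  candidates only pushes trees onto correlated proxies of the drivers).
  Recovery runs rank importance on all held-out events (validation and
  test together) because at 0.78% prevalence the test partition alone
  carries too few positives for a stable ranking; the pipeline's own
  importance report stays on the test partition. These sizes were
  chosen as the smallest that give stable rankings; they are
  configuration, not science.
- Bisection bounds for the label intercept are [−40, 10]; ties at the
  decision threshold classify lethal; demographic year matching takes the
  nearest year, ties to the earlier.

## Known limitations

- The adaptive-variable window n and the minimum event duration are
  conventions, not derived quantities; both are configurable.
- Platt scaling consumes the validation partition, so validation metrics
  mildly favour the calibrated model.
- Permutation importance on heavily correlated feature blocks (the
  differentials) spreads credit; ranking individual features within a
  block is unstable by nature, which is why recovery checks target the
  planted drivers, not a full ordering.
- The generator's label model is exactly the logistic form the shock
  mechanism assumes; real lethality labels carry structure (reporting
  bias, spatial clustering) that no test here exercises.
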