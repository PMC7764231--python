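# Methods

`lunarpm` quantifies how concentrated firework discharge around the Chinese
Lunar New Year perturbs surface PM2.5, using a chain of five building
blocks: satellite AOD merging, neural AOD→PM2.5 retrieval, a
lunar-calendar-anchored time division, multi-year period fusion, and
event/policy statistics. Because the real multi-year station and satellite
archives are not redistributable at package scale, every stage is exercised
against a synthetic world with fully known ground truth; this note explains
the models, the defaults, and what the synthetic results do and do not
establish.

## Satellite AOD merging

Terra-like (morning) and Aqua-like (afternoon) daily AOD rasters on a
common 0.1° pixel-centre grid are combined per pixel: both present → the
arithmetic mean, exactly one present → that value, neither → missing. The
rule is symmetric, its missing mask is the logical AND of the input masks,
and merged values are bounded by the per-pixel min/max of the inputs; these
three properties are enforced by tests. No quality-flag screening is
applied — inputs are assumed to be pre-gridded, QA-screened daily fields.

## Neural retrieval

A three-layer feed-forward back-propagation network maps nine predictors —
longitude (°), latitude (°), day-of-year, AOD (dimensionless), relative
humidity (%), temperature (K), wind speed (m/s), surface pressure (Pa) and
planetary-boundary-layer height (m) — to PM2.5 (μg/m³). The hidden layer
has 18 tanh units by default; a classical sizing heuristic brackets the
optimum between 2+μ and 2n+1 nodes for n inputs and μ outputs, so sizes
outside [2, 19] draw a warning but are accepted (the rule is a heuristic,
not a constraint).

Numerical recipe: inputs and label are z-scored; weights are initialised
from N(0, 1/fan-in) with a seeded generator; optimisation is full-batch
gradient descent with momentum 0.9 and learning rate 0.1 on the mean
squared error, stopping when the relative loss change stays below 1e−6 for
10 consecutive epochs or at 5000 epochs. The epoch budget was set to where
the optimizer reliably reaches the noise floor of the smooth synthetic
mapping; all of these values are exposed as `train()` keyword arguments.
Predictions are clamped at 0 μg/m³ (concentrations are non-negative), and a
grid pixel missing any predictor yields a missing retrieval.

Skill is reported as the Pearson correlation R between observed and
retrieved concentrations and the root-mean-square error
RMSE = √(n⁻¹ Σ(yᵢ − yᵢ′)²). R is implemented in the standard
covariance-over-SDs form. Out-of-sample skill uses sample-based 10-fold
cross-validation: a seeded random partition into folds whose sizes differ
by at most one, each fold predicted by a model trained on the other nine,
with R/RMSE computed on the pooled out-of-fold predictions.

## Lunar time division

The celebration window spans 17 days: New Year's Eve, New Year's Day, and
the first lunar month through the day after the Lantern Festival (lunar
day 15). The Eve is included deliberately: counting only from New Year's
Day gives 16 days, and the discharge peak at 02:00 follows Eve-night
displays, so the 17-day span is reconciled by starting on the Eve.

Anchored on that window, each lunar cycle (one celebration window up to the
next) is tiled with 21 contiguous labelled periods: the celebration, ten
17-day post-celebration blocks counted forward, nine 17-day pre-celebration
blocks counted back from the next window, and a residual `pre-10` that
absorbs whatever remains (15 days for the 2013→2014 cycle; it may be any
non-negative length, and falls in summer where it least affects the winter
analysis). Anchor dates are supplied as configuration (the 2013–2016
Gregorian festival dates ship as defaults); no astronomical lunar
computation is performed, so the package has no load-bearing calendar
dependency.

## Fusion and effect statistics

Retrieved daily grids sharing a period label are fused across years into
one mean map per label (mean of non-missing contributors per pixel). The
station-side period mean is the unweighted mean over all stations and hours
in the period; the sustained-effect comparison sets each cycle's
celebration mean against the equal-weight mean of its `pre-1` and `post-1`
period means. Stations are unweighted throughout — national averages are
plain means, and a "city" series is the unweighted mean of its stations.

Instantaneous effects: the national hourly mean (unweighted over stations
reporting that hour), the per-day maximum and its hour (ties broken to the
earliest hour), and the peak-to-baseline ratio — the event-day maximum as a
percentage of the mean of the flanking days' maxima (one day each side by
default; the width is a parameter).

Each city–cycle pair is classified by three ordered rules evaluated over
the celebration period with the Lantern-Festival days (lunar days 14–16)
excluded: *significant* if the period maximum falls in the 00:00–04:00
window of New Year's Day; otherwise *obvious* if the New-Year-night
increase (value at 04:00 minus value at 00:00) **and** increase rate
(increase over the 00:00 value) are both strictly the largest among the
considered days (ties fail the rule); otherwise *weak*. The increase
operands are the window endpoints; a max-minus-min variant was considered
and rejected as less interpretable for a monotone burst. Rule 1 depends
only on the argmax location, so the *significant* label is invariant under
any strictly increasing transform of the series — a property test.

## Policy anomalies

The normal level for a cycle is the 34-day mean of all hourly values in
`pre-1` ∪ `post-1`. It is a single scalar, not an hour-of-day climatology
(an hour-matched baseline is available as an option); anomalies are hourly
values minus that scalar, so adding a constant to the series leaves them
unchanged, and the anomaly averaged over the baseline days is zero.
Policy comparisons report, per year, the mean anomaly over 00:00–04:00 of
New Year's Day and over the whole celebration period, flagging whether the
discharge-window anomaly declined after the policy year.

## The synthetic world

The generator produces the regime the analysis assumes, with ground truth
for recovery tests. Hourly station PM2.5 is

  (baseline + seasonal + diurnal + spatial) × holiday + spike + noise,

truncated at zero, with: baseline 55 μg/m³; a seasonal cosine of amplitude
30 μg/m³ peaking 15 January (winter maximum); a bimodal diurnal term of
amplitude 15 μg/m³ with Gaussian bumps at 09:00 (σ = 2 h) and 22:30
(σ = 1.5 h), matching the morning/late-evening maxima typical of urban
PM2.5; a smooth low-order sinusoidal spatial field of amplitude 8 μg/m³; a
holiday factor of 0.9 (10% emission reduction) over each 17-day celebration
window; a firework spike of 250 μg/m³ at its central hour, shaped as a
Gaussian over hours 0–4 of New Year's Day peaking at 02:00; and stationary
AR(1) noise (SD 10 μg/m³, lag-1 coefficient 0.6). A multiplicative
log-normal noise option replaces truncation when strictly positive values
are wanted. A subset of stations can carry the spike, so cohort tests can
inject events into k of m "cities".

Grids: meteorology fields are smooth in space (sinusoid sums per variable)
with AR(1) day-to-day anomalies (persistence 0.7) and a summer-peaking
seasonal term for temperature and boundary-layer height. The true
retrieval mapping is

  PM2.5 = AOD × (80 + 0.5·RH + 25·exp(−HPBL/1000)),

a smooth, strictly positive, nonlinear (multiplicative + exponential)
relationship. AOD is obtained by inverting it at the deterministic daily
PM2.5 level, so with zero noise the feature set reproduces the truth
exactly; Terra and Aqua copies receive independent Gaussian AOD noise
(default 0) and independent per-pixel cloud masking (default probability
0.3). All draws run through `numpy.random.default_rng` seeded from
`rng_seed`, so outputs are bit-reproducible.

What the generator does **not** emulate: chemical transport, plume
advection between stations, correlated cloud structures, terrain effects,
station siting bias, or instrument error models. Passing recovery tests
therefore demonstrate that the pipeline's statistics measure what they
claim under the assumed structure — not that the retrieval would attain
any particular skill on real MODIS/archive data.

## Problem sizes in the shipped checks

The test-suite and the reproduction script use a 10-station network over
the 2013–2016 study span for event statistics, a one-year 50×50-pixel grid
world with 2000 training samples for retrieval recovery, and single-cycle
worlds for classification and policy scenarios — sizes at which every
quantity stabilises while the full suite runs in a couple of minutes.

## Known limitations

* The retrieval's skill ceiling on real data is untestable here (see
  above); shipped CV numbers describe the synthetic world only.
* The residual `pre-10` period may be empty for hypothetical anchor pairs
  exactly 340 days apart; the tiling handles this but real lunar years do
  not produce it.
* The classification assumes hourly completeness around the New-Year
  night; missing 00:00/04:00 values degrade rule 2 to the available hours
  with a warning rather than an error.
* Period fusion averages without area weighting, matching the plain
  national averages used throughout.
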