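# Methods

## Problem setting

A cinema audience continuously vents breath- and skin-borne chemistry into
the room's exhaust air. Sampled every 30 s, each screening yields one
mixing-ratio trace per compound (ppb; CO₂ in ppm). The pipeline asks
whether the shape of those traces — after removing the slow occupancy
trend — predicts the film's FSK age class (0, 6, 12, 16), using one model
per compound, leave-one-film-out-per-class evaluation, and a label-shuffle
permutation test.

## One-box mass balance

The screening room is treated as a single well-mixed compartment of volume
V = 6500 m³ flushed with Q = 1300 m³/h of outside air at inflow mixing
ratio C_in. With a constant source E the mixing ratio obeys

    dC/dt = (Q/V)(C_in − C) + E/V,

with closed-form solution

    C(t) = C_ss + (C0 − C_ss) · exp(−t/τ),   C_ss = C_in + E/Q,   τ = V/Q.

For the measured rooms τ = 5 h, so a screening never reaches steady state.
The model is solved in closed form, never by numeric ODE stepping, for
exactness and testability.

### Fitting

Per screening and compound the trace is windowed to [start, end] (closed
interval, boundary samples inclusive), the last 5 minutes are dropped (the
stand-up isoprene burst), and the trace is divided by the viewer count, so
E is per person. With C_in fixed, the solution is *linear* in the
steady-state excess a = E/Q and in C0:

    C(t) − C_in = a · (1 − e^(−t/τ)) + (C0 − C_in) · e^(−t/τ),

so the least-squares optimum is computed exactly by linear least squares
(`numpy.linalg.lstsq`, or `scipy.optimize.lsq_linear` when the E ≥ 0 bound
binds; a config switch permits negative E for depositing species). The
constrained linear formulation replaces an iterative two-parameter
minimization; the optimum is identical.

C_in is estimated as the median of the 10 minutes of data preceding the
screening start (divided by the viewer count), which is robust and
auditable. When no pre-start data exist the configured room inflow value
is used instead. A three-parameter co-fit of C_in is **not** offered: in
the closed form C_in and the excess enter only through their sum
(coefficients a + C_in and C0 on the two basis functions), so they are not
jointly identifiable. The fit uses the whole trimmed window including the
entry rise, which the constant-emission model tracks from C0.

The residual series is measured − modelled. Scene-locked crowd responses
appear as positive excursions under this sign convention, which is what
"highest peaks" presumes.

## Feature set

Per (screening, compound) residual series, 18 named values:

| group | features |
|---|---|
| moments | `std`, `kurtosis` (excess), `skewness` |
| sums | `sum_positive`, `sum_negative` |
| peak counts | all peaks and robust peaks, each / film length (min⁻¹) |
| occurrence | first robust-peak apex time / film length |
| peaks | 5 highest heights, 5 widest widths (robust set, descending, zero-padded) |

A *peak* is an apex with ≥ m strictly increasing steps immediately before
and ≥ m strictly decreasing after (m = 1: all peaks; m = 3: robust peaks).
Plateaus break a run; equal heights/widths are ordered by earlier apex.
Width spans the maximal monotone rise and fall around the apex, in
minutes. The enumerated feature-family list naturally counts to 20 (the
sums of the top-5 heights and widths are also natural members); the
default 18-value composition drops those two aggregates because they are
exact linear functions of the included heights and widths, so no
information is lost. Both the 20-value variant and an alternative 18-value
variant (keep the aggregates, drop the two counts) are reachable through
`FeatureConfig.variant`.

Degenerate inputs are mapped, not errored: an all-constant series has
moments 0 (rather than NaN), all peak features 0, and first-peak
occurrence at the sentinel 1.0.

## Evaluation design

Instances are screenings. For each class one film is held out as the test
set and the class's remaining films train; test eligibility requires ≥ 8
recorded screenings. The class containing the configured "always
together" pair (two films measured once each) is instead *partitioned*
into two options — the pair pooled, or all the class's other films pooled
— since single-screening films cannot be evaluated alone. The Cartesian
product of per-class options gives the split plan: 24 combinations for
the campaign film list.

Per combination one multiclass random forest (500 trees, ⌊p/3⌋ = 6
variables per split, scikit-learn) is trained and its class-probability
outputs scored one-vs-rest per class:

* **ROC-AUC** is computed from midranks, i.e. exactly the Mann–Whitney
  pair-ordering probability with half-credit ties. A (combo, class) with
  no positives or no negatives in the test set is reported missing (NaN),
  excluded from means, and logged — never imputed at 0.5.
* **PRC** points come from `sklearn.metrics.precision_recall_curve`; for
  averaging across combinations, precision is linearly interpolated onto a
  fixed 101-point recall grid, keeping at each distinct recall the
  precision of the highest threshold achieving it (equivalently the
  maximum). Interpolated precision is upward-biased for small test sets;
  the prevalence limit is therefore only asserted at larger sizes in the
  tests.

Reproducibility: a master seed; per-combination (and per-shuffle) seeds
derived deterministically through `numpy.random.SeedSequence`.

## Permutation test

Training films' labels are shuffled at film level (all screenings of a
film move together; the label multiset over films is retained); the test
set keeps its true labels. Default k = 50 shuffles per combination.
Exceedance (permuted AUC ≥ original, ties counting against the original)
is pooled over combinations and the p-value is the add-one estimate
p = (b + 1)/(n + 1), so p is never 0; the raw fraction b/n is selectable.
Per-film p-values apply the same formula restricted to combinations whose
test set contains the film. No multiple-testing correction is applied by
default (the analysis is a screen for candidate compounds); a corrected
report can be derived from the p-value table.

## Synthetic studies

The generator is the forward model of the box model above. Per film a
fixed event schedule (Poisson times, lognormal burst amplitudes, 1.5–3 min
boxcar durations) is drawn once and shared by all of that film's
screenings — film identity is the schedule, class identity its
rate/amplitude statistics. Emissions are per-person baselines (default
25 ppb·m³/h, giving a per-person steady excess E/Q ≈ 0.02 ppb) plus the
scene-locked bursts, scaled per compound (CO₂ uses scale 700 and a
400 ppm inflow so a full house raises CO₂ by ~10³ ppm). Audiences enter
over a 5-min ramp after the nominal start, leave over 2 min, and an
optional 12× baseline burst in the final 3 minutes mimics the stand-up
isoprene spike (removed by the 5-min trim by construction). Under-12
viewers emit a configurable fraction (default 0.5) of the adult rate.
Gaussian noise (default σ = 0.05 ppb; 2 ppm for CO₂) is added per sample.

All screenings sit on one continuous 30-s grid. Because the occupied
room's residence time (5 h) exceeds the gap between screenings, the empty
room is flushed at a stronger purge ventilation (default 8 air
exchanges/h) between screenings, so each 15-min pre-entry baseline window
is settled. Concentrations advance by the exact exponential relaxation
over each sampling step with piecewise-constant emission and ventilation.

What the generator does **not** emulate: instrument drift and
calibration error, correlated (non-white) noise, variable ventilation
during screenings, inter-compound correlation beyond shared scaling,
scene-type structure within a film, or audience heterogeneity beyond the
under-12 split. Passing tests therefore demonstrate correctness of the
pipeline's inference under its own model assumptions, not performance on
real cinema data.

## Study sizes and numerical choices in the test suite

* Identifiability: a (2, 3, 2, 2)-films-per-class study, 10 screenings per
  film, burst amplitudes (200, 1000, 5000, 25000) ppb·m³/h — 5× apart —
  is required to reach mean one-vs-rest AUC ≥ 0.9 per class with the
  full 500-tree ensemble over all 24 combinations.
* Null calibration: 20 replicate studies with identical profiles
  (amplitude 1000 everywhere), 24 combinations × 50 shuffles each. These
  24,480 forest fits use a reduced 20-tree ensemble, a problem size chosen
  to keep the calibration tractable on a single CPU; the 500-tree default
  is untouched everywhere else. Per-replicate mean AUC can sit far from
  0.5 (with 2–3 films per class, chance film-level differences make some
  classes spuriously separable — exactly what the film-level permutation
  null absorbs), so calibration is asserted on the p-value distribution
  (KS vs uniform, α = 0.01, per class) and on the across-replicate grand
  mean AUC.
* Solver tolerances: box-model round trips are checked to 1e-6 relative
  (they achieve ~1e-12); residuals on model-generated input to 1e-9.
* The synthetic "pure box model" check allows residual std up to 1e-5
  ppb/person: the entry-occupancy step is discretized to the 30-s grid,
  leaving a one-sample mismatch.

## Known limitations

* The FSK-16 class of the campaign has 5 screenings across 3 films; its
  AUCs rest on tiny test sets and are reported but hardly interpretable.
* The constant-emission model absorbs slow emission drifts (e.g. rising
  room temperature) into E; such drifts leak into the residual moments.
* Baseline C_in estimation assumes the pre-entry window is audience-free;
  back-to-back real screenings with residual occupancy violate this and
  bias E downward slightly.
* Figures are emitted as plot-ready long tables (`auc_long.tsv`,
  `prc_mean.tsv`, `peak_heights.tsv`) rather than rendered images; the
  tables are the tested interface.
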