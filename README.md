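# crowdvoc

Film age-class prediction from cinema "crowd breath" chemistry.

Cinema audiences continuously emit volatile organic compounds (VOCs) and
CO₂ into a screening room's exhaust air, and some of those emissions are
locked to what is happening on screen. Given per-screening metadata
(film, FSK age class 0/6/12/16, time window, audience size) and 30-second
mixing-ratio traces per compound, this package asks whether the shape of
a compound's trace predicts the film's age classification:

1. **Detrend** — each screening's trace is windowed, the last 5 minutes
   dropped (stand-up isoprene burst), divided by the audience size N, and
   fitted with the one-box mass balance
   `dC/dt = (Q/V)(C_in − C) + E/V` (V = 6500 m³, Q = 1300 m³/h, τ = V/Q
   = 5 h), assuming a constant per-person emission rate E. The fit is
   exact linear least squares of the closed-form solution. Subtracting
   the model leaves the *residual time series*.
2. **Featurize** — 18 values per (screening, compound): residual moments
   (σ, skewness, excess kurtosis), positive/negative sums, peak counts
   per film minute under two rules (any single-step peak; "robust" peaks
   with ≥ 3 strictly increasing and decreasing steps), first-peak
   occurrence, and the 5 highest / 5 widest robust peaks.
3. **Evaluate** — leave one film per class out as the test set (test films
   need ≥ 8 screenings; the two single-screening FSK-16 films always move
   together and are evaluated jointly against the rest of their class),
   giving 24 train/test combinations for the campaign film list. Per
   combination a 500-tree random forest (6 of 18 features per split)
   yields one-vs-rest ROC-AUC (= Mann–Whitney pair-ordering probability)
   and precision–recall curves averaged on a fixed recall grid.
4. **Test significance** — training-film labels are shuffled 50× per
   combination (film-level, class distribution preserved; test labels
   untouched) and the pooled exceedance p-value `p = (b+1)/(n+1)` is
   reported per class, uncorrected.

A synthetic-study generator (the forward model of step 1, with
film-specific scene-locked emission bursts whose statistics differ by
class) makes every stage testable end to end without any measurement
data. See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a four-class synthetic study whose classes differ in burst
amplitude, then run the full analysis:

```sh
crowdvoc simulate --out study --seed 7 --spec examples/demo_spec.yaml
crowdvoc run --config examples/demo_run.yaml
```

The run writes tab-separated result tables (`auc_mean.tsv`, `auc_sd.tsv`,
`pvalues.tsv`, `auc_long.tsv`, `prc_mean.tsv`, `per_film.tsv`,
`peak_heights.tsv`, `features.tsv`, `box_fits.tsv`) plus `report.txt`:

```text
Per-compound one-vs-rest mean AUC over split combinations
(values >= 0.70 flagged with *)

compound           FSK 0     FSK 6    FSK 12    FSK 16
CO2                0.98*     0.88*     1.00*     1.00*
m69.0699           1.00*     1.00*     1.00*     1.00*

Permutation p-values (uncorrected)
compound           FSK 0     FSK 6    FSK 12    FSK 16
CO2                0.189     0.266     0.256     0.198
m69.0699           0.181     0.191     0.258     0.200

config digest: ba02eaf93e20dbd1  seed: 7
```

Reading it: each row is one compound's model; columns are the per-class
mean one-vs-rest AUC over all 24 train/test combinations, `*`-flagged at
≥ 0.70. The simulated burst amplitudes grow with the age class, so both
channels separate every class almost perfectly. The permutation p-values
stay near 0.2 even so: each training set holds only five films, and a
label shuffle has roughly a 1-in-5 chance of handing the decisive film
its true class back, in which case the refit model scores just as well —
with this few films per class the permutation test is intrinsically
coarse, a limitation that real campaigns of this size share. With real
cinema data only some compounds separate some classes at all.

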