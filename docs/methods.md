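# Methods notes

This note documents the models, numerical choices and open design
decisions behind `swaylab`, in the spirit of a package methods
appendix. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic study generator

### Latent-instability model

The generator emulates a full within-subject factorial load-holding
experiment: every subject performs all 24 combinations of Working
Posture (WP, P1–P6), Surface Slope (SS, flat/18°-inclined) and Load
Carriage (LC, 0/10 kg), each repeated twice, for 10 s per trial.
All of a trial's outputs are driven by one positive latent instability
intensity

    λ = exp(β₀ + β_WP[j] + β_SS·s + β_LC·l + β_WPxLC[j]·l + ...
            + b_subject + ε)

with `b_subject ~ N(0, σ_s²)` a between-subject random intercept shared
across a subject's trials and `ε ~ N(0, σ_e²)` residual trial noise.
Working on the log scale keeps λ positive and makes factor effects
multiplicative on sway amplitude, which is how balance degradation
behaves empirically.

Default effect sizes: `β_WP = (0, 0.1, 0.35, 0.5, 0.65, 0.8)` (P1
easiest, overhead carrying hardest), `β_LC = 0.6`, a WP×LC interaction
ramp up to 0.3 (load hurts more in awkward postures), and `β_SS =
0.05`. The SS default is deliberately an order of magnitude below LC:
the study design this generator emulates found the 18° surface to have
a much smaller effect than the 10 kg load, with most measures failing
to detect it. A within-subject design averages 12 cells × 2
repetitions per surface level, so even tiny surface effects become
detectable; 0.05 with the default noise scales puts SS detection in
the "marginal" regime (a minority of measures, varying across
sensors and seeds) while WP and LC stay at essentially full power.

Noise scales: `σ_s = 0.3`, `σ_e = 0.4`. In addition, every sensor axis
is multiplied per trial by an independent lognormal coupling jitter
(`gain_jitter_sd = 0.45`). Without this jitter every amplitude measure
would be an exact deterministic function of λ and the 43 measures would
behave as one test repeated 43 times; the jitter emulates
placement- and strategy-dependent coupling variation and gives the
measure battery realistic partial independence. Scale-invariant
measures (MF, FD) are unaffected by the jitter by construction.

### Signal model

Each sensor axis is stationary Gaussian noise shaped in the frequency
domain by the magnitude response of a second-order Butterworth
band-pass (default 0.1–3 Hz — the band where quiet-stance sway energy
lives) and scaled so its sample SD equals `sensor_gain × λ` in
expectation. Frequency-domain shaping is used instead of a time-domain
IIR pass because the 0.1 Hz corner has a start-up transient comparable
to the whole 10 s trial; the spectral route is exact, stationary and
fast. The analytic output SD for unit white input comes from Parseval
over the rfft bins, so the target SD needs no per-trial empirical
renormalisation and natural sampling fluctuation is preserved.

The upper passband edge scales as `(λ/exp(β₀))^γ` with `γ = 0.7`
(clipped inside the Nyquist range): less stable trials sway both
*larger* and *faster*. Without this coupling the spectral mean
frequency and the fractal dimensions — which are amplitude-invariant —
would be blind to every factor, which contradicts how these measures
behave on real balance data.

Sensor gains default to pelvis 1.0 (closest to the centre of mass),
lower legs 0.8 (ankle strategy), T8 0.75, shoulders 0.6, upper legs
0.5, so the pelvis is the most informative placement.

The COP trajectory is its own band-limited process sharing the same λ
(scale 80 mm·λ, i.e. ≈8 mm sway SD at typical λ); correlation with the
pelvis acceleration arises only through the shared latent. The COP is
deliberately *not* obtained by double-integrating the acceleration:
integration drift would dominate and the labeling channel (COPV_AP)
must stay well conditioned.

The rating is `PPS = clip(12 + 3·log λ + N(0, 0.6), 0, 10)`, kept
continuous by default (a `round_pps` flag snaps it to the 11-point
scale). Intercept and slope are chosen so the default study spans the
scale with roughly balanced stable/unstable classes.

Gravity is not simulated: trials are static postures, so gravity is a
constant per-axis offset, and every measure operates on mean-removed
signals anyway.

Determinism: each trial's randomness comes from a generator seeded
from `(seed, subject, condition, repetition)` and the subject effect
from `(seed, subject)`, so studies are reproducible trial-by-trial and
insensitive to evaluation order.

### What the generator does *not* emulate

No biomechanics (no inverted pendulum, no joint kinematics), no sensor
bias/drift/orientation error, no non-stationarity within a trial, no
inclined-surface geometry (SS is purely an effect size), no
learning/fatigue across repetitions. Passing tests on this generator
demonstrate that the *pipeline* is correct and calibrated, not that
any particular real population would show these effect sizes.

## 2. Preprocessing

"Fourth-order zero-phase low-pass Butterworth" is implemented as an
order-2 design applied forward and backward (`filtfilt`), the standard
reading in which the stated order is the effective order of the
two-pass cascade; `design_order=4` gives the literal alternative. The
cutoff is not dictated by the measure definitions; 10 Hz is the
package default for both ACC and COP, comfortably above sway content
and consistent with common stabilometry practice. Edge handling uses
reflective (`even`) padding of length 3×order. Axis order is AP, ML,
IS; resultants are computed samplewise from the detrended axes.

## 3. The 43 measures

Definitions follow the classical COP stabilometry formulas applied to
the acceleration statokinesigram. Notable choices:

- **AVG on axis directions** is the mean of |detrended signal| — the raw
  mean is ≈0 after gravity removal and would carry no information. On
  the resultants it is the plain mean. Consequently AVG_AP ≡ MD_AP and
  RMS ≡ RMSD numerically; both names are kept because the measure
  registry lists the families separately. An `avg_raw` flag restores
  literal raw means.
- **Areas** (ARE_SW triangle sweep, ARE_CC confidence circle with
  z = 1.645, ARE_CE confidence ellipse with the exact F₀.₀₅[2, n−2]
  quantile) are divided by trial duration ("per unit of time"); a flag
  disables the normalisation. Values stay in the input's units
  ((m/s²)² per second for acceleration input); unit conversion is a
  reporting concern.
- **Fractal dimensions** use FD = ln N / ln(N·d/L) with the planar path
  length L and the characteristic diameter d of the confidence circle
  (FD_CC) or of the circle with the ellipse's area (FD_CE).
- **Mean frequency** is the power-weighted mean of the one-sided
  periodogram, DC excluded; resultant directions use the centred
  resultant-magnitude series. The rotational alternative
  MV/(2π·MD) is exposed as `rotational_mean_frequency` but is not one
  of the 43.
- **MV/PD/PP** integrate the acceleration once (velocity) and twice
  (displacement) by cumulative trapezoids with linear detrending after
  each pass — deterministic and parameter-free drift control that
  admits closed-form checks (a high-pass filter would add a tuning
  parameter). PP is computed on the AP (sagittal) direction.
- **Degenerate inputs** (zero-variance trajectories) yield flagged NaN
  for FD/MF and flagged zeros for areas; flags propagate rather than
  silently becoming numbers.
- **COPV_AP** is the summed absolute AP increment over duration, on the
  filtered COP; with the n/rate duration convention a 30 mm ramp over
  10 s gives exactly 3.0 mm/s.

The whole battery is verified in the test suite against an independent
loop-based transcription of the definitions (1e-9 relative, 1e-6 for
the FFT-based MF) on random Gaussian trials.

## 4. Repeated-measures ANOVA

The three-way fully-within ANOVA is computed from orthonormal
(Helmert) contrast scores per effect: `SS_eff = n·Σ z̄²`,
`SS_err = Σ(z − z̄)²`, `F = (SS_eff/d)/(SS_err/(d(n−1)))` — the
classical decomposition in which each effect is tested against its own
effect-by-subject interaction. Repetitions are averaged within
subject × condition first (repetition is not modelled as a factor).
The same contrast covariance yields Mauchly's W (with the standard χ²
approximation) and the Greenhouse–Geisser ε (clamped to [1/d, 1]).
Following the conventional recipe, GG is applied — multiplying both
degrees of freedom — exactly when the effect has more than one
contrast and Mauchly rejects at α; two-level effects are exempt
(sphericity is vacuous for a single contrast). The implementation is
cross-checked against `statsmodels` `AnovaRM` in the tests and its
type-I error is calibrated by simulation under the generator's null.

Shapiro–Wilk normality results are reported per design cell as
diagnostics only; no automatic nonparametric fallback is taken.
Detection counts use raw p < 0.05 per measure (no multiplicity
correction across the 43 measures, matching how such counts are
conventionally tabulated); a Holm option exists for the paired
t-tests and is off by default.

## 5. Classification

Features are computed on the **raw** (unfiltered) acceleration — the
feature battery is defined on the raw signal, unlike the measure
pipeline — with a flag to filter for comparability. "First five FFT
coefficients" is read as the magnitudes of the five lowest
nonzero-frequency rfft coefficients (DC would duplicate the mean
feature already in FS1). Skewness/kurtosis of zero-variance signals
are imputed as 0. z-scoring is fit on the full dataset before
cross-validation, matching the order feature extraction →
standardisation → CV; note this leaks fold information — a
`fold_safe_zscore` option refits within training folds. Folds are
stratified by class and seeded; trials are treated as i.i.d. instances
(a `group_by_subject` option switches to subject-grouped folds, off by
default). Each trial is an instance; averaging repetitions into
task-level instances is possible upstream of the grid but is not the
default.

Classifier roster (open equivalents of a standard classification-
toolbox roster): KNN with city-block and Euclidean metrics (k = 10),
Gaussian naive Bayes, kernel naive Bayes (per-feature Gaussian KDE
with Silverman bandwidth — implemented in-package since scikit-learn
has no KDE naive Bayes), logistic regression, linear discriminant
analysis, linear and cubic-polynomial SVMs, a decision tree, bagged
trees (100 trees), and an "optimised ensemble" that grid-searches a
small fixed set {bagging 30/60 trees, AdaBoost 30 stumps/depth-3
trees} by inner stratified 5-fold CV. Hyperparameters beyond this
fixed grid are deliberately not tuned. Accuracy is
(TP+TN)/(P+N)·100 per fold, averaged over the 5 folds, reported to
one decimal.

Labels: PPS ≥ 5.0 → unstable (the boundary is unstable); COPV_AP uses
the interpolated median with the boundary trial unstable, which
balances classes to within one trial.

## 6. Problem sizes used by tests and the acceptance script

- Detection-pattern and classification runs: 15 subjects × 24
  conditions × 2 repetitions at the full 10 s / 240 Hz trial format
  (720 trials, 8 sensors). The panel size is the package's chosen
  compromise for routine reruns; effect sizes are never adjusted to
  it.
- Null calibration of the ANOVA: 500 replicate studies of 10 subjects,
  one sensor, 2 s / 60 Hz trials under the all-betas-zero generator;
  the two repetitions are averaged as in the full design. The shorter
  trials only widen measure-level sampling noise, which the null
  calibration is insensitive to.
- Oracle equivalence: 100 Gaussian trials of 600–1200 samples.

## 7. Known limitations

- The generator's single-latent structure makes all amplitude measures
  highly mutually correlated (softened, not removed, by the coupling
  jitter); real measure batteries decorrelate further through
  direction-specific physiology the model does not contain.
- Mauchly's χ² approximation is poor for very small panels (n−1 close
  to the contrast dimension); the implementation returns NaN when the
  contrast covariance is singular rather than pretending.
- GG correction with F < 1 can nominally lower a (large) p-value;
  significance decisions are unaffected.
- The classification defaults reproduce the leakage-prone
  standardisation order by design; use `fold_safe_zscore=True` and
  `group_by_subject=True` for honest generalisation estimates on real
  data.
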