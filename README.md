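# swaylab

Accelerometer-based assessment of working-postural stability.

People who hold demanding static working postures — think of a mason
holding a loaded box on an inclined surface — sway more when their
balance is challenged. Body-worn accelerometers (IMUs) are a cheap,
portable alternative to force-plate center-of-pressure (COP)
measurement for quantifying that sway. `swaylab` implements a complete,
tested analysis pipeline for this problem, aimed at ergonomics and
biomechanics researchers:

1. **Synthetic factorial study generator** — a full within-subject
   design over Working Posture (WP, six levels P1–P6) × Surface Slope
   (SS, flat/inclined) × Load Carriage (LC, 0/10 kg), producing coupled
   tri-axial accelerations for eight body segments (240 Hz, 10 s
   trials), a 2-D COP trajectory (40 Hz) and a 0–10 perceived-stability
   rating (PPS) per trial, all driven by one latent instability
   intensity per trial.
2. **Preprocessing** — fourth-order zero-phase low-pass Butterworth
   filtering, gravity/DC removal, and derivation of the five
   directional series (AP, ML, IS and the 2-D/3-D resultants).
3. **43 sway measures** per sensor × trial: the classical stabilometry
   battery (means, ranges, RMS, trajectory lengths, mean/RMS distances,
   sway areas ARE_SW / 95 % confidence circle ARE_CC / ellipse ARE_CE,
   fractal dimensions FD_CC/FD_CE, spectral mean frequencies, integrated
   mean velocities, planar deviations and the phase-plane parameter),
   applied to the acceleration statokinesigram, plus the COP reference
   measure COPV_AP (mean AP velocity of the COP).
4. **Factor-effect detection** — three-way repeated-measures ANOVA per
   measure per sensor, with Mauchly's sphericity test and the
   Greenhouse–Geisser correction for posture-bearing effects, paired
   t-tests, Shapiro–Wilk diagnostics, and detection-count summaries
   (how many of the 43 measures detect each factor at each sensor).
5. **Stable/unstable classification** — feature sets FS1 (7 moments),
   FS2 (first five FFT magnitudes) and FS3 (both), sensor
   configurations SC1 (8 sensors) / SC2 (4) / SC3 (pelvis+T8) or
   pelvis-only, labels from PPS (stable iff < 5.0) or from the COPV_AP
   median split, z-score standardization, and seeded stratified 5-fold
   cross-validation over eleven classifiers, reporting percent accuracy
   (TP+TN)/(P+N)·100.

## The model at the core

Each trial's sway is governed by a latent instability intensity

λ = exp(β₀ + β_WP[j] + β_SS·1{inclined} + β_LC·1{10 kg} + interactions
  + b_subject + ε),  b_subject ~ N(0, σ_s²), ε ~ N(0, σ_e²)

Sensor accelerations are stationary band-limited Gaussian noise with
per-axis SD proportional to λ (pelvis coupling strongest) and an upper
passband edge that grows as λ^γ, so amplitude-domain *and*
frequency-domain measures respond to the factors; the COP trajectory
and PPS rating are driven by the same λ. Defaults make WP and LC
strongly detectable and SS only marginally — the qualitative pattern
such load-holding experiments report.

For the statistics, every effect is tested against its own
effect-by-subject interaction; for posture-bearing effects the
Greenhouse–Geisser ε (from the orthonormal-contrast covariance) scales
both degrees of freedom whenever Mauchly's test rejects.

## Worked example

```python
import swaylab as sl

cfg = sl.StudyConfig(n_subjects=12, n_repetitions=2, trial_duration=5.0,
                     acc_rate=120.0, seed=42)
study = sl.simulate_study(cfg)                    # 12 x 24 x 2 = 576 trials

vec = sl.compute_all_measures(study.trials[0], "pelvis")
print(vec["RMS_AP"], vec["MF_AP"])                # 0.0555 m/s^2, 1.99 Hz

wide = sl.compute_study_measures(study, sensors=["pelvis"])
print(sl.RMAnova(wide, "RMS_AP").fit().summary())
```

```
Three-way repeated-measures ANOVA on 'RMS_AP' (n=12 subjects, alpha=0.05)
effect             F     df1      df2    eps         p   GG  sig
SS             0.494    1.00    11.00  1.000    0.4966   no
LC           132.002    1.00    11.00  1.000    0.0000   no  *
WP            31.873    2.93    32.23  0.586    0.0000  yes  *
SSxLC          0.000    1.00    11.00  1.000    0.9882   no
SSxWP          1.114    5.00    55.00  0.586    0.3639   no
LCxWP          3.106    2.74    30.12  0.548    0.0451  yes  *
SSxLCxWP       1.000    2.50    27.47  0.499    0.3959  yes
```

The injected load (LC) and posture (WP) effects are detected with large
F statistics while the deliberately small surface effect (SS) is not;
WP's degrees of freedom have been Greenhouse–Geisser-adjusted (ε=0.59)
because its six levels violated sphericity.

Classification on the same study (pelvis sensor, subjective labels):

```python
report = sl.ClassificationGrid(study, sensor_configs=("pelvis",),
                               feature_sets=("FS1",),
                               classifiers=("LogisticRegression",
                                            "DiscriminantAnalysis",
                                            "BaggedTrees"),
                               criterion="pps").fit(seed=42)
print(report.summary())
```

```
Classification accuracies (%) — labeling by pps
SC                   pelvis
FS                      FS1
LogisticRegression     86.1
DiscriminantAnalysis   83.9
BaggedTrees            83.0
Maximum                86.1
Average                84.3
```

A command-line interface mirrors the library:

```bash
swaylab simulate --seed 17 --out study/
swaylab measures --in study/ --sensors pelvis,lower_leg_L --out measures.csv
swaylab effects  --measures measures.csv --out effects/
swaylab classify --data study/ --criterion copv_ap --out report/
swaylab pipeline --seed 17 --out run/
```

## Layout

```
src/swaylab/
  design.py         # factorial design, sensor placements
  config.py         # StudyConfig / EffectParams / PipelineConfig (+ YAML)
  simulate.py       # synthetic study generator
  preprocessing.py  # zero-phase Butterworth, detrending, directions
  measures.py       # the 43 sway measures + COPV_AP
  effects.py        # RM-ANOVA, Mauchly, Greenhouse-Geisser, t-tests
  classify.py       # features, labels, CV, classifier roster, grid
  io.py             # CSV/YAML study format
  pipeline.py       # end-to-end orchestration + manifest
  cli.py            # `swaylab` command
docs/methods.md     # modelling and design notes
```
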