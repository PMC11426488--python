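# plumekin

Peri-encounter analysis of head motion and heading for odor-plume tracking
in freely moving rodents.

A mouse localizing an airborne odor source receives information in brief,
unpredictable filament encounters. With a head-mounted metal-oxide gas
sensor those encounters can be timestamped in a freely moving animal, and a
head-mounted accelerometer plus overhead keypoint tracking reveal what the
animal does around each contact: how vigorously it pitches its head (the
5–14 Hz "active search" band), whether it raises or lowers its head, and
how its body and head angles relative to the source evolve. `plumekin`
implements that full analysis as a reusable, tested pipeline:

* **plume events** — low-pass filtering, difference-of-exponentials
  deconvolution (τ_rise = 0.02 s, τ_decay = 10 s), and change detection on
  the cumulative sum: an event is declared where the ratio of forward to
  reverse 1-s least-squares slopes exceeds a threshold calibrated on blank
  recordings; events closer than 5 s to the previous kept event, closer
  than 15 px to the source, or too close to the recording edge are
  filtered out.
* **head motion** — calibration to g, 20 Hz low-pass, differentiation to
  jerk, analytic Morlet wavelet power in the 5–14 Hz band with per-sample
  dominant frequency, and head-raised/lowered classification from a
  three-Gaussian mixture fit (BIC-checked) to the Z−X moving-median signal,
  thresholded at mean − SD of the highest-mean component.
* **kinematics** — likelihood-masked keypoints to signed body angle
  (0° = aimed at the port; clockwise-on-screen positive), egocentric head
  yaw (left positive), speed, and yaw 0°-crossing times.
* **peri-event statistics** — ±5 s windows around real events vs.
  surrogate windows drawn uniformly from in-arena time (excluding ±1 s
  around real onsets, one surrogate per event per trial); per-trajectory
  1-s-bin means compared by two-sample Kolmogorov–Smirnov per bin; circular
  mean/resultant strength R with paired Wilcoxon signed-rank tests on
  before/after R; z-scored rolling 0°-crossing rates.
* **synthetic world** — a generator producing all four data streams with
  exact ground-truth encounter times and injected peri-encounter
  modulations (or a pure null), used throughout the test suite.

See `docs/methods.md` for the model details, parameter defaults with units,
and what the synthetic world does and does not emulate.

## Worked example

Generate a small synthetic cohort with injected modulations, detect
encounters, and run the peri-event statistics:

```bash
plumekin run-all --out demo --trials 10 --seed 7
```

or, from Python:

```python
import numpy as np
from plumekin.config import AnalysisConfig
from plumekin.synthetic import GroundTruth, gen_cohort
from plumekin import pipeline

cfg = AnalysisConfig()
cohort = gen_cohort(cfg, GroundTruth(), n_trials=20, seed=7)
res = pipeline.analyze_cohort(cohort, cfg, seed=1)

bp = res.bin_tables["band_power"]
for lab, p in zip(bp.labels, bp.p_value):
    print(f"{lab:>10}: p = {p:.3g}")
print("paired R:", res.body_angle_R.p_value)
```

A typical run (the numbers below are from `scripts/acceptance.py --seed 1`)
prints:

```
calibrated slope-ratio threshold: 1.0730
modulated cohort: 20 trials, 115 events
  band power [-1,0): p=3.58e-38 (real 12.3 vs random 6.6)
  band power [0,1):  p=5.14e-34 (real 3.89 vs random 6.66)
  body-angle paired R: p=1.87e-20 (R before 0.840, after 0.971)
null cohort: 54 events, 5/40 bins significant at 0.05
```

Reading this: the detector threshold is set so blank recordings yield at
most 0.1 false events per minute. In the modulated cohort, head-pitch band
power in the second *before* an encounter is roughly double the surrogate
level (the injected pre-encounter amplitude boost) and suppressed in the
second *after* (the injected drop), both overwhelmingly significant across
115 events. The resultant-vector strength of the body angle rises from 0.84
to 0.97 after encounters — heading variability collapses on contact. In the
null cohort no modulation is injected and the per-bin significance count
(5 of 40 bins at α = 0.05) is at chance level.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end-to-end from scratch: it calibrates the detector
threshold on freshly generated blank recordings, generates a modulated and
a null synthetic cohort from the given seed, runs detection, head-motion,
kinematics, and the peri-event statistics on both, prints the summary
above, and writes its JSON result to `--out`.

## Layout

```
src/plumekin/
  config.py      AnalysisConfig (YAML-backed; every numeric knob)
  timeseries.py  TimeSeries / KeypointTrack / TrialRecord + CSV IO
  synthetic.py   ground-truth trial generator
  plume.py       deconvolution + slope-ratio event detection
  headmotion.py  jerk, wavelet band power, head-state GMM
  kinematics.py  angles, speed, zero crossings
  perievent.py   windows, surrogates, KS / circular / crossing-rate stats
  pipeline.py    per-trial and cohort orchestration
  cli.py         `plumekin` command line
```
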