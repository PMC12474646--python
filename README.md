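# mitovo2 — automated mitochondrial oxygen consumption analysis

`mitovo2` analyzes in-vivo mitochondrial oximetry sessions: 1-Hz mitoPO₂
traces (mmHg) recorded in skin by protoporphyrin-IX delayed-fluorescence
monitors. During a *stop-flow* measurement, local probe pressure occludes the
microcirculation and mitoPO₂ falls at the oxygen disappearance rate; the
maximal oxygen consumption **V_max** of that decay is the measurement's
mitoVO₂. The package is for researchers who want these analyses to be
reproducible and free of the inter-rater variability that comes from manually
picking measurement start points.

The pipeline has two steps:

1. **Start-point detection.** A bidirectional LSTM labels every sample of a
   z-scored trace as `start`, `measurement` or `na` (trained on overlapping
   250-sample windows with 240-sample overlap), and a deterministic rule
   engine cleans the labels so that only sustained, artifact-free drops count:
   starts > 30 s apart, start mitoPO₂ > 20 mmHg, start on the local maximum,
   duration > 10 s, no rise in the first 3 s, minimum below 20 mmHg, no
   \> 50 mmHg first-second cliff.
2. **Kinetic fitting.** Each surviving segment is fit by nonlinear least
   squares to a Michaelis–Menten decay with diffusive oxygen influx,

   dPO₂/dt = −V₀·Pₙ / (P₅₀ + Pₙ) + Z·(P₀ − Pₙ),

   integrated with 4th-order Runge–Kutta. V_max is the steepest tangent of
   the fitted curve; a subject's mitoVO₂ is the mean V_max over its
   converged measurements.

Clinical recordings are not redistributable, so a synthetic-session generator
(`mitovo2.synthetic`) produces labeled COMET-style cohorts — baseline
plateaus, model-driven stop-flow decays, exponential reoxygenation, sensor
noise — with full ground truth, and the whole pipeline is validated against
it.

## Worked example

```python
import numpy as np
from mitovo2 import (BiLstmSegmenter, CohortConfig, generate_cohort,
                     analyze_trace, match_starts)

# 1. simulate a training cohort and train the detector (tuned defaults:
#    55 hidden units, learn rate 0.0137, 3 epochs, mini-batch 80)
cohort = generate_cohort(CohortConfig(n_subjects=20, seed=7))
model = BiLstmSegmenter(seed=0).fit([c[0] for c in cohort],
                                    [c[1] for c in cohort])

# 2. analyze an unseen subject
trace, _, truth = generate_cohort(CohortConfig(n_subjects=1, seed=99))[0]
result = analyze_trace(model, trace)
print(f"{len(result.segments)} measurements detected ({len(truth)} simulated)")
for seg, fit in zip(result.segments, result.fits):
    print(f"  start {seg.start_index:4d}  V_max {fit.vmax:5.2f} mmHg/s")
print(f"subject mitoVO2 = {result.mitovo2:.2f} mmHg/s")

rep = match_starts([g.start_index for g in truth],
                   [s.start_index for s in result.segments])
print(f"start-point recall within +/-5 samples: {rep.acc5:.2f}")
```

prints (training takes about half a minute on one CPU):

```
8 measurements detected (8 simulated)
  start   62  V_max  5.95 mmHg/s
  start  181  V_max  8.78 mmHg/s
  start  282  V_max  5.70 mmHg/s
  start  399  V_max 12.49 mmHg/s
  start  523  V_max 13.43 mmHg/s
  start  638  V_max  8.60 mmHg/s
  start  771  V_max 12.00 mmHg/s
  start  875  V_max 10.28 mmHg/s
subject mitoVO2 = 9.65 mmHg/s
start-point recall within +/-5 samples: 1.00
```

Every simulated measurement is recovered within ±5 samples of its true
onset, and the per-measurement V_max values are the steepest tangents of the
fitted decay curves (the subject's true mean V_max here is 10.35 mmHg/s).

A `mitovo2` console script exposes the same steps from the shell
(`simulate`, `train`, `tune`, `detect`, `postprocess`, `fit`, `run`,
`validate`); file formats are two-column CSV for traces
(`sample_time_s,mitopo2_mmhg`) and labels (`sample_time_s,label` with
labels `na`/`start`/`measurement`), and JSON for results. See
`mitovo2 --help`.

## Agreement statistics

`mitovo2.validation` implements the comparison toolkit used to judge the
pipeline: one-to-one start-point matching within ±5 samples with accuracies
at offsets 0/1/3/5, Bland–Altman bias with t-based 95% CI and 1.96·SD limits
of agreement, an extended (variance-components) LoA for subjects with
repeated, unbalanced measurement counts, and the comparability decision
(bias CI inside a predefined ±0.3 mmHg·s⁻¹ margin).

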