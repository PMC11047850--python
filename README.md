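# segrelearn

Who will benefit most from motor-skill training?  In Parkinson's disease,
handwriting often shrinks (micrographia) and intensive writing training can
restore it — but learning gains vary widely between patients.  `segrelearn`
implements, end to end, the analysis pipeline used to predict long-term
writing-skill learning from resting-state brain-network segregation and
clinical measures, for researchers who want to run, audit or extend that
analysis on their own cohorts, and for methodologists who want every stage
verifiable against planted ground truth.

The pipeline has four analytic stages, each usable as a library module or a
CLI subcommand, plus a synthetic-cohort generator that makes all of them
testable without patient data:

1. **Connectivity / segregation** (`segrelearn.connectivity`) — framewise
   displacement (Power convention, 50 mm rotation sphere), scrubbing at
   FD > 0.5 mm or BOLD change above the Tukey fence Q3 + 1.5·IQR, exclusion
   of subjects with > 108 scrubbed volumes (TR 1.7 s ⇒ ≥ ~4 min retained),
   Fisher-z ROI connectivity, network-sorted averaging with negative edges
   excluded, and per-network segregation

       S_k = (W_k − B_k) / W_k

   where `W_k`/`B_k` are mean within-/between-network Fisher-z connectivity.
2. **Writing kinematics** (`segrelearn.writing`) — 7 Hz zero-phase 4th-order
   Butterworth filtering of 200 Hz pen trajectories, stroke extraction from
   alternating vertical extrema, and four trial outcomes: amplitude (% of
   target), COVampl, speed (cm/s), and Deviation = |100 − amplitude|.
3. **Composite learning scores** (`segrelearn.scores`) — correlation-matrix
   PCA of the four outcomes, components retained to > 80% cumulative
   variance, varimax rotation, regression component scores, single/dual-task
   averaging, and the three endpoints acquisition (post − pre), retention
   (follow-up − post) and overall learning (follow-up − pre).
4. **Inference** (`segrelearn.inference`) — repeated-measures ANOVA over
   timepoints with Bonferroni pairwise tests; Pearson and partial
   correlations (controlling baseline accuracy) with bias-corrected and
   accelerated (BCa) 95% bootstrap CIs from 1000 case resamples, significance
   decided by the CI excluding 0; and a backward-elimination OLS model
   (retain at p < 0.1) with BCa CIs on standardised betas.

`segrelearn.synthetic` generates every input with known population
parameters: block-covariance Gaussian ROI timeseries, spiked motion traces,
loop-writing trajectories with planted per-stroke amplitudes, and subject
panels drawn from a planted covariance among predictors, baseline scores and
gains.  See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a cohort (28 clean subjects plus 4 heavy movers that QC excludes)
and run every stage:

```
segrelearn run-all --out run/ --seed 17
```

which ends by printing `run/summary.txt`:

```
segrelearn run summary
======================
subjects simulated: 32; passing QC: 28

Component model (varimax-rotated loadings):
               accuracy  speed
amplitude_pct     0.990 -0.011
cov_ampl_pct     -0.952 -0.021
speed_cm_s        0.021  1.000
deviation_pct    -0.986  0.006
explained variance (%): [71.5, 25.0] (cumulative 96.5)

RM-ANOVA on accuracy composite: F(2,54) = 23.05, p = 0.0000, partial eta^2 = 0.46

Significant associations (BCa 95% CI excludes 0):
   endpoint        predictor    kind      r  ci_lo  ci_hi
acquisition         baseline pearson -0.568 -0.789 -0.236
acquisition              sex partial  0.642  0.378  0.819
  retention              sex partial -0.400 -0.639 -0.007
    overall         baseline pearson -0.543 -0.781 -0.110
    overall              sex partial  0.450  0.072  0.705
    overall seg_sensorimotor partial  0.562  0.280  0.802

Final multivariable model (overall learning):
  retained: ['baseline', 'sex', 'seg_sensorimotor']
  betas: {'baseline': -0.605, 'sex': 0.302, 'seg_sensorimotor': 0.422}
  adjusted R^2 = 0.556 (p = 4.566e-05)
```

Reading the output: the PCA separates an *accuracy* component (amplitude
positive, Deviation and amplitude variability negative — higher = more
accurate writing) from a *speed* component.  Accuracy improves over the
three timepoints (the ANOVA), subjects with more room to improve gain more
(negative baseline correlations), and after controlling baseline accuracy,
female sex and sensorimotor-network segregation predict overall learning —
the backward model retains exactly baseline accuracy, sex and sensorimotor
segregation.  These are recoveries of the effect sizes planted in the
synthetic cohort (e.g. the planted segregation partial correlation is 0.57;
the estimate from 256-volume scans is attenuated toward 0.56 here by
segregation measurement noise), so the run doubles as a full-pipeline
integrity check.

Each stage can also be run alone (`segrelearn simulate | segregation |
writing | compose | infer`); `examples/demo.yaml` shows the full config
surface, and every output directory contains a `manifest.json` from which
all numbers are reproducible.

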