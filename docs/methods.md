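# Methods

`segrelearn` implements, as a reusable and fully testable pipeline, the
analysis chain used to ask whether resting-state brain-network segregation and
clinical measures predict long-term learning of writing skills in Parkinson's
disease: ROI-timeseries quality control and segregation scoring, writing-tablet
kinematics, PCA composite learning scores, and small-sample bootstrap
inference.  Because the subject-level data of the motivating study are not
publicly released, every stage is paired with a synthetic generator that
plants known population parameters, so correctness is established by oracle
identities and parameter recovery rather than by re-reading a fixed dataset.

## 1. Network segregation

**Scrubbing and QC.**  Framewise displacement (FD) is the sum of absolute
backward differences of the six realignment parameters, with the three
rotations converted to arc length on a 50 mm sphere — the Power convention,
adopted because the scrubbing literature's FD is otherwise underspecified.
A volume is scrubbed when FD > 0.5 mm or when the mean BOLD signal change
exceeds the one-sided Tukey fence Q3 + 1.5·IQR of the full series (the
standard boxplot outlier rule).  A subject fails QC when strictly more than
108 volumes are scrubbed; at TR = 1.7 s this corresponds to requiring at
least about 4 minutes of retained data.  Scrubbed volumes are deleted before
correlation (not interpolated), matching the behaviour of scrubbing with
dummy regressors for correlation estimates.

**Connectivity and segregation.**  Pairwise Pearson correlations of the
retained ROI timeseries are Fisher-transformed, z = atanh(r).  Negative
edges are excluded at averaging time — dropped from each cell's mean rather
than zeroed, since zeroing would bias means toward 0.  For a partition of
ROIs into K networks, within-network connectivity W_k is the mean z over
network k's internal edges and between-network connectivity B_k pools all
edges from network k to every other network (edge-weighted).  Segregation is

    S_k = (W_k − B_k) / W_k ,

defined only for W_k > 0; higher values indicate a more modular network.
An alternative reading of B_k — the unweighted mean of the K−1 network-pair
means — is exposed as `between="pair_means"`; the two coincide exactly for
equal-size networks, which is why the toy partitions used in testing cannot
distinguish them.

For timeseries generated with uniform within-block correlation w and
between-block correlation b, the population limit of S is
(atanh(w) − atanh(b)) / atanh(w); the recovery tests check convergence to
this closed form (e.g. 0.7075 for w = 0.6, b = 0.2).

## 2. Writing kinematics

Trials are 27 s loop-writing traces sampled at 200 Hz with a target height
of 0.6 or 1.0 cm (the analysis uses the 1.0 cm size).  Traces are low-pass
filtered at 7 Hz with a 4th-order Butterworth filter applied forward and
backward (zero phase), preserving the timing of extrema; the filter's phase
handling is a package choice, made because stroke boundaries are defined by
extrema locations.  Strokes are segments between alternating local extrema
of the vertical coordinate; extrema with prominence below 5% of the target
size are treated as noise (configurable), and the partial segments before
the first and after the last extremum are discarded because incomplete loops
bias amplitude.  Four outcomes summarise a trial:

* amplitude = 100 · mean stroke height / target (in % of target),
* COVampl = 100 · sd(heights) / mean(heights), with the n−1 denominator,
* speed = path length / duration (cm/s),
* Deviation = |100 − amplitude|, the accuracy outcome.

Outcomes are averaged, unweighted, over the three runs of each
subject × timepoint × condition cell.

## 3. Composite learning scores

A correlation-matrix PCA is fitted over all subject × timepoint × condition
rows of the four outcomes (columns standardised pooled over rows; the
outcomes have incommensurate units).  Components are retained until
cumulative explained variance exceeds 80%, then varimax-rotated (Kaiser row
normalisation, tolerance 1e-8, at most 500 sweeps).  Scores use the
regression (Thompson) estimator W = R⁻¹Λ, which for PCA loadings yields
exactly unit-variance, uncorrelated scores over the fitting rows.  The
component on which Deviation loads most heavily is labelled *accuracy* and
oriented so Deviation loads negatively; the speed component is oriented so
speed loads positively — a higher score therefore always means more accurate
or faster writing, and the convention is deterministic under row
permutation.  Reported explained-variance percentages are the unrotated
eigenvalue shares (the retention rule and the cumulative total are
eigenvalue-based); rotated sums of squared loadings are also stored on the
model object, and an orthogonal rotation conserves their total.

Accuracy scores are averaged over the single- and dual-task conditions
within each timepoint, and difference scores define the three endpoints:
acquisition = post − pre, retention = followup − post, overall =
followup − pre, so acquisition + retention = overall exactly.

## 4. Inference

All variables are demeaned and scaled to unit variance (n−1 denominator)
before modelling; binary predictors are coded 0/1 and standardised the same
way.  Every estimate carries a bias-corrected and accelerated (BCa) 95%
bootstrap confidence interval from 1000 case resamples (the resampling unit
is always the subject row — a model-based residual bootstrap is deliberately
not used at n = 28), and significance is decided by whether the interval
excludes zero; original-sample p values (t distributions) are reported for
transparency.  The BCa bias term is z₀ = Φ⁻¹ of the fraction of bootstrap
replicates below the observed statistic and the acceleration comes from
jackknife skewness; with z₀ = a = 0 the interval reduces exactly to the
percentile interval.  A resample on which a statistic is undefined (e.g. a
single-class draw of a binary variable) is redrawn and counted.  Bootstrap
streams are spawned deterministically from one master seed.

Partial correlations use the residual method (identical to the closed-form
three-variable formula to machine precision) with n − 2 − k degrees of
freedom.  Improvement over timepoints is tested with a one-way
within-subject ANOVA (statsmodels AnovaRM; partial η² = F·df1/(F·df1+df2),
exact for the one-way design; sphericity left unadjusted) with
Bonferroni-corrected paired t-tests.  The multivariable model is ordinary
least squares with backward elimination at p < 0.1: the candidate set is the
CI-significant overall-learning predictors plus baseline accuracy, the
largest-p predictor is removed until all survive, and beta CIs are BCa over
case resamples refitting the *final* model (bootstrapping the selection path
itself is not implied by a reported final model and would mix model
uncertainty into coefficient uncertainty).  No multiplicity correction is
applied across the association grid; Bonferroni is reserved for the ANOVA
contrasts.  Retention's partial correlations control pre-training (not
post-training) accuracy, the natural reading of "baseline".

## 5. Synthetic generators: what they emulate, and what they do not

**ROI timeseries** are zero-mean Gaussians with an exact block correlation
matrix (within-r per network, between-r per pair), checked for positive
definiteness before Cholesky sampling.  They emulate *denoised* resting-state
data entering connectivity estimation; they contain no hemodynamics,
autocorrelation, physiological noise or spatial structure, so passing
recovery tests demonstrates correctness of the estimator chain, not
robustness to realistic fMRI artefacts.

**Motion traces** are white Gaussian jitter (0.01 mm) plus step displacements
at chosen volumes, giving exact control over which volumes trip the FD rule.

**Writing trials** chain half-cosine strokes between planted alternating
extrema, so the realised inter-extremum heights *are* the stored i.i.d.
ground-truth amplitudes h_k = target·(bias/100)·(1 + cv/100·ε_k) — a
construction chosen because a sinusoid with per-half-cycle scaling would
make measured heights averages of adjacent draws and shrink the recoverable
CV by ~1/√2.  Horizontal drift is solved (bisection) so the mean path speed
matches the requested value; digitiser noise (sd 0.005 cm, cf. the tablet's
32.5 µm resolution) is added above the filter's passband.  Letterforms, pen
pressure and within-stroke speed modulation are not modelled.

**Subject panels** are drawn from a single planted covariance over latent
Gaussian variables; binary predictors (female sex, prevalence 11/28; freedom
from gait freezing, 15/28) are produced by thresholding, so planted
correlations involving them live on the latent (biserial) scale.  The
conversion r_latent = r_observed / [φ(τ)/√(p(1−p))] makes the *observed*
point-biserial correlations hit their targets.  The default
`learning_panel_spec` solves, at run time, for the three predictor
intercorrelations that make the planted standardised betas (−0.51, 0.42,
0.49 for baseline, sex, sensorimotor segregation), the marginal
baseline–gain correlations (−0.49 acquisition, −0.39 overall, 0.34
retention) and the baseline-controlled partials (0.57 segregation, 0.51 sex,
plus 0.43/0.31 for acquisition) hold simultaneously; the timepoint-score
correlations follow from corr(pre, gain) = −√((1−ρ)/2) for unit-variance
scores.  This system is exactly solvable, and it implies an
acquisition–retention correlation of −0.61 and a population model R² of
0.60 (adjusted-R² expectation ≈ 0.60 across replicates, with single-sample
values scattering with an SD near 0.06) — useful internal-consistency
checks that the recovery tests exploit.  Three null predictors (age, LEDD,
MoCA) are independent of everything and exist to exercise backward
elimination.

**Planted-factor outcomes** for the component-recovery tests are linear
mixtures of two orthogonal latent factors plus unique noise, with a
simple-structure loading matrix solved numerically so the implied
correlation matrix has top-two eigenvalue shares of exactly 57.4% and 29.5%
(cumulative 86.9%).

## 6. Numerical choices and degenerate inputs

* Quartiles use linear-interpolation percentiles (NumPy default).
* atanh overflows are prevented by rejecting |r| ≥ 1 − 1e-12 between
  distinct ROIs and excluding the diagonal before transformation.
* Eigenvector signs are fixed (largest-magnitude element positive) before
  rotation so varimax input, and hence scores, are reproducible.
* Score weights use a pseudoinverse so exact low-rank outcome tables (an
  outcome set that is a perfect linear image of fewer factors) still score.
* A network cell with no surviving non-negative edges is flagged NaN with a
  warning; segregation raises for W_k ≤ 0 where the ratio is meaningless.
* Degenerate bootstrap distributions collapse the CI to a point with a
  warning rather than failing.
* Pipeline sizes default to 28 QC-passing + 4 QC-failing subjects, 256
  volumes at TR 1.7 s, a 72-ROI / 12-network toy partition (Cole-Anticevic
  network names), 18 trials per subject, and 1000 bootstrap resamples; the
  bundled demo completes in well under five minutes on one CPU.  Writing
  simulation maps a subject's latent accuracy score s to an amplitude bias
  of 85 + 6s % (baseline micrographia around 85% of target, improving with
  training) and COVampl around 10 − 1.5s %, with a dual-task penalty of 2
  amplitude points; mean path speed is 2.0 cm/s ± 0.25 per SD of a latent
  speed trait, floored above the vertical-only minimum implied by the
  stroke rate (1.5 strokes/s).

## 7. Known limitations

* BCa intervals undercover for heavily skewed statistics at n = 28 (~87–88%
  empirical coverage for a lognormal(0,1) mean — a property of the BCa
  method itself, reproduced identically by scipy's implementation, not of
  this package); coverage is within the nominal band for moderate skew.
* The segregation estimate from 256 volumes is noisy; in the end-to-end
  demo this attenuates the estimated-segregation association relative to
  the planted latent one, exactly as measurement error would in real data.
* Backward elimination at a liberal p < 0.1 on 28 cases is optimistic by
  construction; the pipeline reports the elimination trace so that
  instability across resamples is visible, but no cross-validated error is
  computed.
* The generators make no attempt at realistic fMRI noise spectra, letterform
  geometry, or non-Gaussian clinical distributions; recovery results
  validate the estimators, not the field robustness of the measures.
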