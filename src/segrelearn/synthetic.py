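"""Synthetic inputs with known ground truth for every pipeline stage.

The study this pipeline emulates (28 people with Parkinson's disease, a
6-week writing-training program, resting-state fMRI at baseline) did not
release subject-level data, so every stage is made verifiable by generating
its inputs with planted population parameters:

* block-covariance Gaussian ROI timeseries with known within/between-network
  correlations (segregation recovery),
* realignment-parameter traces with injected motion spikes (scrubbing/QC),
* loop-writing pen trajectories with controlled amplitude bias, amplitude
  variability and speed (kinematics recovery),
* subject panels drawn from a planted covariance among clinical predictors,
  baseline writing scores and learning gains (inference recovery).

Binary predictors (sex, freezing of gait) are produced by thresholding a
latent Gaussian at the stated prevalence, so planted correlations involving
them live on the latent (biserial) scale; :func:`latent_r` converts an
observable point-biserial correlation to the latent value that produces it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .partition import PartitionTable
from .writing import WritingTrial

# ---------------------------------------------------------------------------
# ROI timeseries
# ---------------------------------------------------------------------------


@dataclass
class ConnectivitySpec:
    """Target block-correlation structure for simulated ROI timeseries.

    ``within_r`` may be a scalar (all networks) or a mapping network -> r;
    ``between_r`` a scalar or mapping of frozenset pairs -> r.
    """

    within_r: object = 0.5
    between_r: object = 0.15
    n_volumes: int = 256
    tr_s: float = 1.7

    def __post_init__(self):
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.n_volumes < 3:
            raise ValueError("n_volumes < 3 gives rank-deficient correlations")

    def _within(self, network) -> float:
        r = self.within_r[network] if isinstance(self.within_r, dict) else self.within_r
        if not -1 < r < 1:
            raise ValueError(f"within_r for {network!r} outside (-1, 1)")
        return float(r)

    def _between(self, a, b) -> float:
        if isinstance(self.between_r, dict):
            r = self.between_r[frozenset((a, b))]
        else:
            r = self.between_r
        if not -1 < r < 1:
            raise ValueError(f"between_r for ({a!r}, {b!r}) outside (-1, 1)")
        return float(r)

    def correlation_matrix(self, partition: PartitionTable) -> np.ndarray:
        """The implied population ROI correlation matrix (checked positive definite)."""
        p = partition.n_rois
        c = np.empty((p, p))
        names = partition.network_names
        idx = {n: partition.indices(n) for n in names}
        for i, a in enumerate(names):
            c[np.ix_(idx[a], idx[a])] = self._within(a)
            for b in names[i + 1:]:
                r = self._between(a, b)
                c[np.ix_(idx[a], idx[b])] = r
                c[np.ix_(idx[b], idx[a])] = r
        np.fill_diagonal(c, 1.0)
        lam_min = np.linalg.eigvalsh(c).min()
        if lam_min <= 1e-10:
            raise ValueError(
                f"implied block correlation is not positive definite "
                f"(smallest eigenvalue {lam_min:.3e})")
        return c


def gen_roi_timeseries(partition: PartitionTable, spec: ConnectivitySpec,
                       seed: int) -> np.ndarray:
    """Zero-mean Gaussian (n_volumes x n_rois) with the spec's block correlation."""
    c = spec.correlation_matrix(partition)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(c)
    return rng.standard_normal((spec.n_volumes, partition.n_rois)) @ chol.T


# ---------------------------------------------------------------------------
# Motion traces
# ---------------------------------------------------------------------------


def gen_motion_trace(n_volumes: int, spike_indices=(), spike_mm: float = 1.0,
                     seed: int = 0, jitter_mm: float = 0.01) -> np.ndarray:
    """Six realignment parameters (3 translations mm, 3 rotations rad).

    Small white Gaussian jitter plus step displacements of ``spike_mm`` on the
    first translation axis at ``spike_indices`` (a step at volume i produces a
    framewise-displacement spike at exactly volume i).
    """
    if n_volumes < 0:
        raise ValueError("n_volumes must be non-negative")
    spike_indices = np.asarray(spike_indices, dtype=int)
    if spike_indices.size and spike_indices.max() >= n_volumes:
        raise ValueError("spike index beyond n_volumes")
    rng = np.random.default_rng(seed)
    trace = np.empty((n_volumes, 6))
    trace[:, :3] = rng.normal(0, jitter_mm, (n_volumes, 3))
    trace[:, 3:] = rng.normal(0, jitter_mm / 50.0, (n_volumes, 3))
    for i in spike_indices:
        trace[i:, 0] += spike_mm
    return trace


def gen_bold_change(n_volumes: int, outlier_indices=(), outlier_scale: float = 6.0,
                    seed: int = 0) -> np.ndarray:
    """Mean BOLD signal-change series (a.u.): |N(0,1)| noise plus planted outliers."""
    rng = np.random.default_rng(seed)
    b = np.abs(rng.normal(0, 1, n_volumes))
    for i in np.asarray(outlier_indices, dtype=int):
        b[i] += outlier_scale
    return b


# ---------------------------------------------------------------------------
# Writing trials
# ---------------------------------------------------------------------------


def gen_writing_trial(target_cm: float = 1.0, amplitude_bias_pct: float = 100.0,
                      amp_cv_pct: float = 10.0, speed_cm_s: float = 2.0,
                      duration_s: float = 27.0, fs_hz: float = 200.0,
                      seed: int = 0, strokes_per_s: float = 1.5,
                      noise_cm: float = 0.005, **meta) -> WritingTrial:
    """Quasi-sinusoidal loop-writing trace with planted per-stroke amplitudes.

    Each stroke is a half-cosine vertical segment between consecutive planted
    extrema, so the realised inter-extremum heights equal the i.i.d. draws

        h_k = target_cm * (bias/100) * (1 + cv/100 * eps_k),  eps_k ~ N(0,1)

    stored on the returned trial as ``stroke_heights_cm`` (the recovery
    ground truth).  Horizontal progression is a constant drift solved so the
    mean path speed matches ``speed_cm_s``.  High-frequency positional noise
    of sd ``noise_cm`` emulates digitiser error and is removed by the 7 Hz
    filter downstream.
    """
    if target_cm <= 0:
        raise ValueError("target size must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if fs_hz <= 14:
        raise ValueError("sampling rate must exceed twice the 7 Hz filter cutoff")
    rng = np.random.default_rng(seed)
    n_strokes = max(2, int(round(duration_s * strokes_per_s)))
    mean_h = target_cm * amplitude_bias_pct / 100.0
    heights = mean_h * (1.0 + (amp_cv_pct / 100.0) * rng.standard_normal(n_strokes))
    heights = np.clip(heights, 0.05 * mean_h, None)  # keep strokes detectable

    # alternating extrema levels: e_0 = 0, e_{k+1} = e_k -/+ h_k
    sign = 1.0
    levels = [0.0]
    for h in heights:
        levels.append(levels[-1] + sign * h)
        sign = -sign
    levels = np.asarray(levels)

    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    # stroke k occupies [k, k+1) / strokes-per-trial of the trial
    phase = t / duration_s * n_strokes
    k = np.minimum(phase.astype(int), n_strokes - 1)
    s = phase - k
    y = levels[k] + (levels[k + 1] - levels[k]) * (1 - np.cos(np.pi * s)) / 2

    # solve horizontal drift speed so mean path speed ~ speed_cm_s
    dy = np.diff(y)
    dt = 1.0 / fs_hz

    def mean_speed(vx):
        return np.sum(np.hypot(vx * dt, dy)) / (t[-1] - t[0])

    v_vertical = mean_speed(0.0)
    if speed_cm_s <= v_vertical:
        raise ValueError(
            f"requested speed {speed_cm_s:.2f} cm/s below the vertical-only "
            f"path speed {v_vertical:.2f} cm/s")
    vx = optimize.brentq(lambda v: mean_speed(v) - speed_cm_s, 0.0,
                         2.0 * speed_cm_s + 1.0)
    x = vx * t

    if noise_cm > 0:
        x = x + rng.normal(0, noise_cm, n)
        y = y + rng.normal(0, noise_cm, n)
    trial = WritingTrial(t, x, y, target_cm=target_cm, **meta)
    trial.stroke_heights_cm = heights  # ground truth for recovery tests
    return trial


# ---------------------------------------------------------------------------
# Subject panels
# ---------------------------------------------------------------------------


def biserial_factor(prevalence: float) -> float:
    """Attenuation phi(tau)/sqrt(p(1-p)) of a correlation when one normal
    variable is dichotomised at prevalence p."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    tau = stats.norm.ppf(1 - prevalence)
    return stats.norm.pdf(tau) / np.sqrt(prevalence * (1 - prevalence))


def latent_r(observed_r: float, prevalence: float) -> float:
    """Latent-scale correlation that yields ``observed_r`` after dichotomisation."""
    return observed_r / biserial_factor(prevalence)


@dataclass
class PanelSpec:
    """Planted population for a subject panel.

    ``target_covariance`` is the latent-scale covariance (unit variances) over
    ``variable_names``; ``binary_vars`` maps a variable to its prevalence
    P(var = 1), realised by thresholding the latent Gaussian; ``means`` shifts
    continuous variables after sampling.
    """

    n_subjects: int
    variable_names: tuple
    target_covariance: np.ndarray
    binary_vars: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)

    def __post_init__(self):
        self.variable_names = tuple(self.variable_names)
        c = np.asarray(self.target_covariance, dtype=float)
        if c.shape != (len(self.variable_names),) * 2:
            raise ValueError("covariance shape does not match variable_names")
        if not np.allclose(c, c.T):
            raise ValueError("target covariance must be symmetric")
        lam = np.linalg.eigvalsh(c).min()
        if lam < -1e-10:
            raise ValueError(f"target covariance not PSD (eigenvalue {lam:.3e})")
        for v, p in self.binary_vars.items():
            if v not in self.variable_names:
                raise ValueError(f"binary variable {v!r} not in variable_names")
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {v!r} must be in (0, 1)")
        self.target_covariance = c


def gen_subject_panel(spec: PanelSpec, seed: int) -> pd.DataFrame:
    """Draw a subject panel from the planted covariance.

    Binary columns are 1 when the latent Gaussian exceeds its prevalence
    threshold (so positive latent correlations give positive observed ones).
    """
    rng = np.random.default_rng(seed)
    c = spec.target_covariance
    # allow PSD-but-singular covariances via eigen square root
    lam, v = np.linalg.eigh(c)
    root = v @ np.diag(np.sqrt(np.clip(lam, 0, None)))
    z = rng.standard_normal((spec.n_subjects, len(spec.variable_names))) @ root.T
    df = pd.DataFrame(z, columns=list(spec.variable_names))
    df.insert(0, "subject", [f"s{i + 1:02d}" for i in range(spec.n_subjects)])
    for var, p in spec.binary_vars.items():
        tau = stats.norm.ppf(1 - p)
        df[var] = (df[var] > tau).astype(int)
    for var, mu in spec.means.items():
        df[var] = df[var] + mu
    return df


# -- the study-condition panel ----------------------------------------------

# reported effect sizes the planted population reproduces (observed scale)
LEARNING_EFFECTS = {
    "betas": {"pre": -0.51, "sex": 0.42, "seg_sensorimotor": 0.49},
    "r_pre_overall": -0.39,
    "r_pre_acquisition": -0.49,
    "r_pre_retention": 0.34,
    "partial_overall": {"sex": 0.51, "seg_sensorimotor": 0.57},
    "partial_acquisition": {"sex": 0.43, "seg_sensorimotor": 0.31},
    "timepoint_means": {"pre": 0.0, "post": 0.66, "followup": 0.44},
    "prevalence": {"sex": 11 / 28, "fog_free": 15 / 28},
}


def _rho_from_gain_corr(r_gain: float) -> float:
    """corr(a, b) of unit-variance scores given corr(a, b - a) = r_gain < 0
    ... inverse of corr(a, b-a) = -sqrt((1-rho)/2)."""
    return 1.0 - 2.0 * r_gain ** 2


@lru_cache(maxsize=None)
def _solve_predictor_block():
    """Intercorrelations (pre-sex, pre-seg, sex-seg, observed scale) solved so
    the planted betas reproduce the reported marginal and partial correlations."""
    b = np.array([LEARNING_EFFECTS["betas"][k] for k in ("pre", "sex", "seg_sensorimotor")])
    r_py = LEARNING_EFFECTS["r_pre_overall"]
    t_sex = LEARNING_EFFECTS["partial_overall"]["sex"]
    t_seg = LEARNING_EFFECTS["partial_overall"]["seg_sensorimotor"]

    def eqs(p):
        r12, r13, r23 = p
        rxx = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]])
        rxy = rxx @ b
        pc_sex = (rxy[1] - r12 * rxy[0]) / np.sqrt((1 - r12 ** 2) * (1 - rxy[0] ** 2))
        pc_seg = (rxy[2] - r13 * rxy[0]) / np.sqrt((1 - r13 ** 2) * (1 - rxy[0] ** 2))
        return [rxy[0] - r_py, pc_sex - t_sex, pc_seg - t_seg]

    sol, info, ier, msg = optimize.fsolve(eqs, [0.05, 0.2, 0.1], full_output=True)
    if ier != 1:
        raise RuntimeError(f"predictor intercorrelation solve failed: {msg}")
    r12, r13, r23 = sol
    rxy = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]]) @ b
    return (r12, r13, r23), rxy


def learning_panel_spec(n_subjects: int = 28) -> PanelSpec:
    """The default study-condition panel: planted effects = the reported ones.

    Variables: pre/post/followup accuracy scores (unit variance, means 0,
    0.66, 0.44), female sex and freedom from gait freezing as latent-threshold
    binaries, sensorimotor segregation (standardised), and three null clinical
    predictors (age, LEDD, MoCA).  All reported effect sizes are planted on
    the observed scale; correlations involving binaries are inflated to the
    latent scale so the observed point-biserial values match.
    """
    eff = LEARNING_EFFECTS
    (r12, r13, r23), rxy = _solve_predictor_block()
    lam_sex = biserial_factor(eff["prevalence"]["sex"])

    rho_pp = _rho_from_gain_corr(eff["r_pre_acquisition"])      # corr(pre, post)
    rho_pf = _rho_from_gain_corr(eff["r_pre_overall"])          # corr(pre, followup)
    sd_acq = np.sqrt(2 * (1 - rho_pp))
    sd_ov = np.sqrt(2 * (1 - rho_pf))
    # corr(post, followup) from corr(pre, followup - post) = r_pre_retention
    sd_ret = (rho_pf - rho_pp) / eff["r_pre_retention"]
    rho_post_f = 1.0 - sd_ret ** 2 / 2.0

    def marginal_from_partial(partial, r_with_pre, r_pre_gain):
        return (partial * np.sqrt((1 - r_with_pre ** 2) * (1 - r_pre_gain ** 2))
                + r_with_pre * r_pre_gain)

    r_sex_acq = marginal_from_partial(eff["partial_acquisition"]["sex"], r12,
                                      eff["r_pre_acquisition"])
    r_seg_acq = marginal_from_partial(eff["partial_acquisition"]["seg_sensorimotor"],
                                      r13, eff["r_pre_acquisition"])

    names = ("pre", "post", "followup", "sex", "seg_sensorimotor",
             "fog_free", "age", "ledd", "moca")
    c = np.eye(len(names))
    ix = {n: i for i, n in enumerate(names)}

    def setc(a, b, v):
        c[ix[a], ix[b]] = c[ix[b], ix[a]] = v

    setc("pre", "post", rho_pp)
    setc("pre", "followup", rho_pf)
    setc("post", "followup", rho_post_f)
    # sensorimotor segregation (continuous, observed = latent)
    setc("pre", "seg_sensorimotor", r13)
    setc("post", "seg_sensorimotor", r13 + r_seg_acq * sd_acq)
    setc("followup", "seg_sensorimotor", r13 + rxy[2] * sd_ov)
    # female sex: observed-scale targets divided by the biserial factor
    setc("pre", "sex", r12 / lam_sex)
    setc("post", "sex", (r12 + r_sex_acq * sd_acq) / lam_sex)
    setc("followup", "sex", (r12 + rxy[1] * sd_ov) / lam_sex)
    setc("sex", "seg_sensorimotor", r23 / lam_sex)

    return PanelSpec(
        n_subjects=n_subjects,
        variable_names=names,
        target_covariance=c,
        binary_vars={"sex": eff["prevalence"]["sex"],
                     "fog_free": eff["prevalence"]["fog_free"]},
        means={"post": eff["timepoint_means"]["post"],
               "followup": eff["timepoint_means"]["followup"]},
    )


# ---------------------------------------------------------------------------
# Planted-factor writing outcomes (component-recovery ground truth)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _solve_outcome_loadings(share1: float, share2: float):
    """Simple-structure 2-factor loading matrix for the four writing outcomes
    whose implied correlation matrix has top-2 eigenvalue shares (%) equal to
    (share1, share2).  Amplitude and deviation load on the accuracy factor,
    amplitude variability on both, speed on the speed factor."""
    lam1, lam2 = 4 * share1 / 100.0, 4 * share2 / 100.0

    def resid(q):
        a, a3, d, b = q
        load = np.array([[a, 0], [a, 0], [a3, d], [0, b]])
        r = load @ load.T + np.diag(1 - (load ** 2).sum(1))
        ev = np.sort(np.linalg.eigvalsh(r))[::-1]
        return [ev[0] - lam1, ev[1] - lam2]

    res = optimize.least_squares(resid, [0.9, 0.7, 0.5, 0.9],
                                 bounds=([0.3, 0.3, 0.05, 0.3],
                                         [0.985, 0.95, 0.8, 0.985]))
    if np.max(np.abs(res.fun)) > 1e-6:
        raise RuntimeError(f"loading solve residual too large: {res.fun}")
    a, a3, d, b = res.x
    return np.array([[a, 0], [a, 0], [a3, d], [0, b]])


OUTCOME_COLUMNS = ("amplitude_pct", "cov_ampl_pct", "speed_cm_s", "deviation_pct")


def gen_outcome_factors(n_rows: int, shares=(57.4, 29.5), seed: int = 0) -> pd.DataFrame:
    """Four standardised writing-outcome columns from two orthogonal latent
    factors (accuracy, speed) plus unique noise, with the factors' population
    eigenvalue shares planted at ``shares`` percent.

    Deviation is the negative image of amplitude's factor contribution (worse
    accuracy = larger deviation), so the fitted accuracy component orients the
    way the composite-score convention expects.
    """
    # solver row order: amplitude, deviation, cov_ampl, speed
    load = _solve_outcome_loadings(*shares)
    # orient: amplitude +accuracy, deviation -accuracy, variability -accuracy
    load = load * np.array([[1, 1], [-1, 1], [-1, 1], [1, 1]], dtype=float)
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n_rows, 2))
    u = rng.standard_normal((n_rows, 4)) * np.sqrt(1 - (load ** 2).sum(1))
    data = f @ load.T + u
    return pd.DataFrame(data[:, [0, 2, 3, 1]], columns=list(OUTCOME_COLUMNS))


# ---------------------------------------------------------------------------
# Run-directory emission
# ---------------------------------------------------------------------------


def write_run(outdir, partition: PartitionTable, panel: pd.DataFrame,
              manifest: dict) -> None:
    """Write a generated cohort to a run directory with a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partition.to_tsv(outdir / "partition.tsv")
    panel.to_csv(outdir / "panel.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
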