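"""End-to-end orchestration: simulate -> segregation -> writing -> compose -> infer.

One :class:`RunConfig` (a flat YAML file) and one master seed drive the whole
run; per-stage random streams are spawned deterministically from the master
seed so stages can be re-run in isolation.  Every stage writes its artifacts
into the run directory together with a manifest recording the full config,
and a human-readable summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, inference, scores, synthetic, writing
from .partition import PartitionTable

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; unknown keys in a config file are rejected."""

    seed: int = 17
    # cohort
    n_subjects: int = 28
    n_qc_fail: int = 4              # extra simulated subjects excluded at QC
    # resting-state simulation + scrubbing
    n_volumes: int = 256
    tr_s: float = 1.7
    fd_thresh_mm: float = 0.5
    max_scrubbed: int = 108
    n_networks: int = 12
    rois_per_network: int = 6
    within_r: float = 0.35
    between_r: float = 0.12
    seg_within_slope: float = 0.04  # within-r shift per SD of planted segregation
    between_mode: str = "pooled"    # or "pair_means"
    # writing simulation + kinematics
    duration_s: float = 27.0
    fs_hz: float = 200.0
    target_cm: float = 1.0
    strokes_per_s: float = 1.5
    base_speed_cm_s: float = 2.0
    cutoff_hz: float = 7.0
    filter_order: int = 4
    prominence_frac: float = 0.05
    # composite scores
    var_threshold: float = 0.80
    # inference
    n_boot: int = 1000
    ci_level: float = 0.95
    p_retain: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _child_seed(rng) -> int:
    return int(rng.integers(0, 2 ** 31 - 1))


# ---------------------------------------------------------------------------
# stage: simulate
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: RunConfig, outdir: Path) -> dict:
    """Generate the whole synthetic cohort under ``outdir``.

    Subjects beyond ``n_subjects`` (the ``n_qc_fail`` extras) receive heavily
    spiked motion so the QC stage excludes them, reproducing the exclusion
    narrative of a real cohort.
    """
    rng_panel, rng_net, rng_writing = _streams(cfg.seed, 3)
    outdir.mkdir(parents=True, exist_ok=True)

    n_total = cfg.n_subjects + cfg.n_qc_fail
    spec = synthetic.learning_panel_spec(n_subjects=n_total)
    panel = synthetic.gen_subject_panel(spec, seed=_child_seed(rng_panel))
    panel.to_csv(outdir / "panel_true.csv", index=False)

    partition = PartitionTable.balanced(cfg.n_networks, cfg.rois_per_network)
    partition.to_tsv(outdir / "partition.tsv")

    fmri_dir = outdir / "fmri"
    fmri_dir.mkdir(exist_ok=True)
    roi_cols = [f"roi{r}" for r in partition.roi_ids]
    for i, row in panel.iterrows():
        within = {n: cfg.within_r for n in partition.network_names}
        if "Sensorimotor" in within:
            within["Sensorimotor"] = cfg.within_r + \
                cfg.seg_within_slope * row["seg_sensorimotor"]
        cspec = synthetic.ConnectivitySpec(within_r=within, between_r=cfg.between_r,
                                           n_volumes=cfg.n_volumes, tr_s=cfg.tr_s)
        ts = synthetic.gen_roi_timeseries(partition, cspec, seed=_child_seed(rng_net))
        spikes = () if i < cfg.n_subjects else \
            np.arange(10, 10 + (cfg.max_scrubbed + 12)) % cfg.n_volumes
        motion = synthetic.gen_motion_trace(cfg.n_volumes, spike_indices=spikes,
                                            spike_mm=1.0, seed=_child_seed(rng_net))
        bold = synthetic.gen_bold_change(cfg.n_volumes, seed=_child_seed(rng_net))
        sid = row["subject"]
        pd.DataFrame(ts, columns=roi_cols).to_csv(
            fmri_dir / f"{sid}_timeseries.tsv", sep="\t", index=False)
        pd.DataFrame(motion, columns=["tx", "ty", "tz", "rx", "ry", "rz"]).to_csv(
            fmri_dir / f"{sid}_motion.tsv", sep="\t", index=False)
        pd.DataFrame({"bold_change": bold}).to_csv(
            fmri_dir / f"{sid}_bold.tsv", sep="\t", index=False)

    # writing trials: accuracy scores drive amplitude bias and variability,
    # an independent latent speed score drives path speed
    trials_dir = outdir / "trials"
    trials_dir.mkdir(exist_ok=True)
    sidecar = []
    for _, row in panel.iterrows():
        sid = row["subject"]
        speed_score = rng_writing.standard_normal()
        for tp in ("pre", "post", "followup"):
            acc = row[tp]
            for cond in ("single", "dual"):
                bias = 85.0 + 6.0 * acc - (2.0 if cond == "dual" else 0.0)
                cv = max(3.0, 10.0 - 1.5 * acc + (1.0 if cond == "dual" else 0.0))
                # floor keeps the requested path speed above the vertical-only
                # minimum implied by stroke rate x stroke height
                speed = max(1.8, cfg.base_speed_cm_s + 0.25 * speed_score)
                for run in (1, 2, 3):
                    trial = synthetic.gen_writing_trial(
                        target_cm=cfg.target_cm,
                        amplitude_bias_pct=bias + rng_writing.normal(0, 1.5),
                        amp_cv_pct=cv, speed_cm_s=speed,
                        duration_s=cfg.duration_s, fs_hz=cfg.fs_hz,
                        strokes_per_s=cfg.strokes_per_s,
                        seed=_child_seed(rng_writing),
                        condition=cond, timepoint=tp, subject=sid, run=run)
                    fname = f"{sid}_{tp}_{cond}_r{run}.csv"
                    trial.to_csv(trials_dir / fname)
                    sidecar.append({"file": fname, "subject": sid, "timepoint": tp,
                                    "condition": cond, "target_cm": cfg.target_cm,
                                    "run": run})
    pd.DataFrame(sidecar).to_csv(trials_dir / "trials.tsv", sep="\t", index=False)
    return {"n_simulated": n_total, "n_expected_pass": cfg.n_subjects}


# ---------------------------------------------------------------------------
# stage: segregation
# ---------------------------------------------------------------------------


def segregation_stage(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    partition = PartitionTable.from_tsv(outdir / "partition.tsv")
    fmri_dir = outdir / "fmri"
    subjects = sorted({p.name.split("_")[0] for p in fmri_dir.glob("*_timeseries.tsv")})
    seg_rows, qc_rows = [], []
    for sid in subjects:
        ts = pd.read_csv(fmri_dir / f"{sid}_timeseries.tsv", sep="\t").to_numpy()
        motion = pd.read_csv(fmri_dir / f"{sid}_motion.tsv", sep="\t").to_numpy()
        bold = pd.read_csv(fmri_dir / f"{sid}_bold.tsv", sep="\t")["bold_change"].to_numpy()
        table, info = connectivity.subject_segregation(
            ts, motion, bold, partition, tr_s=cfg.tr_s,
            fd_thresh=cfg.fd_thresh_mm, max_scrubbed=cfg.max_scrubbed,
            between=cfg.between_mode)
        qc_rows.append({"subject": sid, **info})
        if table is not None:
            table.insert(0, "subject", sid)
            seg_rows.append(table)
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    n_fail = int((~qc["qc_pass"]).sum())
    log.info("QC: %d/%d subjects pass (%d excluded)", len(subjects) - n_fail,
             len(subjects), n_fail)
    if not seg_rows:
        raise RuntimeError("no subjects pass QC")
    seg = pd.concat(seg_rows, ignore_index=True)
    seg.to_csv(outdir / "segregation.tsv", sep="\t", index=False)
    return seg


# ---------------------------------------------------------------------------
# stage: writing metrics + composite scores
# ---------------------------------------------------------------------------


def writing_stage(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    metrics = writing.process_directory(outdir / "trials", cutoff_hz=cfg.cutoff_hz,
                                        order=cfg.filter_order)
    metrics.to_csv(outdir / "writing_metrics.csv", index=False)
    return metrics


def compose_stage(cfg: RunConfig, outdir: Path, metrics: pd.DataFrame,
                  keep_subjects=None):
    agg = writing.aggregate_runs(metrics)
    if keep_subjects is not None:
        agg = agg[agg["subject"].isin(keep_subjects)].reset_index(drop=True)
    agg = agg[agg["target_cm"] == cfg.target_cm].reset_index(drop=True)
    agg.to_csv(outdir / "outcomes_aggregated.csv", index=False)
    model = scores.fit_components(agg, var_threshold=cfg.var_threshold)
    panel = scores.score_panel(model, agg)
    gains = scores.compute_gains(panel)
    panel.to_csv(outdir / "composite_panel.csv", index=False)
    gains.to_csv(outdir / "gains.csv", index=False)
    report = model.loadings.copy()
    report.loc["explained_pct"] = list(model.explained_pct) + \
        [np.nan] * (len(model.component_names) - len(model.explained_pct))
    report.to_csv(outdir / "component_model.tsv", sep="\t")
    return model, panel, gains


# ---------------------------------------------------------------------------
# stage: inference
# ---------------------------------------------------------------------------


def infer_stage(cfg: RunConfig, outdir: Path, gains: pd.DataFrame,
                panel: pd.DataFrame, seg: pd.DataFrame,
                clinical: pd.DataFrame) -> dict:
    sm_seg = (seg[seg["network"] == "Sensorimotor"]
              [["subject", "segregation"]]
              .rename(columns={"segregation": "seg_sensorimotor"}))
    predictors = clinical.merge(sm_seg, on="subject", validate="1:1")
    table = inference.association_table(gains, predictors, n_boot=cfg.n_boot,
                                        seed=cfg.seed)
    table.to_csv(outdir / "association_table.csv", index=False)

    anova = inference.rm_anova(panel, value="accuracy")
    (outdir / "anova.json").write_text(json.dumps({
        "F": anova.f, "df1": anova.df1, "df2": anova.df2, "p": anova.p,
        "partial_eta_sq": anova.partial_eta_sq,
        "pairwise": anova.pairwise.to_dict(orient="records")}, indent=2))

    # multivariable model: CI-significant overall-learning predictors + baseline
    sig = table[(table["endpoint"] == "overall") & table["significant"]
                & (table["predictor"] != "baseline")]["predictor"].tolist()
    merged = gains.merge(predictors, on="subject")
    model = None
    if sig:
        X = merged[["baseline"] + sig]
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed + 1))
        model = inference.backward_select(merged["overall"], X,
                                          p_retain=cfg.p_retain,
                                          n_boot=cfg.n_boot, rng=rng)
        (outdir / "model_report.json").write_text(json.dumps({
            "candidates": ["baseline"] + sig,
            "retained": model.retained,
            "betas": model.betas.round(4).to_dict(),
            "p_values": model.p_values.round(4).to_dict(),
            "ci": model.ci.round(4).to_dict(orient="index"),
            "adj_r_squared": model.adj_r_squared,
            "r_squared": model.r_squared,
            "model_p": model.model_p,
            "elimination_trace": model.elimination_trace}, indent=2))
    return {"association_table": table, "anova": anova, "model": model}


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------


def run_all(cfg: RunConfig, outdir) -> Path:
    """Execute every stage in order; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(
        json.dumps({"config": asdict(cfg)}, indent=2))

    sim_info = simulate_cohort(cfg, outdir)
    seg = segregation_stage(cfg, outdir)
    metrics = writing_stage(cfg, outdir)
    passing = set(seg["subject"])
    model, panel, gains = compose_stage(cfg, outdir, metrics,
                                        keep_subjects=passing)
    clinical = (pd.read_csv(outdir / "panel_true.csv")
                [["subject", "sex", "fog_free", "age", "ledd", "moca"]])
    clinical = clinical[clinical["subject"].isin(passing)]
    results = infer_stage(cfg, outdir, gains, panel, seg, clinical)

    summary = _summary_text(cfg, sim_info, seg, model, gains, results)
    (outdir / "summary.txt").write_text(summary)
    return outdir


def _summary_text(cfg, sim_info, seg, model, gains, results) -> str:
    lines = [
        "segrelearn run summary",
        "======================",
        f"subjects simulated: {sim_info['n_simulated']}; "
        f"passing QC: {gains.shape[0]}",
        "",
        "Component model (varimax-rotated loadings):",
        model.loadings.round(3).to_string(),
        f"explained variance (%): "
        f"{np.round(model.explained_pct, 1).tolist()} "
        f"(cumulative {model.cumulative_pct:.1f})",
        "",
        "RM-ANOVA on accuracy composite: "
        f"F({results['anova'].df1},{results['anova'].df2}) = "
        f"{results['anova'].f:.2f}, p = {results['anova'].p:.4f}, "
        f"partial eta^2 = {results['anova'].partial_eta_sq:.2f}",
        "",
        "Significant associations (BCa 95% CI excludes 0):",
        results["association_table"]
        .query("significant")[["endpoint", "predictor", "kind", "r",
                               "ci_lo", "ci_hi"]]
        .round(3).to_string(index=False),
    ]
    m = results.get("model")
    if m is not None and m.retained:
        lines += ["", "Final multivariable model (overall learning):",
                  f"  retained: {m.retained}",
                  f"  betas: {m.betas.round(3).to_dict()}",
                  f"  adjusted R^2 = {m.adj_r_squared:.3f} (p = {m.model_p:.4g})"]
    return "\n".join(str(x) for x in lines) + "\n"
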