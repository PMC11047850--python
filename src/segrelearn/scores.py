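"""Composite learning scores: PCA of writing outcomes, varimax rotation,
regression component scores, condition averaging and gain scores.

The four trial outcomes (amplitude, amplitude variability, speed, deviation)
are reduced by a correlation-matrix PCA over all subject x timepoint x
condition rows.  Components are retained until cumulative explained variance
exceeds 80%, varimax-rotated, and scored with the regression (Thompson)
estimator W = R^-1 L, which yields exactly unit-variance scores for PCA
loadings.  The component on which deviation loads most heavily is the
*accuracy* component, oriented so deviation loads negatively (higher score =
more accurate writing); the speed component is oriented so speed loads
positively.  Scores are averaged over single and dual task conditions within
each timepoint, and difference scores define acquisition (post - pre),
retention (followup - post) and overall learning (followup - pre).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import OUTCOME_COLUMNS  # canonical outcome column order

log = logging.getLogger(__name__)

VAR_THRESHOLD = 0.80
TIMEPOINTS = ("pre", "post", "followup")


def varimax(loadings: np.ndarray, kaiser: bool = True, tol: float = 1e-8,
            max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation matrix T for a p x m loading matrix.

    Kaiser row normalisation divides rows by their communalities before
    optimisation and restores them afterwards (the dominant convention).
    """
    lam = np.asarray(loadings, dtype=float)
    p, m = lam.shape
    if m < 2:
        return np.eye(m)
    comm = np.sqrt((lam ** 2).sum(axis=1)) if kaiser else np.ones(p)
    comm = np.where(comm == 0, 1.0, comm)
    a = lam / comm[:, None]
    t = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        b = a @ t
        u, s, vt = np.linalg.svd(
            a.T @ (b ** 3 - b @ np.diag((b ** 2).sum(axis=0)) / p))
        t = u @ vt
        d = s.sum()
        if d_old != 0 and (d - d_old) / d < tol:
            break
        d_old = d
    return t


@dataclass
class ComponentModel:
    """Fitted, rotated component structure of the writing outcomes."""

    outcome_names: tuple
    component_names: tuple          # e.g. ("accuracy", "speed")
    loadings: pd.DataFrame          # outcomes x components, varimax-rotated
    weights: pd.DataFrame           # regression score weights, outcomes x comps
    explained_pct: np.ndarray       # unrotated eigenvalue shares of retained comps
    rotated_pct: np.ndarray         # SS-loading shares after rotation
    cumulative_pct: float
    means: np.ndarray               # standardisation constants of the fit rows
    sds: np.ndarray

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Component scores for rows of outcome columns (fit-row scaling)."""
        z = (table[list(self.outcome_names)].to_numpy() - self.means) / self.sds
        return pd.DataFrame(z @ self.weights.to_numpy(),
                            columns=list(self.component_names),
                            index=table.index)


def fit_components(table: pd.DataFrame, var_threshold: float = VAR_THRESHOLD,
                   outcome_names=OUTCOME_COLUMNS) -> ComponentModel:
    """Correlation-matrix PCA with varimax rotation and regression scoring.

    Retains the smallest leading set of components whose cumulative explained
    variance exceeds ``var_threshold``.  Raises on zero-variance columns;
    warns and retains everything if the threshold is unreachable.
    """
    outcome_names = tuple(outcome_names)
    x = table[list(outcome_names)].to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError("need more rows than outcome columns for the PCA")
    if np.isnan(x).any():
        raise ValueError("complete cases only: outcome table contains NaN")
    sds = x.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [outcome_names[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance outcome column(s): {bad}")
    means = x.mean(axis=0)
    z = (x - means) / sds
    r = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(r)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic eigenvector sign: largest-|.| element positive
    for j in range(p):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]

    shares = evals / evals.sum()
    cum = np.cumsum(shares)
    m = int(np.searchsorted(cum, var_threshold, side="right") + 1)
    if cum[-1] <= var_threshold:
        warnings.warn("variance threshold unreachable; retaining all components")
        m = p
    m = min(m, p)

    lam = evecs[:, :m] * np.sqrt(evals[:m])
    t = varimax(lam)
    lam_rot = lam @ t
    rotated_ss = (lam_rot ** 2).sum(axis=0)

    # assign constructs: accuracy = largest |deviation| loading, then speed
    dev_i = outcome_names.index("deviation_pct") if "deviation_pct" in outcome_names else p - 1
    spd_i = outcome_names.index("speed_cm_s") if "speed_cm_s" in outcome_names else 0
    comp_order = list(range(m))
    acc_c = int(np.argmax(np.abs(lam_rot[dev_i, :])))
    comp_order.remove(acc_c)
    if comp_order:
        spd_c = comp_order[int(np.argmax(np.abs(lam_rot[spd_i, comp_order])))]
        comp_order.remove(spd_c)
    else:
        spd_c = None
    ordered = [acc_c] + ([spd_c] if spd_c is not None else []) + comp_order
    names = ["accuracy"] + (["speed"] if spd_c is not None else []) + [
        f"component{j + 1}" for j in range(len(comp_order))]

    lam_rot = lam_rot[:, ordered]
    rotated_ss = rotated_ss[ordered]
    # orientation: deviation negative on accuracy, speed positive on speed
    if lam_rot[dev_i, 0] > 0:
        lam_rot[:, 0] = -lam_rot[:, 0]
    if spd_c is not None and lam_rot[spd_i, 1] < 0:
        lam_rot[:, 1] = -lam_rot[:, 1]

    # pinv handles the exact-factor case where R is singular (rank m < p)
    weights = np.linalg.pinv(r) @ lam_rot
    return ComponentModel(
        outcome_names=outcome_names,
        component_names=tuple(names),
        loadings=pd.DataFrame(lam_rot, index=outcome_names, columns=names),
        weights=pd.DataFrame(weights, index=outcome_names, columns=names),
        explained_pct=100 * shares[:m],
        rotated_pct=100 * rotated_ss / evals.sum(),
        cumulative_pct=float(100 * cum[m - 1]),
        means=means,
        sds=sds,
    )


def score_panel(model: ComponentModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per subject x timepoint composite scores (mean of single and dual rows).

    A subject x timepoint with one condition missing gets the available
    condition's score, flagged in the ``incomplete`` column; subjects with no
    rows at a timepoint are simply absent (logged by the caller's join).
    """
    scores = model.transform(table)
    df = pd.concat(
        [table[["subject", "timepoint", "condition"]].reset_index(drop=True),
         scores.reset_index(drop=True)], axis=1)
    grouped = df.groupby(["subject", "timepoint"], as_index=False)
    out = grouped[list(model.component_names)].mean()
    out["incomplete"] = grouped["condition"].nunique()["condition"].to_numpy() < 2
    if out["incomplete"].any():
        log.warning("%d subject-timepoints scored from a single condition",
                    int(out["incomplete"].sum()))
    return out


def compute_gains(panel: pd.DataFrame, component: str = "accuracy") -> pd.DataFrame:
    """Acquisition (post - pre), retention (followup - post) and overall
    (followup - pre) gains per subject; requires all three timepoints."""
    wide = panel.pivot(index="subject", columns="timepoint", values=component)
    missing = [t for t in TIMEPOINTS if t not in wide.columns]
    if missing:
        raise ValueError(f"panel lacks timepoint(s): {missing}")
    complete = wide.dropna(subset=list(TIMEPOINTS))
    dropped = set(wide.index) - set(complete.index)
    if dropped:
        log.warning("dropping %d subject(s) with missing timepoints: %s",
                    len(dropped), sorted(dropped))
    return pd.DataFrame({
        "subject": complete.index,
        "baseline": complete["pre"].to_numpy(),
        "acquisition": (complete["post"] - complete["pre"]).to_numpy(),
        "retention": (complete["followup"] - complete["post"]).to_numpy(),
        "overall": (complete["followup"] - complete["pre"]).to_numpy(),
    }).reset_index(drop=True)
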