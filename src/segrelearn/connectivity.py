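"""Motion scrubbing, QC, Fisher-z connectivity and network segregation.

The resting-state pipeline stage: from realignment parameters and denoised
ROI timeseries to a per-network segregation score

    S_k = (W_k - B_k) / W_k

where ``W_k`` is the mean within-network Fisher-z connectivity of network k
and ``B_k`` the mean connectivity of its edges to all other networks.
Negative edges are excluded from both means, as the value of anti-correlations
is controversial.  Higher S means a more modular (segregated) network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .partition import PartitionTable

#: radius (mm) used to convert rotational displacement to translation;
#: the dominant convention in the scrubbing literature
ROTATION_RADIUS_MM = 50.0

FD_THRESHOLD_MM = 0.5
MAX_SCRUBBED_VOLUMES = 108
DEFAULT_TR_S = 1.7


@dataclass
class ScrubMask:
    """Per-volume scrub flags (True = volume removed) plus the TR."""

    flags: np.ndarray
    tr_s: float = DEFAULT_TR_S

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return self.flags.size

    @property
    def n_scrubbed(self) -> int:
        return int(self.flags.sum())


def compute_fd(motion: np.ndarray) -> np.ndarray:
    """Framewise displacement (mm) from 6 realignment parameters.

    Sum of absolute backward differences of 3 translations (mm) and
    3 rotations (rad), rotations converted to arc length on a 50 mm sphere.
    FD of the first volume is 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion trace must be (n_volumes, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def flag_scrub_volumes(fd: np.ndarray, bold_change: np.ndarray,
                       fd_thresh: float = FD_THRESHOLD_MM,
                       tr_s: float = DEFAULT_TR_S) -> ScrubMask:
    """Flag volumes with FD above threshold or outlying mean BOLD change.

    The BOLD rule is the one-sided Tukey fence: a volume is flagged when its
    global signal change exceeds Q3 + 1.5*IQR of the full series.
    """
    fd = np.asarray(fd, dtype=float)
    bold_change = np.asarray(bold_change, dtype=float)
    if fd.shape != bold_change.shape:
        raise ValueError("fd and bold_change must have the same length")
    q1, q3 = np.percentile(bold_change, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return ScrubMask((fd > fd_thresh) | (bold_change > fence), tr_s=tr_s)


def qc_pass(mask: ScrubMask, max_scrubbed: int = MAX_SCRUBBED_VOLUMES):
    """QC decision: fail iff strictly more than ``max_scrubbed`` volumes scrubbed.

    Returns ``(passed, retained_minutes)``.  The default of 108 at TR 1.7 s
    corresponds to requiring at least ~4 min of retained resting-state data.
    """
    passed = mask.n_scrubbed <= max_scrubbed
    retained_min = (mask.n_volumes - mask.n_scrubbed) * mask.tr_s / 60.0
    return passed, retained_min


def roi_correlation_matrix(ts: np.ndarray, mask: ScrubMask | None = None) -> np.ndarray:
    """Pairwise Pearson correlation of ROI timeseries, Fisher r-to-z transformed.

    Scrubbed volumes are deleted before correlating.  The diagonal is set to
    NaN (self-connectivity is undefined and never averaged).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be (n_volumes, n_rois)")
    if mask is not None:
        if mask.n_volumes != ts.shape[0]:
            raise ValueError("scrub mask length does not match volume count")
        ts = ts[~mask.flags]
    if ts.shape[0] < 3:
        raise ValueError("fewer than 3 volumes retained; correlation undefined")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance ROI(s) at column(s) {dead.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0 - 1e-12):
        i, j = np.argwhere((np.abs(r) >= 1.0 - 1e-12) & off)[0]
        raise ValueError(f"|r| = 1 between ROIs {i} and {j}; Fisher z infinite")
    np.fill_diagonal(r, 0.0)  # diagonal is excluded; avoid atanh(1) overflow
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    return z


@dataclass
class NetworkMatrix:
    """K x K network-averaged connectivity with per-cell surviving edge counts.

    Cell (k, k) is the mean within-network z of network k; cell (k, l) the
    mean z over all ROI pairs spanning networks k and l.  Edges with z < 0
    are excluded from every mean; a cell whose edges are all excluded holds
    NaN and count 0.
    """

    values: np.ndarray
    counts: np.ndarray
    networks: tuple

    @property
    def k(self) -> int:
        return len(self.networks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.networks, columns=self.networks)


def network_average_matrix(z: np.ndarray, partition: PartitionTable) -> NetworkMatrix:
    """Average a Fisher-z ROI matrix into network blocks, dropping negative edges."""
    z = np.asarray(z, dtype=float)
    if z.shape[0] != z.shape[1]:
        raise ValueError("z matrix must be square")
    if z.shape[0] != partition.n_rois:
        raise ValueError(
            f"partition covers {partition.n_rois} ROIs but z is {z.shape[0]}x{z.shape[0]}"
        )
    names = partition.network_names
    k = len(names)
    values = np.full((k, k), np.nan)
    counts = np.zeros((k, k), dtype=int)
    idx = [partition.indices(n) for n in names]
    iu = np.triu_indices(z.shape[0], 1)
    for a in range(k):
        for b in range(a, k):
            if a == b:
                block = z[np.ix_(idx[a], idx[a])]
                edges = block[np.triu_indices(len(idx[a]), 1)]
            else:
                edges = z[np.ix_(idx[a], idx[b])].ravel()
            keep = edges[edges >= 0]
            counts[a, b] = counts[b, a] = keep.size
            if keep.size:
                values[a, b] = values[b, a] = keep.mean()
            else:
                warnings.warn(
                    f"no surviving (non-negative) edges for cell ({names[a]}, {names[b]})"
                )
    del iu
    return NetworkMatrix(values, counts, tuple(names))


def segregation(nm: NetworkMatrix, network, between: str = "pooled") -> dict:
    """Segregation score of one network.

    Parameters
    ----------
    between
        ``"pooled"`` (default): B_k is the edge-weighted mean over every edge
        from network k to any other network.  ``"pair_means"``: B_k is the
        unweighted mean of the K-1 network-pair means.  The two agree exactly
        for equal-size networks.
    """
    try:
        k = nm.networks.index(network)
    except ValueError:
        raise KeyError(f"unknown network {network!r}") from None
    w = nm.values[k, k]
    if not np.isfinite(w):
        raise ValueError(f"within-network connectivity undefined for {network!r}")
    if w <= 0:
        raise ValueError(f"within-network connectivity {w:.4f} <= 0; ratio meaningless")
    others = [l for l in range(nm.k) if l != k]
    vals = nm.values[k, others]
    cnts = nm.counts[k, others]
    if between == "pooled":
        good = np.isfinite(vals) & (cnts > 0)
        if not good.any():
            raise ValueError(f"no between-network edges for {network!r}")
        b = float(np.sum(vals[good] * cnts[good]) / np.sum(cnts[good]))
    elif between == "pair_means":
        good = np.isfinite(vals)
        if not good.any():
            raise ValueError(f"no between-network means for {network!r}")
        b = float(vals[good].mean())
    else:
        raise ValueError("between must be 'pooled' or 'pair_means'")
    return {
        "network": network,
        "within": float(w),
        "between": b,
        "segregation": float((w - b) / w),
        "n_edges_within": int(nm.counts[k, k]),
        "n_edges_between": int(cnts.sum()),
    }


def segregation_table(nm: NetworkMatrix, between: str = "pooled") -> pd.DataFrame:
    """Segregation scores for every network, as a tidy table."""
    return pd.DataFrame([segregation(nm, n, between=between) for n in nm.networks])


def subject_segregation(ts: np.ndarray, motion: np.ndarray, bold_change: np.ndarray,
                        partition: PartitionTable, tr_s: float = DEFAULT_TR_S,
                        fd_thresh: float = FD_THRESHOLD_MM,
                        max_scrubbed: int = MAX_SCRUBBED_VOLUMES,
                        between: str = "pooled"):
    """Full per-subject chain: FD -> scrub -> QC -> z matrix -> segregation table.

    Returns ``(table or None, qc_info)``; table is None when QC fails.
    """
    fd = compute_fd(motion)
    mask = flag_scrub_volumes(fd, bold_change, fd_thresh=fd_thresh, tr_s=tr_s)
    passed, retained_min = qc_pass(mask, max_scrubbed=max_scrubbed)
    info = {"n_scrubbed": mask.n_scrubbed, "qc_pass": passed,
            "retained_minutes": retained_min}
    if not passed:
        return None, info
    z = roi_correlation_matrix(ts, mask)
    nm = network_average_matrix(z, partition)
    return segregation_table(nm, between=between), info
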