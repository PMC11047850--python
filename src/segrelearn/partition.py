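"""Parcel-to-network partition tables.

A partition assigns every region of interest (ROI, parcel) to exactly one
large-scale network, e.g. the 718-ROI / 12-network Cole-Anticevic brain-wide
partition.  The partition defines the block structure of every connectivity
summary downstream: within-network blocks on the diagonal, between-network
blocks off it.  Any partition with at least two ROIs per network is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# canonical 12 network names of the Cole-Anticevic partition, reused by the
# synthetic generators so demo output reads like real segregation tables
COLE_ANTICEVIC_NETWORKS = (
    "Primary visual",
    "Secondary visual",
    "Sensorimotor",
    "Cingulo-opercular",
    "Dorsal attention",
    "Language",
    "Frontoparietal",
    "Auditory",
    "Default",
    "Posterior multimodal",
    "Ventral multimodal",
    "Orbito-affective",
)


@dataclass(frozen=True)
class PartitionTable:
    """Mapping of ROI labels to network labels.

    Parameters
    ----------
    roi_ids
        Unique integer label per parcel, length ``n_rois``.
    networks
        Network label (string) per parcel, aligned with ``roi_ids``.
    """

    roi_ids: np.ndarray
    networks: np.ndarray
    _names: tuple = field(init=False, repr=False, default=())

    def __post_init__(self):
        roi_ids = np.asarray(self.roi_ids)
        networks = np.asarray(self.networks, dtype=object)
        if roi_ids.shape != networks.shape or roi_ids.ndim != 1:
            raise ValueError("roi_ids and networks must be aligned 1-D arrays")
        if len(np.unique(roi_ids)) != roi_ids.size:
            raise ValueError("duplicate ROI ids in partition")
        names, counts = np.unique(networks, return_counts=True)
        small = names[counts < 2]
        if small.size:
            raise ValueError(
                f"every network needs >= 2 ROIs for within-network edges; "
                f"offending: {list(small)}"
            )
        # preserve first-appearance order of network names
        seen: dict = {}
        for n in networks:
            seen.setdefault(n, None)
        object.__setattr__(self, "roi_ids", roi_ids)
        object.__setattr__(self, "networks", networks)
        object.__setattr__(self, "_names", tuple(seen))

    @property
    def n_rois(self) -> int:
        return self.roi_ids.size

    @property
    def network_names(self) -> tuple:
        return self._names

    @property
    def n_networks(self) -> int:
        return len(self._names)

    def indices(self, network) -> np.ndarray:
        """Positional indices (into roi_ids order) of one network's ROIs."""
        idx = np.flatnonzero(self.networks == network)
        if idx.size == 0:
            raise KeyError(f"unknown network {network!r}")
        return idx

    # ---- construction helpers -------------------------------------------

    @classmethod
    def balanced(cls, n_networks: int = 12, rois_per_network: int = 6,
                 names=None) -> "PartitionTable":
        """Toy partition with equal-size networks, Cole-Anticevic names by default."""
        if names is None:
            if n_networks <= len(COLE_ANTICEVIC_NETWORKS):
                names = COLE_ANTICEVIC_NETWORKS[:n_networks]
            else:
                names = tuple(f"Network{k + 1}" for k in range(n_networks))
        nets = np.repeat(np.asarray(names, dtype=object), rois_per_network)
        return cls(np.arange(nets.size), nets)

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "PartitionTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df["roi_id"].to_numpy(), df["network"].to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame({"roi_id": self.roi_ids, "network": self.networks}).to_csv(
            path, sep="\t", index=False
        )
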