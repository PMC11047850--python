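import numpy as np
import pytest

from segrelearn.partition import PartitionTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240412)


@pytest.fixture
def two_net_partition():
    """2 networks x 4 ROIs, small enough for brute-force oracles."""
    return PartitionTable.balanced(2, 4, names=("A", "B"))


@pytest.fixture
def toy_partition():
    """3 networks x 3 ROIs with a Sensorimotor label."""
    return PartitionTable.balanced(
        3, 3, names=("Sensorimotor", "Default", "Primary visual"))


def brute_force_network_means(z, partition):
    """Independent pair-loop oracle for network-averaged connectivity.

    Literal double loop over ROI pairs, accumulating sums per network cell
    after dropping negative edges; shares no code with the implementation.
    """
    names = list(partition.network_names)
    k = len(names)
    net_of = {int(r): n for r, n in zip(partition.roi_ids, partition.networks)}
    pos = {n: i for i, n in enumerate(names)}
    sums = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    p = z.shape[0]
    for i in range(p):
        for j in range(i + 1, p):
            v = z[i, j]
            if v < 0:
                continue
            a = pos[net_of[int(partition.roi_ids[i])]]
            b = pos[net_of[int(partition.roi_ids[j])]]
            lo, hi = min(a, b), max(a, b)
            sums[lo, hi] += v
            counts[lo, hi] += 1
    vals = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a, k):
            if counts[a, b]:
                vals[a, b] = vals[b, a] = sums[a, b] / counts[a, b]
            counts[b, a] = counts[a, b]
    return vals, counts


def brute_force_segregation(z, partition, network):
    """Edge-pooled segregation by direct enumeration (oracle)."""
    net_of = {int(r): n for r, n in zip(partition.roi_ids, partition.networks)}
    w_edges, b_edges = [], []
    p = z.shape[0]
    for i in range(p):
        for j in range(i + 1, p):
            v = z[i, j]
            if v < 0:
                continue
            ni = net_of[int(partition.roi_ids[i])]
            nj = net_of[int(partition.roi_ids[j])]
            if ni == network and nj == network:
                w_edges.append(v)
            elif ni == network or nj == network:
                b_edges.append(v)
    w = np.mean(w_edges)
    b = np.mean(b_edges)
    return (w - b) / w
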