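"""Weighted graph metrics: efficiency, clustering, lobe aggregates.

Edge weights w_ij in [0, 1] are mapped to lengths 1/w_ij (stronger coupling =
shorter path), the dominant convention for weighted efficiency. Nodal
efficiency of node i is the mean inverse shortest-path length to every other
node, NE_i = (1/(N-1)) * sum_{j != i} 1/d_ij, and global efficiency GE is the
mean of the NE_i. The weighted nodal clustering coefficient uses the
Zhang-Horvath form

    NCC_i = sum_{j != k} w_ij w_jk w_ki / ((sum_j w_ij)^2 - sum_j w_ij^2),

which lies in [0, 1] for weights in [0, 1]; the Onnela geometric-mean
variant is available via ``variant="onnela"``. The average clustering
coefficient is the mean of the NCC_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import ConnectivityMatrix
from .montage import LOBES


@dataclass
class DistanceMatrix:
    """All-pairs shortest path lengths; inf marks disconnected pairs."""

    d: np.ndarray
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if (np.diag(self.d) != 0).any():
            raise ValueError("self-distances must be zero")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")


@dataclass
class GraphMetrics:
    """Global and nodal metrics of one connectivity matrix."""

    global_efficiency: float
    average_clustering: float
    nodal_efficiency: np.ndarray
    nodal_clustering: np.ndarray
    channel_labels: tuple[str, ...]
    lobe_efficiency: dict[str, float]
    lobe_clustering: dict[str, float]
    clustering_variant: str = "zhang"


def weights_to_lengths(weights: np.ndarray) -> np.ndarray:
    """Edge lengths 1/w; absent (zero-weight) edges stay 0 = no edge."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or (w > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_paths(lengths: np.ndarray, channel_labels: tuple[str, ...] = ()) -> DistanceMatrix:
    """Exact all-pairs weighted shortest paths (Dijkstra); 0 entries = no edge."""
    lengths = np.asarray(lengths, dtype=float)
    if (lengths < 0).any():
        raise ValueError("edge lengths must be non-negative")
    d = _csgraph_shortest_path(lengths, method="D", directed=False)
    return DistanceMatrix(d=d, channel_labels=channel_labels)


def nodal_efficiency(dm: DistanceMatrix) -> np.ndarray:
    """NE_i = (1/(N-1)) sum_{j != i} 1/d_ij, with 1/inf = 0."""
    d = dm.d
    n = d.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(ne: np.ndarray) -> float:
    """GE = mean of the nodal efficiencies (0 for an empty vector)."""
    ne = np.asarray(ne, dtype=float)
    return float(ne.mean()) if ne.size else 0.0


def nodal_clustering(weights: np.ndarray, variant: str = "zhang") -> np.ndarray:
    """Weighted nodal clustering coefficient per node.

    ``zhang``: Zhang-Horvath form (default, bounded in [0, 1] for weights in
    [0, 1]); ``onnela``: geometric-mean triangle intensity over the binary
    neighborhood. Nodes whose denominator vanishes (degree <= 1) get 0.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or (w > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    if variant == "zhang":
        numer = np.diag(w @ w @ w)             # ordered pairs j != k
        s = w.sum(axis=1)
        q = (w ** 2).sum(axis=1)
        denom = s**2 - q
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
        return np.clip(ncc, 0.0, 1.0)
    if variant == "onnela":
        wmax = w.max()
        if wmax == 0:
            return np.zeros(w.shape[0])
        w_hat = (w / wmax) ** (1.0 / 3.0)
        numer = np.diag(w_hat @ w_hat @ w_hat)
        k = (w > 0).sum(axis=1)
        denom = k * (k - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    raise ValueError("variant must be 'zhang' or 'onnela'")


def average_clustering(ncc: np.ndarray) -> float:
    """Cave = mean of the nodal clustering coefficients."""
    ncc = np.asarray(ncc, dtype=float)
    return float(ncc.mean()) if ncc.size else 0.0


def lobe_aggregate(values: np.ndarray, channel_labels: tuple[str, ...]) -> dict[str, float]:
    """Mean of a per-channel metric over each lobe of the 16-channel montage."""
    by_label = dict(zip(channel_labels, np.asarray(values, dtype=float)))
    unknown = set(channel_labels) - {ch for chans in LOBES.values() for ch in chans}
    if unknown:
        raise ValueError(f"channels with no lobe assignment: {sorted(unknown)}")
    out = {}
    for lobe, chans in LOBES.items():
        present = [by_label[ch] for ch in chans if ch in by_label]
        if present:  # lobes absent from a partial montage are omitted
            out[lobe] = float(np.mean(present))
    return out


def compute_graph_metrics(cm: ConnectivityMatrix, clustering: str = "zhang") -> GraphMetrics:
    """Full metric set for one connectivity matrix."""
    dm = shortest_paths(weights_to_lengths(cm.weights), cm.channel_labels)
    ne = nodal_efficiency(dm)
    ncc = nodal_clustering(cm.weights, variant=clustering)
    return GraphMetrics(
        global_efficiency=global_efficiency(ne),
        average_clustering=average_clustering(ncc),
        nodal_efficiency=ne,
        nodal_clustering=ncc,
        channel_labels=cm.channel_labels,
        lobe_efficiency=lobe_aggregate(ne, cm.channel_labels),
        lobe_clustering=lobe_aggregate(ncc, cm.channel_labels),
        clustering_variant=clustering,
    )


def global_efficiency_of_weights(weights: np.ndarray) -> float:
    """GE straight from a weight matrix (used per window by the dynamics stage)."""
    dm = shortest_paths(weights_to_lengths(weights))
    return global_efficiency(nodal_efficiency(dm))
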