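"""Static functional connectivity: amplitude envelopes, LOFC and HOFC.

Low-order functional connectivity (LOFC) is the absolute Pearson correlation
between the Hilbert amplitude envelopes of every channel pair. High-order
functional connectivity (HOFC) correlates whole connectivity *profiles*: for
a node pair (i, j) it takes columns i and j of the Fisher-z-transformed LOFC
matrix, removes rows {i, j} from both (so the remaining N-2 entries align by
node identity), and stores the absolute Pearson correlation of the reduced
columns. HOFC is therefore high whenever two nodes connect to the rest of
the network in a similar pattern, even if their signals are not themselves
correlated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .montage import validate_band
from .preprocess import BandSignals

_CLIP = 1.0 - 1e-7


@dataclass
class EnvelopeMatrix:
    """Channels x samples non-negative amplitude envelopes of one band."""

    data: np.ndarray
    band: str
    rate: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if (self.data < 0).any():
            raise ValueError("envelope amplitudes must be non-negative")


@dataclass
class ConnectivityMatrix:
    """N x N symmetric weighted network with entries in [0, 1] and zero diagonal."""

    weights: np.ndarray
    order: str  # "low" | "high"
    band: str
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if self.order not in ("low", "high"):
            raise ValueError("order must be 'low' or 'high'")
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] != len(self.channel_labels):
            raise ValueError("label count must match matrix size")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be zero")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def amplitude_envelope(bs: BandSignals) -> EnvelopeMatrix:
    """Magnitude of the analytic signal for each channel.

    Requires at least two full cycles of the band's lower edge so the
    analytic signal is meaningful.
    """
    lo, _ = validate_band(bs.band)
    min_samples = int(np.ceil(2 * bs.rate / lo))
    if bs.n_samples < min_samples:
        raise ValueError(
            f"segment too short for a {bs.band} envelope: need >= {min_samples} "
            f"samples (two cycles of {lo} Hz at {bs.rate} Hz), got {bs.n_samples}"
        )
    env = np.abs(hilbert(bs.data, axis=-1))
    return EnvelopeMatrix(
        data=env, band=bs.band, rate=bs.rate, channel_labels=bs.channel_labels
    )


def _pearson_matrix(data: np.ndarray, labels: tuple[str, ...]) -> np.ndarray:
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples per channel for correlation")
    var = data.var(axis=1)
    dead = [labels[i] for i in np.flatnonzero(var == 0)]
    if dead:
        raise ValueError(f"zero-variance channel(s): {dead}")
    return np.corrcoef(data)


def compute_lofc(env: EnvelopeMatrix) -> ConnectivityMatrix:
    """Absolute envelope Pearson correlation; diagonal forced to zero."""
    r = _pearson_matrix(env.data, env.channel_labels)
    w = np.abs(r)
    np.fill_diagonal(w, 0.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    return ConnectivityMatrix(
        weights=w, order="low", band=env.band, channel_labels=env.channel_labels
    )


def fisher_z(r):
    """arctanh variance-stabilizing transform; |r| clipped to 1 - 1e-7 first."""
    r = np.asarray(r, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("fisher_z requires finite input")
    if (np.abs(r) > 1 + 1e-12).any():
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return out if out.ndim else float(out)


def compute_hofc(lofc: ConnectivityMatrix) -> ConnectivityMatrix:
    """Topographical-profile-similarity (high-order) network from a LOFC matrix.

    Vectorized over pairs: the Pearson correlation of the two reduced columns
    is assembled from full-column sums with the entries of rows {i, j}
    subtracted, which is algebraically identical to deleting those rows.
    """
    if lofc.order != "low":
        raise ValueError("HOFC is computed from a low-order matrix")
    n = lofc.n_nodes
    if n < 4:
        raise ValueError("HOFC needs at least 4 nodes (>= 2 residual profile entries)")
    z = fisher_z(lofc.weights)

    m = n - 2
    col_sum = z.sum(axis=0)            # S_i over all rows
    col_sq = (z ** 2).sum(axis=0)
    gram = z.T @ z                     # sum_k z[k,i] z[k,j]

    i_idx, j_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    zii = np.diag(z)                   # z[i,i]
    # entries of column i at rows i and j
    zi_at_i = zii[i_idx]               # z[i,i]
    zi_at_j = z[j_idx, i_idx]          # z[j,i]
    zj_at_i = z[i_idx, j_idx]          # z[i,j]
    zj_at_j = zii[j_idx]               # z[j,j]

    s1 = col_sum[i_idx] - zi_at_i - zi_at_j
    s2 = col_sum[j_idx] - zj_at_i - zj_at_j
    q1 = col_sq[i_idx] - zi_at_i**2 - zi_at_j**2
    q2 = col_sq[j_idx] - zj_at_i**2 - zj_at_j**2
    p = gram - zi_at_i * zj_at_i - zi_at_j * zj_at_j

    cov = p - s1 * s2 / m
    var1 = np.maximum(q1 - s1**2 / m, 0.0)
    var2 = np.maximum(q2 - s2**2 / m, 0.0)
    denom = np.sqrt(var1 * var2)
    if (denom[~np.eye(n, dtype=bool)] == 0).any():
        bad = sorted(
            {lofc.channel_labels[i] for i, j in zip(*np.nonzero((denom == 0) & ~np.eye(n, dtype=bool)))}
        )
        raise ValueError(f"constant connectivity profile(s) make HOFC undefined: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    w = np.abs(np.clip(r, -1.0, 1.0))
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return ConnectivityMatrix(
        weights=w, order="high", band=lofc.band, channel_labels=lofc.channel_labels
    )


def mean_connectivity(cm: ConnectivityMatrix) -> float:
    """Mean of the N(N-1)/2 upper-triangle off-diagonal weights."""
    iu = np.triu_indices(cm.n_nodes, k=1)
    return float(cm.weights[iu].mean())


def band_connectivity(bs: BandSignals, order: str = "low") -> ConnectivityMatrix:
    """Convenience path band signals -> envelope -> LOFC (-> HOFC)."""
    lofc = compute_lofc(amplitude_envelope(bs))
    if order == "low":
        return lofc
    if order == "high":
        return compute_hofc(lofc)
    raise ValueError("order must be 'low' or 'high'")


def save_matrix_csv(cm: ConnectivityMatrix, path: str | Path) -> Path:
    """Write weights as CSV with labels as header row and index column."""
    path = Path(path)
    labels = list(cm.channel_labels)
    pd.DataFrame(cm.weights, index=labels, columns=labels).to_csv(path, float_format="%.12g")
    return path


def load_matrix_csv(path: str | Path, order: str, band: str) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        weights=df.to_numpy(), order=order, band=band,
        channel_labels=tuple(df.columns),
    )


def save_matrix_json(cm: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "order": cm.order,
        "band": cm.band,
        "labels": list(cm.channel_labels),
        "weights": cm.weights.tolist(),
    }))
    return path


def load_matrix_json(path: str | Path) -> ConnectivityMatrix:
    obj = json.loads(Path(path).read_text())
    return ConnectivityMatrix(
        weights=np.asarray(obj["weights"]), order=obj["order"],
        band=obj["band"], channel_labels=tuple(obj["labels"]),
    )
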