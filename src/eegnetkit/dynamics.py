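"""Dynamic windowed networks and integration/segregation state entropy.

The band envelope is computed once on the full-length band signal, then cut
into non-overlapping windows (trailing partial window discarded); one LOFC
or HOFC matrix is built per window. Each window is classified *integrated*
(1) when its global efficiency strictly exceeds the median window GE of that
recording/band/order/length, else *segregated* (0) — a parameter-free,
scale-invariant median split (the classification criterion is pluggable).

Consecutive state pairs (sliding step 1, n-1 pairs) form the four transition
patterns 00/01/10/11; their empirical distribution p over M = 4 patterns
gives the normalized state entropy

    NSE = -(1/log M) * sum_i p_i log p_i,    NSE in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import (
    ConnectivityMatrix,
    EnvelopeMatrix,
    amplitude_envelope,
    compute_hofc,
    compute_lofc,
)
from .graph import global_efficiency_of_weights
from .montage import validate_band
from .preprocess import BandSignals

PATTERNS = ("00", "01", "10", "11")
M_PATTERNS = 4


@dataclass
class StateSequence:
    """Per-window binary integration states for one recording/band/order/length."""

    states: np.ndarray
    band: str
    order: str
    window_length_s: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be binary")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class PatternDistribution:
    """Empirical distribution over the four transition patterns."""

    p: dict[str, float]
    counts: dict[str, int]
    n_pairs: int

    def __post_init__(self) -> None:
        if set(self.p) != set(PATTERNS):
            raise ValueError(f"patterns must be exactly {PATTERNS}")
        total = sum(self.p.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern probabilities sum to {total}, not 1")
        if any(v < 0 for v in self.p.values()):
            raise ValueError("probabilities must be non-negative")


def fmin_window(band: str, rule: str = "lower") -> float:
    """The '1/fmin' window length (s) for a band.

    ``rule="lower"`` (default): reciprocal of the band's lower edge —
    delta 1.0 s, theta 0.25 s, alpha 0.125 s, beta 1/13 s.
    ``rule="center"``: reciprocal of the band's center frequency.
    """
    lo, hi = validate_band(band)
    if rule == "lower":
        return 1.0 / lo
    if rule == "center":
        return 2.0 / (lo + hi)
    raise ValueError("rule must be 'lower' or 'center'")


def standard_window_lengths(band: str, rule: str = "lower") -> tuple[float, ...]:
    """The seven analysis window lengths: {1/fmin, 1, 2, 4, 6, 8, 10} s."""
    return (fmin_window(band, rule), 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)


def segment_windows(data: np.ndarray, rate: float, length_s: float) -> list[np.ndarray]:
    """Consecutive non-overlapping channels x window slices; remainder dropped."""
    data = np.asarray(data)
    win = int(np.floor(length_s * rate))
    if win < 2:
        raise ValueError(f"window of {length_s} s at {rate} Hz has < 2 samples")
    n_win = data.shape[-1] // win
    if n_win < 2:
        raise ValueError(
            f"only {n_win} complete {length_s} s window(s); need >= 2 for transitions"
        )
    return [data[..., k * win : (k + 1) * win] for k in range(n_win)]


def windowed_networks(
    env: EnvelopeMatrix, length_s: float, order: str = "low"
) -> list[ConnectivityMatrix]:
    """One connectivity matrix per non-overlapping envelope window."""
    if order not in ("low", "high"):
        raise ValueError("order must be 'low' or 'high'")
    out = []
    for win in segment_windows(env.data, env.rate, length_s):
        win_env = EnvelopeMatrix(
            data=win, band=env.band, rate=env.rate, channel_labels=env.channel_labels
        )
        cm = compute_lofc(win_env)
        if order == "high":
            cm = compute_hofc(cm)
        out.append(cm)
    return out


def classify_states(
    matrices: list[ConnectivityMatrix], window_length_s: float
) -> StateSequence:
    """Median split on per-window global efficiency (strict >, ties segregated)."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 window matrices to classify states")
    ge = np.array([global_efficiency_of_weights(m.weights) for m in matrices])
    median = np.median(ge)
    states = (ge > median).astype(np.int8)
    if np.ptp(ge) == 0:
        warnings.warn(
            "all windows have identical global efficiency; labeling all segregated",
            stacklevel=2,
        )
    return StateSequence(
        states=states,
        band=matrices[0].band,
        order=matrices[0].order,
        window_length_s=window_length_s,
    )


def transition_patterns(ss: StateSequence) -> PatternDistribution:
    """Distribution of consecutive state pairs (n-1 sliding pairs)."""
    states = ss.states
    if len(states) < 2:
        raise ValueError("need at least 2 states to form a transition pattern")
    pairs = states[:-1] * 2 + states[1:]
    counts = {pat: int((pairs == k).sum()) for k, pat in enumerate(PATTERNS)}
    n_pairs = len(states) - 1
    p = {pat: counts[pat] / n_pairs for pat in PATTERNS}
    return PatternDistribution(p=p, counts=counts, n_pairs=n_pairs)


def state_entropy(pd_: PatternDistribution) -> float:
    """Normalized Shannon entropy of the transition-pattern distribution."""
    probs = np.array([pd_.p[pat] for pat in PATTERNS])
    nz = probs[probs > 0]
    nse = float(-(nz * np.log(nz)).sum() / np.log(M_PATTERNS))
    return min(max(nse, 0.0), 1.0) + 0.0  # +0.0 normalizes -0.0


def dynamic_entropy(
    bs: BandSignals,
    length_s: float,
    order: str = "low",
) -> tuple[float, PatternDistribution, StateSequence]:
    """Band signals -> windows -> networks -> states -> NSE, the full dynamic path."""
    env = amplitude_envelope(bs)
    mats = windowed_networks(env, length_s, order=order)
    ss = classify_states(mats, length_s)
    dist = transition_patterns(ss)
    return state_entropy(dist), dist, ss


def window_majority_states(timeline: np.ndarray, rate: float, length_s: float) -> np.ndarray:
    """Ground-truth per-window states from a per-sample regime timeline (majority vote)."""
    win = int(np.floor(length_s * rate))
    n_win = len(timeline) // win
    return np.array(
        [int(np.mean(timeline[k * win : (k + 1) * win]) > 0.5) for k in range(n_win)],
        dtype=np.int8,
    )
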