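"""Synthetic resting-state EEG cohorts with known coupling and state dynamics.

Each band signal on each channel is a weighted mixture of three band-limited
Gaussian noise sources:

    x_ch = a_g * shared  +  a_w * community[ch]  +  a_i * independent_ch

where ``shared`` is common to all channels, ``community`` is common to the
channels of one community, and the independent source is private. The mixing
weights derive from a :class:`CouplingSpec`: ``a_g = global_coupling``,
``a_w = within_community_coupling``, ``a_i = max(0, 1 - a_g - a_w)``.
Amplitude-envelope correlation between channels therefore rises with either
coupling weight, which is exactly the structure the low- and high-order
connectivity analysis assumes.

Integrated/segregated dynamics are planted by alternating two regimes with
dwell times around ``state_epoch_s``: during an *integrated* epoch the shared
source's weight is boosted and the community weight suppressed; a *segregated*
epoch does the reverse. The per-sample regime timeline is returned in the
cohort ledger so state-classification stages can be scored against ground
truth.

A pink-noise (1/f) background scaled by ``noise_sd`` is added to the broadband
sum so the preprocessing chain is exercised on realistic spectra.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .montage import BAND_ORDER, BANDS, MONTAGE_16, validate_band
from .recording import EEGRecording, save_csv, save_edf

#: Default community split of the montage: anterior vs posterior channels.
DEFAULT_COMMUNITIES: dict[str, int] = {
    ch: (0 if ch in ("FP1", "FP2", "F3", "F4", "F7", "F8", "C3", "C4") else 1)
    for ch in MONTAGE_16
}

#: Typical per-band RMS amplitude (uV) used when mixing bands into broadband.
BAND_AMPLITUDE_UV: dict[str, float] = {
    "delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 5.0,
}


@dataclass(frozen=True)
class CouplingSpec:
    """Planted envelope-coupling structure for one band.

    Parameters
    ----------
    band : str
        One of delta/theta/alpha/beta.
    global_coupling : float in [0, 1]
        Mixing weight of the source shared by all channels.
    within_community_coupling : float in [0, 1]
        Mixing weight of the per-community source.
    community_assignment : mapping channel -> community label
        Every montage channel must appear exactly once.
    noise_sd : float
        Standard deviation (uV) of the broadband pink-noise background.
    amplitude : float
        RMS amplitude (uV) of the band signal in the broadband mixture.
    """

    band: str
    global_coupling: float
    within_community_coupling: float = 0.0
    community_assignment: dict = field(default_factory=lambda: dict(DEFAULT_COMMUNITIES))
    noise_sd: float = 2.0
    amplitude: float | None = None

    def __post_init__(self) -> None:
        validate_band(self.band)
        for name in ("global_coupling", "within_community_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        missing = set(MONTAGE_16) - set(self.community_assignment)
        if missing:
            raise ValueError(f"channels without a community label: {sorted(missing)}")
        if self.amplitude is None:
            object.__setattr__(self, "amplitude", BAND_AMPLITUDE_UV[self.band])


def default_preset(condition: str) -> dict[str, CouplingSpec]:
    """Band->CouplingSpec map for one condition of the default cohort preset.

    The post condition raises delta-band global coupling and lowers it in
    theta/alpha/beta, mirroring the direction of the pre/post contrast the
    pipeline is designed to detect. Magnitudes are a documented choice, not a
    fit (see docs/methods.md).
    """
    if condition not in ("pre", "post"):
        raise ValueError("condition must be 'pre' or 'post'")
    g = {"pre": {"delta": 0.30, "theta": 0.45, "alpha": 0.45, "beta": 0.45},
         "post": {"delta": 0.45, "theta": 0.30, "alpha": 0.30, "beta": 0.30}}[condition]
    return {
        band: CouplingSpec(band=band, global_coupling=g[band],
                           within_community_coupling=0.30)
        for band in BAND_ORDER
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic pre/post cohort.

    ``conditions`` maps "pre"/"post" to band->CouplingSpec; identical
    ``CohortSpec`` + seed gives bit-identical output.
    """

    n_subjects: int = 28
    conditions: dict = field(default_factory=lambda: {c: default_preset(c) for c in ("pre", "post")})
    duration_s: float = 300.0
    sampling_rate: float = 1000.0
    state_epoch_s: float = 20.0
    dwell_jitter: float = 0.2
    regime_contrast: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration_s < 60:
            raise ValueError("duration_s must be >= 60 s")
        if set(self.conditions) != {"pre", "post"}:
            raise ValueError("conditions must map exactly 'pre' and 'post'")
        if not 0.0 <= self.dwell_jitter < 1.0:
            raise ValueError("dwell_jitter must be in [0, 1)")
        if not 0.0 <= self.regime_contrast <= 1.0:
            raise ValueError("regime_contrast must be in [0, 1]")


def band_limited_noise(
    n_samples: int,
    rate: float,
    band: str,
    rng: np.random.Generator,
    n_sources: int = 1,
) -> np.ndarray:
    """Unit-variance Gaussian white noise confined to a canonical band.

    Zero-phase order-4 Butterworth band-pass at the band's nominal edges.
    Returns shape (n_samples,) for a single source, else (n_sources, n_samples).
    """
    lo, hi = validate_band(band)
    if rate < 2 * hi:
        raise ValueError(f"rate {rate} Hz cannot represent the {band} band (needs >= {2 * hi} Hz)")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    white = rng.standard_normal((n_sources, n_samples))
    x = signal.sosfiltfilt(sos, white, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    x = x / sd
    return x[0] if n_sources == 1 else x


def pink_noise(n_samples: int, rng: np.random.Generator, n_sources: int = 1) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_sources, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    with np.errstate(divide="ignore"):
        shape = np.where(freqs > 0, 1.0 / np.sqrt(freqs), 0.0)
    x = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    x = x / sd
    return x[0] if n_sources == 1 else x


def generate_state_dynamics(
    epoch_s: float,
    duration_s: float,
    rate: float,
    rng: np.random.Generator,
    jitter: float = 0.2,
) -> np.ndarray:
    """Per-sample binary regime timeline (1 = integrated, 0 = segregated).

    Regimes strictly alternate; each dwell time is ``epoch_s`` jittered by a
    uniform +/- ``jitter`` fraction (``jitter=0`` gives exact tiling). The
    starting regime is drawn from ``rng``.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    n = int(round(duration_s * rate))
    if epoch_s > duration_s:
        warnings.warn("state epoch exceeds the recording; single-regime timeline", stacklevel=2)
    state = int(rng.integers(0, 2))
    timeline = np.empty(n, dtype=np.int8)
    pos = 0
    while pos < n:
        dwell = epoch_s * (1.0 + jitter * float(rng.uniform(-1, 1)))
        length = max(1, int(round(dwell * rate)))
        timeline[pos : pos + length] = state
        pos += length
        state = 1 - state
    return timeline


def generate_band_sources(
    spec: CouplingSpec,
    duration_s: float,
    rate: float,
    rng: np.random.Generator,
    regime: np.ndarray | None = None,
    regime_contrast: float = 0.6,
    channel_labels: tuple[str, ...] = MONTAGE_16,
) -> np.ndarray:
    """Channels x samples band-limited signals with the planted coupling.

    With a ``regime`` timeline, the coupling budget g + w is redistributed
    between the shared and community sources so that the shared source
    dominates during integrated samples and the community sources during
    segregated ones, while the total coupling stays constant:

        integrated:  a_g = g + c*w,      a_w = (1 - c)*w
        segregated:  a_g = (1 - c)*g,    a_w = w + c*g

    with c = ``regime_contrast`` (c = 1 concentrates all coupling on one
    source per regime; c = 0 disables the modulation).
    """
    n = int(round(duration_s * rate))
    g = spec.global_coupling
    w = spec.within_community_coupling
    a_ind = max(0.0, 1.0 - g - w)

    communities = sorted({spec.community_assignment[ch] for ch in channel_labels})
    n_src = 1 + len(communities) + len(channel_labels)
    sources = np.atleast_2d(band_limited_noise(n, rate, spec.band, rng, n_sources=n_src))
    shared = sources[0]
    comm_sources = {c: sources[1 + k] for k, c in enumerate(communities)}
    indep = sources[1 + len(communities):]

    if regime is None:
        a_g_t = np.full(n, g)
        a_w_t = np.full(n, w)
    else:
        regime = np.asarray(regime)
        if regime.shape[0] != n:
            raise ValueError("regime timeline length must match the sample count")
        c = regime_contrast
        integrated = regime == 1
        a_g_t = np.where(integrated, g + c * w, (1.0 - c) * g)
        a_w_t = np.where(integrated, (1.0 - c) * w, w + c * g)

    out = np.empty((len(channel_labels), n))
    for i, ch in enumerate(channel_labels):
        out[i] = (
            a_g_t * shared
            + a_w_t * comm_sources[spec.community_assignment[ch]]
            + a_ind * indep[i]
        )
    return out


def generate_recording(
    band_specs: dict[str, CouplingSpec],
    duration_s: float,
    rate: float,
    rng: np.random.Generator,
    subject_id: str,
    condition: str,
    regime: np.ndarray | None = None,
    regime_contrast: float = 0.6,
) -> EEGRecording:
    """Broadband recording = amplitude-scaled band mixtures + pink background."""
    n = int(round(duration_s * rate))
    total = np.zeros((len(MONTAGE_16), n))
    for band in BAND_ORDER:
        if band not in band_specs:
            continue
        spec = band_specs[band]
        x = generate_band_sources(
            spec, duration_s, rate, rng, regime=regime, regime_contrast=regime_contrast
        )
        rms = x.std(axis=1, keepdims=True)
        rms[rms == 0] = 1.0
        total += spec.amplitude * x / rms
    noise_sd = float(np.mean([s.noise_sd for s in band_specs.values()]))
    if noise_sd > 0:
        total += noise_sd * np.atleast_2d(pink_noise(n, rng, n_sources=total.shape[0]))
    return EEGRecording(
        data=total, rate=rate, subject_id=subject_id, condition=condition
    )


@dataclass
class Cohort:
    """Generated recordings plus the ground-truth ledger."""

    spec: CohortSpec
    recordings: dict  # subject_id -> {"pre": EEGRecording, "post": EEGRecording}
    timelines: dict   # subject_id -> {"pre": ndarray, "post": ndarray}

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.recordings)

    def ledger(self) -> dict:
        """JSON-serializable record of every planted parameter and timeline."""

        def spec_dict(cs: CouplingSpec) -> dict:
            return {
                "band": cs.band,
                "global_coupling": cs.global_coupling,
                "within_community_coupling": cs.within_community_coupling,
                "community_assignment": dict(cs.community_assignment),
                "noise_sd": cs.noise_sd,
                "amplitude": cs.amplitude,
            }

        return {
            "n_subjects": self.spec.n_subjects,
            "duration_s": self.spec.duration_s,
            "sampling_rate": self.spec.sampling_rate,
            "state_epoch_s": self.spec.state_epoch_s,
            "dwell_jitter": self.spec.dwell_jitter,
            "regime_contrast": self.spec.regime_contrast,
            "seed": self.spec.seed,
            "channel_labels": list(MONTAGE_16),
            "conditions": {
                cond: {b: spec_dict(cs) for b, cs in bands.items()}
                for cond, bands in self.spec.conditions.items()
            },
            "timelines": {
                sid: {cond: _segments(tl) for cond, tl in conds.items()}
                for sid, conds in self.timelines.items()
            },
        }


def _segments(timeline: np.ndarray) -> list[list[int]]:
    """Run-length encode a per-sample timeline as [state, start, length] triples."""
    edges = np.flatnonzero(np.diff(timeline)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [len(timeline)]])
    return [[int(timeline[s]), int(s), int(e - s)] for s, e in zip(starts, ends)]


def expand_segments(segments: list[list[int]], n_samples: int) -> np.ndarray:
    """Inverse of the ledger's run-length encoding."""
    out = np.zeros(n_samples, dtype=np.int8)
    for state, start, length in segments:
        out[start : start + length] = state
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full pre/post cohort deterministically from ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    subject_seqs = root.spawn(spec.n_subjects)
    recordings: dict = {}
    timelines: dict = {}
    for idx, seq in enumerate(subject_seqs):
        sid = f"s{idx:02d}"
        recordings[sid] = {}
        timelines[sid] = {}
        for cond, cond_seq in zip(("pre", "post"), seq.spawn(2)):
            rng = np.random.default_rng(cond_seq)
            timeline = generate_state_dynamics(
                spec.state_epoch_s, spec.duration_s, spec.sampling_rate,
                rng, jitter=spec.dwell_jitter,
            )
            rec = generate_recording(
                spec.conditions[cond], spec.duration_s, spec.sampling_rate,
                rng, subject_id=sid, condition=cond,
                regime=timeline, regime_contrast=spec.regime_contrast,
            )
            recordings[sid][cond] = rec
            timelines[sid][cond] = timeline
    return Cohort(spec=spec, recordings=recordings, timelines=timelines)


def generate_moca_table(
    n_subjects: int,
    rng: np.random.Generator,
    baseline_range: tuple[int, int] = (19, 24),
    improve_fraction: float = 26 / 28,
    decline_fraction: float = 1 / 28,
) -> "pd.DataFrame":
    """Optional integer MoCA-style score table for the stats bookkeeping path.

    Draws baseline scores uniformly on ``baseline_range`` (inclusive) and
    assigns post-training deltas so the expected improved/stable/declined
    split matches the given fractions. Scores are clamped to the 0-30 scale.
    """
    import pandas as pd

    lo, hi = baseline_range
    pre = rng.integers(lo, hi + 1, size=n_subjects)
    u = rng.uniform(size=n_subjects)
    delta = np.where(
        u < improve_fraction, rng.integers(1, 4, size=n_subjects),
        np.where(u < improve_fraction + decline_fraction,
                 -rng.integers(1, 3, size=n_subjects), 0),
    )
    post = np.clip(pre + delta, 0, 30)
    return pd.DataFrame({
        "subject": [f"s{i:02d}" for i in range(n_subjects)],
        "moca_pre": pre.astype(int),
        "moca_post": post.astype(int),
    })


def save_cohort(cohort: Cohort, out_dir: str | Path, fmt: str = "csv") -> Path:
    """Write every recording (CSV or EDF) plus the JSON ground-truth ledger."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, conds in sorted(cohort.recordings.items()):
        for cond, rec in sorted(conds.items()):
            stem = out_dir / f"{sid}_{cond}"
            if fmt == "csv":
                save_csv(rec, stem.with_suffix(".csv"))
            elif fmt == "edf":
                save_edf(rec, stem.with_suffix(".edf"))
            else:
                raise ValueError("fmt must be 'csv' or 'edf'")
    ledger_path = out_dir / "ground_truth.json"
    ledger_path.write_text(json.dumps(cohort.ledger(), indent=1, sort_keys=True))
    return out_dir
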