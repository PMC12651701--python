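"""The 16-channel 10-20 montage, its lobe partition, and the canonical EEG bands."""

from __future__ import annotations

#: Channel order used throughout: frontal, left/right temporal, parietal, occipital.
MONTAGE_16: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4",
    "F7", "T3", "T5", "F8", "T4", "T6",
    "C3", "C4", "P3", "P4",
    "O1", "O2",
)

#: Lobe partition of the montage. Left and right temporal chains are pooled
#: into a single temporal lobe, giving lobe sizes 4/6/4/2.
LOBES: dict[str, tuple[str, ...]] = {
    "frontal": ("FP1", "FP2", "F3", "F4"),
    "temporal": ("F7", "T3", "T5", "F8", "T4", "T6"),
    "parietal": ("C3", "C4", "P3", "P4"),
    "occipital": ("O1", "O2"),
}

#: Nominal band edges in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta")


def lobe_of(channel: str) -> str:
    """Return the lobe a montage channel belongs to.

    Raises
    ------
    KeyError
        If the channel label is not one of the 16 montage channels.
    """
    for lobe, chans in LOBES.items():
        if channel in chans:
            return lobe
    raise KeyError(f"unknown montage channel: {channel!r}")


def validate_band(band: str) -> tuple[float, float]:
    """Return nominal (low, high) edges for a canonical band name."""
    try:
        return BANDS[band]
    except KeyError:
        raise ValueError(
            f"band must be one of {sorted(BANDS)}, got {band!r}"
        ) from None
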