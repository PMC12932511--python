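"""Frequency-band definitions for the seven-band analysis.

The analysis decomposes every epoch into a full-band version plus six
canonical EEG rhythms.  Band edges above ``0.45 * sampling_rate`` are
clipped to that value (the practical upper edge of a zero-phase
Butterworth band-pass) so the same band set can be applied to 500 Hz
scalp EEG and 2,000 Hz SEEG alike.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Fraction of the sampling rate used as the practical upper filter edge.
NYQUIST_CAP = 0.45

#: Canonical band edges in Hz. ``None`` marks a Nyquist-capped upper edge.
DEFAULT_BAND_EDGES: dict[str, tuple[float, float | None]] = {
    "full": (0.5, 300.0),
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
    "hf": (80.0, None),
}

BAND_NAMES = tuple(DEFAULT_BAND_EDGES)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with resolved edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(
                f"band {self.name!r}: low edge {self.low_hz} must be below "
                f"high edge {self.high_hz}"
            )


def resolve_band(name: str, sampling_rate: float) -> BandDefinition:
    """Resolve a canonical band name to concrete edges at a sampling rate."""
    low, high = DEFAULT_BAND_EDGES[name]
    cap = NYQUIST_CAP * sampling_rate
    high = cap if high is None else min(high, cap)
    return BandDefinition(name, low, high)


def default_bands(sampling_rate: float) -> list[BandDefinition]:
    """The seven analysis bands resolved for ``sampling_rate``."""
    return [resolve_band(name, sampling_rate) for name in BAND_NAMES]
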