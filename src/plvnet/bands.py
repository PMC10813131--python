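"""Frequency-band definitions for narrowband network analysis.

The canonical five-band decomposition tiles 1-50 Hz: delta (1-4), theta
(4-8), alpha (8-13), beta (13-30) and gamma (30-50 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with lower and upper edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low_hz < high_hz, "
                f"got ({self.low_hz}, {self.high_hz})"
            )

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)


DELTA = BandSpec("delta", 1.0, 4.0)
THETA = BandSpec("theta", 4.0, 8.0)
ALPHA = BandSpec("alpha", 8.0, 13.0)
BETA = BandSpec("beta", 13.0, 30.0)
GAMMA = BandSpec("gamma", 30.0, 50.0)

#: Canonical bands in ascending frequency order.
CANONICAL_BANDS: tuple[BandSpec, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA)

BAND_BY_NAME: dict[str, BandSpec] = {b.name: b for b in CANONICAL_BANDS}


def get_band(name_or_band: "str | BandSpec") -> BandSpec:
    """Resolve a band given either its canonical name or a BandSpec."""
    if isinstance(name_or_band, BandSpec):
        return name_or_band
    try:
        return BAND_BY_NAME[name_or_band]
    except KeyError:
        raise KeyError(
            f"unknown band {name_or_band!r}; known: {sorted(BAND_BY_NAME)}"
        ) from None
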