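"""Canonical EEG frequency bands.

Band membership uses half-open intervals [f_lo, f_hi): a bin at exactly
8 Hz belongs to alpha, not theta. The conventional 4-5 Hz gap between
delta and theta is kept as printed in the clinical literature this
package follows — bins in [4, 5) belong to no band.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with half-open edges [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValidationError(
                f"band {self.name!r}: f_lo ({self.f_lo}) must be < f_hi ({self.f_hi})"
            )

    def contains(self, freq) -> bool:
        return (self.f_lo <= freq) & (freq < self.f_hi)


DELTA = BandDefinition("delta", 1.0, 4.0)
THETA = BandDefinition("theta", 5.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 60.0)

#: Default analysis bands, in canonical order.
BANDS: tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA)

BAND_MAP: dict[str, BandDefinition] = {b.name: b for b in BANDS}


def get_band(band: "str | BandDefinition") -> BandDefinition:
    """Resolve a band given by name or definition."""
    if isinstance(band, BandDefinition):
        return band
    try:
        return BAND_MAP[band]
    except KeyError:
        raise ValidationError(
            f"unknown band {band!r}; known bands: {sorted(BAND_MAP)}"
        ) from None
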