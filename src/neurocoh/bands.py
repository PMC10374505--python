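"""Frequency-band definitions for band-limited connectivity analysis.

The five canonical clinical EEG bands span 0.1-50 Hz. Bands are half-open
intervals ``[low, high)`` on the spectral grid, except that the top band may
close its upper edge so that the five bands are disjoint and exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BandDefinition", "DEFAULT_BANDS", "band_mask"]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band.

    Parameters
    ----------
    name : str
        Band label (e.g. ``"delta"``).
    low, high : float
        Band edges in Hz; must satisfy ``0 <= low < high``.
    closed_upper : bool
        If True, a spectral bin exactly at ``high`` belongs to this band.
        Used for the top band so the band family tiles the analysis range.
    """

    name: str
    low: float
    high: float
    closed_upper: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(
                f"invalid band {self.name!r}: need 0 <= low < high, "
                f"got low={self.low}, high={self.high}"
            )

    def validate_for_fs(self, fs: float) -> None:
        if self.high > fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz exceeds the "
                f"Nyquist frequency {fs / 2} Hz"
            )


#: The five analysis bands: delta 0.1-4, theta 4-8, alpha 8-13, beta 13-30,
#: gamma 30-50 Hz (gamma closes its upper edge).
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.1, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0, closed_upper=True),
)


def band_mask(freqs: np.ndarray, band: BandDefinition, *, exclude_dc: bool = True) -> np.ndarray:
    """Boolean mask selecting the spectral bins belonging to ``band``.

    A bin at frequency f is in the band iff ``low <= f < high`` (or
    ``f == high`` when ``closed_upper``). The DC bin is excluded by default
    because detrending makes it degenerate.
    """
    freqs = np.asarray(freqs, dtype=float)
    mask = (freqs >= band.low) & (freqs < band.high)
    if band.closed_upper:
        mask |= np.isclose(freqs, band.high)
    if exclude_dc:
        mask &= freqs > 0
    return mask
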