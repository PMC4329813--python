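"""Cochlear place–frequency (tonotopic) mapping for the mouse.

The basilar membrane maps frequency to place log-linearly: with
``d`` the percent distance from the apex, characteristic frequency is

    f(kHz) = 10 ** ((A - (100 - d)) / B)

with default constants A = 156.5 and B = 82.5 (per log10-kHz), the
mouse map used throughout the package.  The same class accepts other
constants, so alternative published mouse maps can be used as drop-in
backends.  With the defaults the apex (d = 0) sits at ≈ 4.8 kHz and the
basal extreme (d = 100) at ≈ 79 kHz, which is why discarding the basal
fifth of the cochlea loses the 50–80 kHz range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlaceFrequencyMap", "octave_distance"]


@dataclass(frozen=True)
class PlaceFrequencyMap:
    """Log-linear tonotopic map, percent distance measured from the apex."""

    A: float = 156.5
    B: float = 82.5

    def __post_init__(self):
        if self.B <= 0:
            raise ValueError("B must be > 0 (strictly monotone map)")

    @property
    def f_min(self) -> float:
        """CF at the apex, kHz."""
        return float(10 ** ((self.A - 100) / self.B))

    @property
    def f_max(self) -> float:
        """CF at the basal extreme, kHz."""
        return float(10 ** (self.A / self.B))

    def percent_to_frequency(self, d_apex):
        """Characteristic frequency (kHz) at percent distance from the apex."""
        d = np.asarray(d_apex, dtype=float)
        if np.any((d < 0) | (d > 100)):
            raise ValueError("percent distance must lie in [0, 100]")
        out = 10 ** ((self.A - (100 - d)) / self.B)
        return float(out) if np.isscalar(d_apex) else out

    def frequency_to_percent(self, f_khz):
        """Exact inverse of :meth:`percent_to_frequency`."""
        f = np.asarray(f_khz, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequency must be positive (kHz)")
        d = 100 - (self.A - self.B * np.log10(f))
        if np.any((d < -1e-9) | (d > 100 + 1e-9)):
            raise ValueError("frequency outside the map's range")
        d = np.clip(d, 0.0, 100.0)
        return float(d) if np.isscalar(f_khz) else d


def octave_distance(f_khz, ref_khz):
    """Signed distance in octaves between two frequencies."""
    return np.log2(np.asarray(f_khz, dtype=float) / ref_khz)
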