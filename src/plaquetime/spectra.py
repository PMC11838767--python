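"""The Spectrum container shared by the isotope model and the peak-fitting stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Spectrum:
    """An m/z-intensity trace with acquisition-mode tag and ROI metadata.

    ``meta`` carries ROI identity (plaque id, subregion center/periphery,
    anatomical region, animal) when the spectrum comes from an annotated ROI.
    """

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "linear"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.ndim != 1:
            raise ValueError("spectrum axes must be one-dimensional")
        if self.mz.size >= 2 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.mode not in ("linear", "reflector"):
            raise ValueError("mode must be 'linear' or 'reflector'")

    def restrict(self, lo: float, hi: float) -> "Spectrum":
        sel = (self.mz >= lo) & (self.mz <= hi)
        return Spectrum(self.mz[sel], self.intensity[sel], self.mode, dict(self.meta))

    def copy_with(self, intensity: np.ndarray) -> "Spectrum":
        return Spectrum(self.mz.copy(), np.asarray(intensity, float), self.mode, dict(self.meta))
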