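"""Instrument peak-shape model: shape family plus an FWHM-vs-m/z law.

A quadrupole scanned at "unit resolution" is modelled with a Gaussian line
shape whose full width at half maximum grows linearly with m/z,
``FWHM(m) = a + b*m``. The default anchors the width to a resolving power
R_FWHM = 500 (FWHM ≈ 0.44 Th at m/z 222), typical of a triple quadrupole
acquiring profile data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PeakShapeModel", "GAUSSIAN_FWHM_SIGMA"]

GAUSSIAN_FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM / sigma


@dataclass(frozen=True)
class PeakShapeModel:
    family: str = "gaussian"
    fwhm_a: float = 0.0  # Th, intercept of FWHM(m) = a + b*m
    fwhm_b: float = 1.0 / 500.0  # per-Th slope
    asymmetry: float | None = None  # reserved; Gaussian family ignores it

    def __post_init__(self) -> None:
        if self.family != "gaussian":
            raise ValueError(f"unsupported shape family {self.family!r}")

    @classmethod
    def from_resolving_power(cls, r_fwhm: float) -> "PeakShapeModel":
        """Constant resolving power: FWHM(m) = m / R."""
        if r_fwhm <= 0:
            raise ValueError("resolving power must be positive")
        return cls(fwhm_a=0.0, fwhm_b=1.0 / r_fwhm)

    def fwhm_at(self, mz: float) -> float:
        w = self.fwhm_a + self.fwhm_b * mz
        if w <= 0:
            raise ValueError(f"non-positive FWHM {w} at m/z {mz}")
        return w

    def evaluate(self, grid: np.ndarray, center: float, area: float) -> np.ndarray:
        """Unit-area line shape scaled to *area*, sampled on *grid*."""
        sigma = self.fwhm_at(center) / GAUSSIAN_FWHM_SIGMA
        x = (np.asarray(grid, dtype=float) - center) / sigma
        return area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(-0.5 * x * x)

    def add_peak(
        self, grid: np.ndarray, intensity: np.ndarray, center: float, area: float
    ) -> None:
        """Accumulate one peak into *intensity* in place.

        Only the ±10σ neighbourhood of the centroid is touched (the tail
        beyond is < 1e-21 of the apex), which keeps rendering many peaks on
        a long acquisition grid cheap. Requires an ascending *grid*.
        """
        sigma = self.fwhm_at(center) / GAUSSIAN_FWHM_SIGMA
        lo = int(np.searchsorted(grid, center - 10 * sigma))
        hi = int(np.searchsorted(grid, center + 10 * sigma))
        if hi <= lo:
            return
        x = (grid[lo:hi] - center) / sigma
        intensity[lo:hi] += area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
            -0.5 * x * x
        )
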