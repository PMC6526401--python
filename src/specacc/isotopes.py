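"""Theoretical isotope patterns and their rendering as profile spectra.

Patterns are computed by iterative fine-structure convolution: each element's
n-atom distribution is built by exponentiation-by-squaring of its single-atom
isotope distribution, the per-element distributions are convolved together,
and peaks below a relative-abundance threshold are pruned. This is exact (up
to pruning) at the ≤50-atom scale of small-molecule work; no FFT or
nominal-mass approximations are involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import ELECTRON_MASS, ElementIsotopeTable, default_table
from .formula import Formula
from .lineshape import PeakShapeModel
from .spectrum import ProfileSpectrum

__all__ = [
    "IsotopePattern",
    "NominalAggregate",
    "isotope_pattern",
    "aggregate_nominal",
    "render_profile",
]

# Fine-structure peaks closer than this are merged (abundance-weighted mass).
_MERGE_TOL = 1e-6  # Da
# Intermediate convolutions prune harder than the final threshold to keep the
# peak lists short without disturbing the final pattern.
_INTERMEDIATE_FACTOR = 1e-3


@dataclass
class IsotopePattern:
    """Centroid isotope pattern: (m/z, relative abundance in % of base peak)."""

    peaks: list[tuple[float, float]]
    prune_threshold: float
    charge: int = 0

    @property
    def mono_mz(self) -> float:
        """m/z of the monoisotopic (lowest-mass) peak."""
        return self.peaks[0][0]

    @property
    def base_mz(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]


@dataclass
class NominalAggregate:
    """Cluster abundances of M, M+1, ... in % of the M cluster."""

    clusters: list[float]


def _merge(peaks: list[tuple[float, float]]) -> list[tuple[float, float]]:
    peaks.sort()
    out: list[tuple[float, float]] = []
    for m, a in peaks:
        if out and m - out[-1][0] < _MERGE_TOL:
            pm, pa = out[-1]
            tot = pa + a
            out[-1] = ((pm * pa + m * a) / tot, tot)
        else:
            out.append((m, a))
    return out


def _prune(peaks: list[tuple[float, float]], rel: float) -> list[tuple[float, float]]:
    if not peaks:
        return peaks
    cut = max(a for _, a in peaks) * rel
    return [(m, a) for m, a in peaks if a > cut]


def _convolve(
    a: list[tuple[float, float]], b: list[tuple[float, float]], rel: float
) -> list[tuple[float, float]]:
    prod = [(ma + mb, aa * ab) for ma, aa in a for mb, ab in b]
    return _prune(_merge(prod), rel)


def _element_power(
    single: list[tuple[float, float]], n: int, rel: float
) -> list[tuple[float, float]]:
    """n-fold self-convolution by squaring."""
    result = [(0.0, 1.0)]
    base = single
    while n:
        if n & 1:
            result = _convolve(result, base, rel)
        n >>= 1
        if n:
            base = _convolve(base, base, rel)
    return result


def isotope_pattern(
    ion: Formula,
    prune: float = 1e-8,
    table: ElementIsotopeTable | None = None,
) -> IsotopePattern:
    """Fine-structure isotope distribution of *ion*, base peak scaled to 100.

    ``prune`` is the relative-abundance threshold below which peaks are
    dropped. m/z values carry the electron-mass/charge correction when the
    formula is charged; a neutral gives plain mass values.
    """
    if not (0 <= prune < 1):
        raise ValueError("prune must be in [0, 1)")
    t = table or default_table()
    rel = prune * _INTERMEDIATE_FACTOR
    dist = [(0.0, 1.0)]
    for sym, n in ion.counts:
        single = [(i.mass, i.abundance) for i in t.distribution(sym)]
        dist = _convolve(dist, _element_power(single, n, rel), rel)
    z = ion.charge
    if z != 0:
        dist = [((m - z * ELECTRON_MASS) / abs(z), a) for m, a in dist]
    dist = _prune(dist, prune)
    base = max(a for _, a in dist)
    peaks = [(m, 100.0 * a / base) for m, a in sorted(dist)]
    return IsotopePattern(peaks, prune, z)


def aggregate_nominal(
    pattern: IsotopePattern, k_max: int = 3, window: float = 0.3
) -> NominalAggregate:
    """Sum fine-structure peaks into M, M+1, ..., M+k_max clusters.

    A peak belongs to cluster k if it lies within ±*window* Th of
    ``mono + k``; the M cluster is normalised to 100.
    """
    if k_max < 0:
        raise ValueError("k_max must be nonnegative")
    mono = pattern.mono_mz
    sums = [0.0] * (k_max + 1)
    for m, a in pattern.peaks:
        for k in range(k_max + 1):
            if abs(m - (mono + k)) <= window:
                sums[k] += a
                break
    if sums[0] <= 0:
        raise ValueError("empty M cluster; pattern does not start at mono")
    scale = 100.0 / sums[0]
    return NominalAggregate([s * scale for s in sums])


def render_profile(
    pattern: IsotopePattern,
    shape: PeakShapeModel,
    grid_step: float = 0.01,
    window: tuple[float, float] | None = None,
) -> ProfileSpectrum:
    """Render centroids as a continuous profile under the line-shape model.

    Each centroid contributes a unit-area peak scaled by its abundance; the
    integral of the rendered profile equals the summed abundances (within
    discretisation error). *window* is absolute (lo, hi) in Th; the default
    pads 5 FWHM beyond the outermost peaks.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if window is None:
        lo = pattern.peaks[0][0] - 5 * shape.fwhm_at(pattern.peaks[0][0])
        hi = pattern.peaks[-1][0] + 5 * shape.fwhm_at(pattern.peaks[-1][0])
        window = (lo, hi)
    lo, hi = window
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    intensity = np.zeros_like(grid)
    any_inside = False
    for m, a in pattern.peaks:
        if lo <= m <= hi:
            any_inside = True
        shape.add_peak(grid, intensity, m, a)
    meta = {"rendered": True, "grid_step": grid_step}
    if not any_inside:
        meta["empty_window"] = True
        intensity = np.zeros_like(grid)
    return ProfileSpectrum(grid, intensity, meta)
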