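"""Post-acquisition mass calibration from internal calibrants.

A scanning quadrupole's mass axis drifts; spiked internal calibrants of known
formula anchor a polynomial correction fitted after acquisition. The model
has two parts:

* a mass-axis polynomial (order ≤ 2) mapping raw m/z to calibrated m/z,
  least-squares fitted to (measured, true) calibrant centroids;
* a line-shape model (Gaussian FWHM vs m/z) fitted to the calibrant peak
  profiles, used later to render theoretical isotope patterns in the
  instrument's own shape so observed and theoretical profiles are compared
  in the same space.

Rather than reshaping the measured data onto an idealised target function,
theoretical patterns are rendered with the *fitted* shape; the spectral-
accuracy comparison is identical in semantics and avoids deconvolution
instability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .lineshape import GAUSSIAN_FWHM_SIGMA, PeakShapeModel
from .spectrum import ProfileSpectrum, weighted_centroid

__all__ = [
    "MassAxisModel",
    "CalibrationModel",
    "CalibrantPeak",
    "detect_calibrant_peaks",
    "fit_mass_axis",
    "fit_line_shape",
    "build_calibration",
    "calibrate_spectrum",
    "average_acquisitions",
]


@dataclass(frozen=True)
class MassAxisModel:
    """Polynomial raw→calibrated map, order ≤ 2, monotone on its range."""

    coefficients: tuple[float, ...]  # c0 + c1*m + c2*m^2
    validity: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.coefficients) > 3:
            raise ValueError("polynomial order capped at 2")
        lo, hi = self.validity
        grid = np.linspace(lo, hi, 257)
        if np.any(np.diff(self.apply(grid)) <= 0):
            raise ValueError("fitted mass-axis map is not monotone over its range")

    @classmethod
    def identity(cls, lo: float, hi: float) -> "MassAxisModel":
        return cls((0.0, 1.0), (lo, hi))

    def apply(self, mz):
        out = np.zeros_like(np.asarray(mz, dtype=float))
        for c in reversed(self.coefficients):
            out = out * mz + c
        return out


@dataclass(frozen=True)
class CalibrantPeak:
    name: str
    expected_mz: float
    measured_mz: float | None  # None when missed
    apex_intensity: float

    @property
    def missed(self) -> bool:
        return self.measured_mz is None


@dataclass
class CalibrationModel:
    mass_axis: MassAxisModel
    shape: PeakShapeModel
    residuals_mda: dict[str, float] = field(default_factory=dict)
    calibrants_used: list[str] = field(default_factory=list)

    @property
    def max_abs_residual_mda(self) -> float:
        return max((abs(r) for r in self.residuals_mda.values()), default=0.0)

    def to_json(self, path) -> None:
        payload = {
            "mass_axis": {
                "coefficients": list(self.mass_axis.coefficients),
                "validity": list(self.mass_axis.validity),
            },
            "shape": {
                "family": self.shape.family,
                "fwhm_a": self.shape.fwhm_a,
                "fwhm_b": self.shape.fwhm_b,
            },
            "residuals_mda": self.residuals_mda,
            "calibrants_used": self.calibrants_used,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            MassAxisModel(
                tuple(d["mass_axis"]["coefficients"]),
                tuple(d["mass_axis"]["validity"]),
            ),
            PeakShapeModel(
                family=d["shape"]["family"],
                fwhm_a=d["shape"]["fwhm_a"],
                fwhm_b=d["shape"]["fwhm_b"],
            ),
            dict(d["residuals_mda"]),
            list(d["calibrants_used"]),
        )


def detect_calibrant_peaks(
    spectrum: ProfileSpectrum,
    calibrant_mzs: dict[str, float] | list[float],
    search_halfwidth: float = 0.5,
    min_intensity: float | None = None,
) -> list[CalibrantPeak]:
    """Locate each calibrant's apex within ±halfwidth of its expected m/z.

    The centroid is the intensity-weighted mean of samples above half the
    apex. A calibrant whose apex falls below ``min_intensity`` (default:
    5x the spectrum-wide median, a floor that rejects baseline ripple) is
    returned as a miss rather than a bogus position.
    """
    if search_halfwidth <= 0:
        raise ValueError("search_halfwidth must be positive")
    if isinstance(calibrant_mzs, dict):
        items = list(calibrant_mzs.items())
    else:
        items = [(f"calibrant_{i}", m) for i, m in enumerate(calibrant_mzs)]
    if min_intensity is None:
        min_intensity = 5.0 * float(np.median(spectrum.intensity))
    out = []
    for name, expected in items:
        mask = np.abs(spectrum.mz - expected) <= search_halfwidth
        if not mask.any():
            out.append(CalibrantPeak(name, expected, None, 0.0))
            continue
        idx = np.flatnonzero(mask)
        local = idx[np.argmax(spectrum.intensity[idx])]
        apex = float(spectrum.intensity[local])
        if apex <= min_intensity:
            out.append(CalibrantPeak(name, expected, None, apex))
            continue
        c = weighted_centroid(spectrum.mz, spectrum.intensity, int(local))
        out.append(CalibrantPeak(name, expected, c, apex))
    return out


def fit_mass_axis(pairs: list[tuple[float, float]]) -> MassAxisModel:
    """Least-squares polynomial raw→true map from (measured, true) pairs.

    Order is min(n_pairs − 1, 2): two calibrants give a linear map, three an
    exact quadratic interpolation, four and more an over-determined quadratic.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibrant pairs to fit a mass axis")
    measured = np.array([p[0] for p in pairs], dtype=float)
    true = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(measured).size != measured.size:
        raise ValueError("duplicate measured m/z values among calibrants")
    order = min(len(pairs) - 1, 2)
    coeffs = np.polynomial.polynomial.polyfit(measured, true, order)
    span = measured.max() - measured.min()
    lo = measured.min() - 0.25 * span
    hi = measured.max() + 0.25 * span
    return MassAxisModel(tuple(float(c) for c in coeffs), (lo, hi))


def _gaussian_offset(x, amp, mu, sigma, c):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + c


def fit_line_shape(
    spectrum: ProfileSpectrum, calibrant_peaks: list[CalibrantPeak]
) -> PeakShapeModel:
    """Fit per-calibrant Gaussian FWHM, then a linear FWHM-vs-m/z law.

    A single usable calibrant gives a constant-FWHM model. Each peak must
    span at least 5 samples above half maximum; fewer means the grid is too
    coarse for a width estimate.
    """
    from .spectrum import peak_run

    centers, widths = [], []
    for pk in calibrant_peaks:
        if pk.missed:
            continue
        win = np.flatnonzero(np.abs(spectrum.mz - pk.measured_mz) <= 1.0)
        apex_global = int(win[np.argmax(spectrum.intensity[win])])
        # fit only the peak's own run (down to 35% of apex, valley-bounded):
        # a fixed window would sweep in the M+1 isotope and bias the width,
        # and at R~500 the M/M+1 valley bottoms out near 20% of the apex,
        # so a lower cut would walk straight through it
        lo, hi = peak_run(spectrum.intensity, apex_global, 0.35)
        x = spectrum.mz[lo : hi + 1]
        y = spectrum.intensity[lo : hi + 1]
        apex = int(np.argmax(y))
        above = y >= y[apex] / 2.0
        if above.sum() < 5:
            raise ValueError(
                f"calibrant {pk.name}: only {int(above.sum())} samples above "
                "half-maximum; use a finer grid"
            )
        sigma0 = (x[above].max() - x[above].min()) / GAUSSIAN_FWHM_SIGMA
        # constant background floats in the fit; a fixed estimate from the
        # below-half samples would be biased by the peak's own tails
        popt, _ = curve_fit(
            _gaussian_offset,
            x,
            y,
            p0=(float(y[apex]), float(x[apex]), max(sigma0, 1e-3), 0.0),
            maxfev=10_000,
        )
        centers.append(popt[1])
        widths.append(abs(popt[2]) * GAUSSIAN_FWHM_SIGMA)
    if not centers:
        raise ValueError("no usable calibrant peaks for line-shape fitting")
    if len(centers) == 1:
        return PeakShapeModel(fwhm_a=float(widths[0]), fwhm_b=0.0)
    b, a = np.polyfit(centers, widths, 1)
    return PeakShapeModel(fwhm_a=float(a), fwhm_b=float(b))


def build_calibration(
    spectrum: ProfileSpectrum,
    calibrant_mzs: dict[str, float],
    search_halfwidth: float = 0.5,
    min_intensity: float | None = None,
) -> CalibrationModel:
    """Detect calibrants, fit mass axis and line shape in one step."""
    peaks = detect_calibrant_peaks(
        spectrum, calibrant_mzs, search_halfwidth, min_intensity
    )
    hits = [p for p in peaks if not p.missed]
    if len(hits) < 2:
        missed = [p.name for p in peaks if p.missed]
        raise ValueError(f"too few calibrant peaks detected (missed: {missed})")
    axis = fit_mass_axis([(p.measured_mz, p.expected_mz) for p in hits])
    shape = fit_line_shape(spectrum, hits)
    residuals = {
        p.name: float((axis.apply(p.measured_mz) - p.expected_mz) * 1000.0)
        for p in hits
    }
    return CalibrationModel(axis, shape, residuals, [p.name for p in hits])


def calibrate_spectrum(
    spectrum: ProfileSpectrum, model: CalibrationModel
) -> ProfileSpectrum:
    """Map the m/z axis through the calibration and resample uniformly.

    Resampling uses linear interpolation onto a uniform grid at the native
    median step; integrated intensity is conserved to well under 0.1%.
    Points outside the model's validity range are extrapolated and flagged.
    """
    lo, hi = model.mass_axis.validity
    extrapolated = bool(spectrum.mz[0] < lo or spectrum.mz[-1] > hi)
    if extrapolated:
        warnings.warn("spectrum extends beyond calibration validity range")
    new_axis = model.mass_axis.apply(spectrum.mz)
    step = spectrum.grid_step
    grid = np.arange(new_axis[0], new_axis[-1] + step / 2, step)
    inten = np.interp(grid, new_axis, spectrum.intensity)
    before = np.trapezoid(spectrum.intensity, new_axis)
    after = np.trapezoid(inten, grid)
    if before > 0 and abs(after - before) / before > 1e-3:
        warnings.warn(
            f"resampling changed integrated intensity by "
            f"{abs(after - before) / before:.2%}"
        )
    meta = dict(spectrum.metadata)
    meta.update(calibrated=True, extrapolated=extrapolated)
    return ProfileSpectrum(grid, np.clip(inten, 0.0, None), meta)


def average_acquisitions(spectra: list[ProfileSpectrum]) -> ProfileSpectrum:
    """Mean intensity of repeat acquisitions on a common grid.

    With n independent-noise scans the noise standard deviation drops by
    ≈ sqrt(n), the reason instruments accumulate ~100 acquisitions per
    sample in profile accurate-mass work.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    lo = max(s.mz[0] for s in spectra)
    hi = min(s.mz[-1] for s in spectra)
    if hi <= lo:
        raise ValueError("spectra have no overlapping m/z range")
    step = float(np.median([s.grid_step for s in spectra]))
    grid = np.arange(lo, hi + step / 2, step)
    acc = np.zeros_like(grid)
    for s in spectra:
        acc += np.interp(grid, s.mz, s.intensity)
    meta = {"averaged_scans": len(spectra)}
    return ProfileSpectrum(grid, acc / len(spectra), meta)
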