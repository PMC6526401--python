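"""One-call composition of the full accurate-mass workflow.

``identify_peak`` takes raw profile scans, a calibrant table and the
approximate position of the peak of interest, and runs:
average → fit calibration → apply it → locate the analyte's monoisotopic
centroid → enumerate formula candidates at that accurate mass → rank them
by spectral accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calibration import (
    CalibrationModel,
    average_acquisitions,
    build_calibration,
    calibrate_spectrum,
)
from .scoring import DEFAULT_WINDOW, _observed_mono_centroid, rank_candidates
from .search import Candidate, CandidateSet, SearchConstraints, enumerate_candidates
from .spectrum import ProfileSpectrum

__all__ = ["IdentificationResult", "identify_peak"]


@dataclass
class IdentificationResult:
    model: CalibrationModel
    calibrated: ProfileSpectrum
    observed_mz: float  # analyte monoisotopic centroid after calibration
    candidates: CandidateSet
    ranked: list[Candidate]

    @property
    def best(self) -> Candidate:
        return self.ranked[0]


def identify_peak(
    scans: list[ProfileSpectrum] | ProfileSpectrum,
    calibrant_mzs: dict[str, float],
    approx_mz: float,
    constraints: SearchConstraints | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    search_halfwidth: float = 0.5,
    min_intensity: float | None = None,
) -> IdentificationResult:
    """Identify the molecular formula of the peak near *approx_mz*.

    *approx_mz* is read off the raw (uncalibrated) spectrum, so the analyte
    is located within ±*search_halfwidth* of its calibrated image. Raises
    when the analyte peak cannot be found after calibration.
    """
    spectrum = (
        scans
        if isinstance(scans, ProfileSpectrum)
        else average_acquisitions(list(scans))
    )
    model = build_calibration(
        spectrum, calibrant_mzs, search_halfwidth, min_intensity
    )
    calibrated = calibrate_spectrum(spectrum, model)
    target = float(model.mass_axis.apply(approx_mz))
    observed = _observed_mono_centroid(calibrated, target, halfwidth=search_halfwidth)
    if observed is None:
        raise ValueError(f"no analyte peak found near calibrated m/z {target:.4f}")
    candidates = enumerate_candidates(observed, constraints)
    if len(candidates) == 0:
        raise ValueError(f"no formula candidates at m/z {observed:.4f}")
    ranked = rank_candidates(calibrated, candidates, model.shape, window)
    return IdentificationResult(model, calibrated, observed, candidates, ranked)
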