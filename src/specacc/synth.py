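"""Synthetic profile-spectrum generator with known ground truth.

Emulates ESI+ profile acquisition on a scanning triple quadrupole: Gaussian
peaks at R_FWHM ≈ 500, a scan range of m/z 150–350, a polynomial mass-axis
distortion (peaks appear at ``m + d(m)``), a constant baseline, additive
Gaussian intensity noise, and optional fixed-m/z interference peaks. Every
stage of the workflow — calibrant detection, axis fitting, line-shape
fitting, windowed spectral-accuracy scoring — can thus be tested against a
known answer without instrument data.

The defaults mirror the acquisition conditions of routine small-molecule
accurate-mass work on a Quattro-class instrument; what they deliberately do
not model is ionisation efficiency, matrix suppression or detector
statistics (see the methods note).
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field, replace

import numpy as np

from .formula import Formula
from .isotopes import isotope_pattern
from .lineshape import PeakShapeModel
from .spectrum import ProfileSpectrum

__all__ = [
    "Species",
    "SimulationConfig",
    "simulate_spectrum",
    "simulate_acquisition_series",
    "write_mzml",
]


@dataclass(frozen=True)
class Species:
    """One simulated ion: a formula (full isotope pattern) or a bare m/z
    (single interference peak), with a relative abundance."""

    ion: Formula | float
    abundance: float = 100.0


@dataclass(frozen=True)
class SimulationConfig:
    species: tuple[Species, ...]
    shape: PeakShapeModel = field(default_factory=PeakShapeModel)
    distortion: tuple[float, ...] = (0.0,)  # raw = true + d(true), order <= 2
    noise_sigma: float = 0.0
    baseline: float = 0.0
    grid_range: tuple[float, float] = (150.0, 350.0)
    grid_step: float = 0.01
    seed: int = 0

    def distort(self, mz: float) -> float:
        d = 0.0
        for c in reversed(self.distortion):
            d = d * mz + c
        return mz + d


def _centroids(config: SimulationConfig) -> list[tuple[float, float]]:
    lo, hi = config.grid_range
    peaks: list[tuple[float, float]] = []
    for sp in config.species:
        if isinstance(sp.ion, Formula):
            pat = isotope_pattern(sp.ion)
            base = config.distort(pat.base_mz)
            if not (lo <= base <= hi):
                raise ValueError(
                    f"species {sp.ion.hill()} base peak at m/z {base:.4f} "
                    "outside grid range"
                )
            for m, a in pat.peaks:
                peaks.append((m, a / 100.0 * sp.abundance))
        else:
            raw = config.distort(float(sp.ion))
            if not (lo <= raw <= hi):
                raise ValueError(
                    f"species peak at m/z {raw:.4f} outside grid range"
                )
            peaks.append((float(sp.ion), sp.abundance))
    # drop (distorted) centroids outside the grid; they cannot contribute
    return [(m, a) for m, a in peaks if lo <= config.distort(m) <= hi]


def simulate_spectrum(config: SimulationConfig) -> ProfileSpectrum:
    """One seeded profile scan. Zero noise ⇒ deterministic render; a fixed
    seed reproduces bit-identical arrays."""
    lo, hi = config.grid_range
    grid = np.arange(lo, hi + config.grid_step / 2, config.grid_step)
    intensity = np.zeros_like(grid)
    for m, area in _centroids(config):
        config.shape.add_peak(grid, intensity, config.distort(m), area)
    intensity += config.baseline
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        intensity = intensity + rng.normal(0.0, config.noise_sigma, grid.size)
    intensity = np.clip(intensity, 0.0, None)
    meta = {"synthetic": True, "seed": config.seed}
    return ProfileSpectrum(grid, intensity, meta)


def simulate_acquisition_series(
    config: SimulationConfig, n_scans: int
) -> list[ProfileSpectrum]:
    """n independent noise realisations; per-scan seeds derive
    deterministically from the master seed."""
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    children = np.random.SeedSequence(config.seed).generate_state(n_scans)
    return [
        simulate_spectrum(replace(config, seed=int(children[i]) % (2**31)))
        for i in range(n_scans)
    ]


# -- minimal mzML writing (fixture-grade: uncompressed 64-bit arrays, the
# subset of the schema the pyteomics reader needs) --------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="synthetic_run">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % values.size, *values)
    return base64.b64encode(raw).decode("ascii")


def write_mzml(spectra: list[ProfileSpectrum], path, mode: str = "profile") -> None:
    """Write scans as minimal mzML readable by standard mzML parsers."""
    mode_param = (
        '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>'
        if mode == "profile"
        else '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
    )
    parts = [_MZML_HEADER.format(count=len(spectra))]
    for i, s in enumerate(spectra):
        mz64, in64 = _b64(s.mz), _b64(s.intensity)
        parts.append(
            f"""      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(s)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        {mode_param}
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(in64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{in64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""
        )
    parts.append(_MZML_FOOTER)
    with open(path, "w") as fh:
        fh.write("".join(parts))
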