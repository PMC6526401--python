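"""Profile-spectrum container and I/O (CSV and mzML).

A profile spectrum is intensity sampled on an ascending m/z grid — the
object a quadrupole scanning in continuum mode produces, as opposed to a
centroided stick spectrum. CSV is the plain two-column interchange format
(header ``mz,intensity``); mzML reading goes through pyteomics and accepts
profile scans only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ProfileSpectrum",
    "read_spectrum",
    "write_csv",
    "centroid",
    "weighted_centroid",
]


@dataclass
class ProfileSpectrum:
    """m/z grid (strictly ascending) with nonnegative finite intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size < 2:
            raise ValueError("spectrum needs at least two samples")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite values in spectrum")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly ascending")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def grid_step(self) -> float:
        return float(np.median(np.diff(self.mz)))

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.mz))

    def slice(self, lo: float, hi: float) -> "ProfileSpectrum":
        mask = (self.mz >= lo) & (self.mz <= hi)
        if mask.sum() < 2:
            raise ValueError(f"window [{lo}, {hi}] outside spectrum range")
        return ProfileSpectrum(self.mz[mask], self.intensity[mask], dict(self.metadata))

    @classmethod
    def repaired(cls, mz, intensity, metadata=None) -> "ProfileSpectrum":
        """Build a spectrum, sorting / de-duplicating / clipping as needed."""
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        order = np.argsort(mz, kind="stable")
        if not np.array_equal(order, np.arange(mz.size)):
            warnings.warn("m/z axis was not sorted; repairing")
            mz, intensity = mz[order], intensity[order]
        keep = np.concatenate(([True], np.diff(mz) > 0))
        if not keep.all():
            warnings.warn("duplicate m/z samples dropped")
            mz, intensity = mz[keep], intensity[keep]
        intensity = np.clip(intensity, 0.0, None)
        return cls(mz, intensity, metadata or {})


def _read_csv(path: Path) -> ProfileSpectrum:
    mz, inten = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    start = 1 if lines[0].lower().replace(" ", "").startswith("mz,") else 0
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            m, i = float(parts[0]), float(parts[1])
        except (IndexError, ValueError):
            raise ValueError(f"{path}: malformed CSV row at line {ln}: {line!r}")
        mz.append(m)
        inten.append(i)
    if not mz:
        raise ValueError(f"{path}: no data rows")
    return ProfileSpectrum.repaired(mz, inten, {"source": str(path)})


# mzML reading is a small self-contained parser (element tree + base64
# arrays) covering the MS1-profile subset this tool consumes: 32/64-bit
# float arrays, uncompressed or zlib. Spectrum mode is taken from the
# profile/centroid cvParams (MS:1000128 / MS:1000127).

_ACC_PROFILE = "MS:1000128"
_ACC_CENTROID = "MS:1000127"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    import base64
    import zlib

    accessions = {
        el.get("accession")
        for el in bda.iter()
        if _localname(el.tag) == "cvParam"
    }
    kind = None
    if _ACC_MZ_ARRAY in accessions:
        kind = "mz"
    elif _ACC_INT_ARRAY in accessions:
        kind = "intensity"
    raw = b""
    for el in bda.iter():
        if _localname(el.tag) == "binary" and el.text:
            raw = base64.b64decode(el.text)
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in accessions else "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path, scan_selector) -> list[ProfileSpectrum]:
    import xml.etree.ElementTree as ET

    tree = ET.parse(str(path))
    spectra = [el for el in tree.getroot().iter() if _localname(el.tag) == "spectrum"]
    out: list[ProfileSpectrum] = []
    for idx, spec in enumerate(spectra):
        if scan_selector != "all" and idx not in scan_selector:
            continue
        accessions = {
            el.get("accession")
            for el in spec
            if _localname(el.tag) == "cvParam"
        }
        if _ACC_CENTROID in accessions:
            raise ValueError(
                f"{path}: scan {idx} is centroided; profile spectra required"
            )
        if _ACC_PROFILE not in accessions:
            raise ValueError(
                f"{path}: scan {idx} does not declare profile mode; "
                "centroid data cannot be calibrated"
            )
        arrays: dict[str, np.ndarray] = {}
        for el in spec.iter():
            if _localname(el.tag) == "binaryDataArray":
                kind, values = _decode_binary_array(el)
                if kind:
                    arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path}: scan {idx} lacks m/z or intensity arrays")
        out.append(
            ProfileSpectrum.repaired(
                arrays["mz"],
                arrays["intensity"],
                {"source": str(path), "scan_index": idx},
            )
        )
    if not out:
        raise ValueError(f"{path}: no matching profile scans")
    return out


def read_spectrum(path, fmt: str | None = None, scan_selector="all") -> list[ProfileSpectrum]:
    """Read profile spectra from CSV or mzML.

    Returns a list (one element for CSV; one per selected scan for mzML).
    ``scan_selector`` is ``"all"`` or an iterable of scan indices.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    kind = fmt or ("mzml" if p.suffix.lower() == ".mzml" else "csv")
    if kind == "csv":
        return [_read_csv(p)]
    if kind == "mzml":
        sel = scan_selector if scan_selector == "all" else set(scan_selector)
        return _read_mzml(p, sel)
    raise ValueError(f"unknown format {kind!r}")


def write_csv(spectrum: ProfileSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("mz,intensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{float(m)!r},{float(i)!r}\n")


def weighted_centroid(mz: np.ndarray, intensity: np.ndarray, apex_idx: int) -> float:
    """Centroid over the contiguous run of samples above 50% of the apex,
    weighted by the intensity excess over the half-maximum.

    The run stops at a valley (intensity turning back up) and is symmetrised
    about the apex, so the flank of a partially resolved neighbour one line
    width away cannot drag the centroid sideways. Weighting by the excess
    over half-maximum (rather than raw intensity) makes the estimate
    insensitive to whether the edge samples just clear the threshold.
    """
    lo, hi = _half_max_run(intensity, apex_idx)
    half = intensity[apex_idx] / 2.0
    w = intensity[lo : hi + 1] - half
    total = float(np.sum(w))
    if total <= 0:
        return float(mz[apex_idx])
    return float(np.sum(mz[lo : hi + 1] * w) / total)


def peak_run(
    intensity: np.ndarray, apex_idx: int, frac: float = 0.5
) -> tuple[int, int]:
    """Contiguous run around *apex_idx* above ``frac`` of the apex,
    truncated at valleys.

    A valley only terminates the walk when intensity rebounds by more than
    15% of the peak prominence above the running minimum — plain "stop on
    any uptick" would truncate at the first noise wiggle near the apex.
    """
    apex = intensity[apex_idx]
    cut = apex * frac
    rebound = 0.15 * (apex - cut)

    def boundary(direction: int) -> int:
        i = apex_idx
        low_idx, low_val = apex_idx, apex
        while 0 <= i + direction < intensity.size and intensity[i + direction] >= cut:
            i += direction
            if intensity[i] < low_val:
                low_idx, low_val = i, intensity[i]
            elif intensity[i] > low_val + rebound:
                return low_idx  # crossed a valley into a neighbouring peak
        return i

    return boundary(-1), boundary(+1)


def _half_max_run(intensity: np.ndarray, apex_idx: int) -> tuple[int, int]:
    """Half-maximum run, symmetrised about the apex (for centroiding)."""
    lo, hi = peak_run(intensity, apex_idx, 0.5)
    reach = min(apex_idx - lo, hi - apex_idx)
    return apex_idx - reach, apex_idx + reach


def centroid(
    spectrum: ProfileSpectrum, threshold: float = 0.0
) -> list[tuple[float, float]]:
    """Centroided peak list: local maxima above *threshold*.

    Each peak's position starts from the intensity-weighted mean of the
    samples above half its apex (the estimator the calibration step uses),
    then a refinement pass subtracts every *other* peak's Gaussian
    reconstruction before re-centroiding — a partially resolved cluster
    (e.g. M+1 one line width from a tenfold-taller M) would otherwise pull
    centroids a few mTh toward its heavier neighbour.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    x = spectrum.mz
    y = spectrum.intensity
    found: list[tuple[int, float]] = []  # (apex index, first-pass centroid)
    for i in range(1, y.size - 1):
        if y[i] > threshold and y[i] >= y[i - 1] and y[i] > y[i + 1]:
            found.append((i, weighted_centroid(x, y, i)))
    if len(found) <= 1:
        return [(c, float(y[i])) for i, c in found]
    # per-peak Gaussian reconstruction from apex height and half-max width
    models = []
    for i, c in found:
        lo, hi = _half_max_run(y, i)
        width = max(x[hi] - x[lo], x[1] - x[0])
        models.append((c, float(y[i]), width / 2.3548))
    peaks = []
    for k, (i, _) in enumerate(found):
        rest = y.copy()
        for j, (c, h, sigma) in enumerate(models):
            if j != k:
                rest -= h * np.exp(-0.5 * ((x - c) / sigma) ** 2)
        rest = np.clip(rest, 0.0, None)
        peaks.append((weighted_centroid(x, rest, i), float(y[i])))
    return peaks
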