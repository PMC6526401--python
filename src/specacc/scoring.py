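"""Spectral accuracy: scoring calibrated profile windows against candidate
isotope patterns, and producing the ranked candidate table.

Spectral accuracy (SA) quantifies how well an observed, calibrated profile
isotope pattern matches a candidate formula's theoretical pattern rendered
in the fitted instrument line shape. With observed window o and theoretical
profile t on a common grid,

    SA = 100 * (1 - ||o - s*t|| / ||o||),   s = argmin_{s>=0} ||o - s*t||,

clipped below at 0. A perfect fit scores 100%; disjoint patterns score 0%.
The root-mean-square residual of the optimally scaled theoretical pattern
relative to the observed norm is the driving quantity, so SA is invariant to
rescaling either spectrum.

The window is taken relative to the candidate's monoisotopic peak, by
default −0.5 to +3.5 Da so the M, M+1, M+2 and M+3 isotopic peaks all enter
the comparison. Interference peaks inside that window depress SA; narrowing
the window (e.g. to +2.5 Da) excludes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formula import mass_accuracy
from .isotopes import isotope_pattern
from .lineshape import PeakShapeModel
from .search import Candidate, CandidateSet
from .spectrum import ProfileSpectrum, weighted_centroid

__all__ = [
    "ProfileWindow",
    "extract_window",
    "spectral_accuracy",
    "rank_candidates",
    "report",
    "summary_string",
]

DEFAULT_WINDOW = (-0.5, 3.5)


@dataclass
class ProfileWindow:
    """Baseline-subtracted sub-spectrum around a monoisotopic peak."""

    mono_mz: float
    start: float  # Da relative to mono, < 0
    end: float  # Da relative to mono, > 0
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def is_empty(self) -> bool:
        return bool(np.all(self.intensity == 0))


def extract_window(
    calibrated: ProfileSpectrum,
    mono_mz: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> ProfileWindow:
    """Extract [mono+start, mono+end], subtract baseline, floor at zero.

    The baseline is the median of the lowest decile of intensities inside
    the window — robust to isotope peaks occupying most of the window while
    still tracking a constant background pedestal.
    """
    start, end = window
    if not (start < 0 < end):
        raise ValueError("window must satisfy start < 0 < end")
    sub = calibrated.slice(mono_mz + start, mono_mz + end)
    return ProfileWindow(mono_mz, start, end, sub.mz, _subtract_floor(sub.intensity))


def _subtract_floor(y: np.ndarray) -> np.ndarray:
    """Lowest-decile-median baseline subtraction, floored at zero."""
    k = max(1, y.size // 10)
    baseline = float(np.median(np.sort(y)[:k]))
    return np.clip(y - baseline, 0.0, None)


def spectral_accuracy(
    observed: ProfileWindow, theoretical: ProfileSpectrum
) -> float | None:
    """SA in percent, or None when the observed window carries no signal."""
    o = observed.intensity.astype(float)
    norm_o = float(np.linalg.norm(o))
    if norm_o == 0.0:
        return None
    t = np.interp(observed.mz, theoretical.mz, theoretical.intensity, left=0.0, right=0.0)
    tt = float(t @ t)
    s = max(0.0, float(o @ t) / tt) if tt > 0 else 0.0
    residual = float(np.linalg.norm(o - s * t))
    return max(0.0, 100.0 * (1.0 - residual / norm_o))


def _observed_mono_centroid(
    calibrated: ProfileSpectrum, exact_mz: float, halfwidth: float = 0.3
) -> float | None:
    mask = np.abs(calibrated.mz - exact_mz) <= halfwidth
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    local = int(idx[np.argmax(calibrated.intensity[idx])])
    if calibrated.intensity[local] <= 0:
        return None
    return weighted_centroid(calibrated.mz, calibrated.intensity, local)


def rank_candidates(
    calibrated: ProfileSpectrum,
    candidates: CandidateSet,
    shape: PeakShapeModel,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> list[Candidate]:
    """Score every candidate's SA against the calibrated spectrum and rank.

    Each candidate's theoretical pattern is rendered in the fitted line
    shape directly on the observed grid of its own window. Δm is recomputed
    from the observed monoisotopic centroid within ±0.3 Th of the
    candidate's exact m/z. Ranking is by SA descending, ties by smaller
    |Δm| then Hill string; candidates with undefined SA sink to the bottom
    flagged as such.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    scored: list[Candidate] = []
    for cand in candidates:
        pattern = isotope_pattern(cand.formula)
        obs = extract_window(calibrated, cand.exact_mz, window)
        grid = obs.mz
        theo = np.zeros_like(grid)
        for m, a in pattern.peaks:
            shape.add_peak(grid, theo, m, a)
        # identical baseline treatment on both sides: the windowing also
        # strips the theoretical profile's own tail-overlap floor, so a
        # correct candidate fits its own data at SA ~ 100
        theo_spec = ProfileSpectrum(grid, _subtract_floor(theo), {"rendered": True})
        sa = spectral_accuracy(obs, theo_spec)
        mono_obs = _observed_mono_centroid(calibrated, cand.exact_mz)
        delta = (
            mass_accuracy(mono_obs, cand.exact_mz)
            if mono_obs is not None
            else cand.delta_m_mda
        )
        scored.append(
            Candidate(
                formula=cand.formula,
                exact_mz=cand.exact_mz,
                delta_m_mda=delta,
                rdbe=cand.rdbe,
                sa=sa,
                sa_undefined=sa is None,
            )
        )
    scored.sort(
        key=lambda c: (
            c.sa_undefined,
            -(c.sa if c.sa is not None else 0.0),
            abs(c.delta_m_mda),
            c.formula.hill(),
        )
    )
    for i, c in enumerate(scored, start=1):
        c.rank = i
    return scored


def summary_string(ranked: list[Candidate], formula_hill: str) -> str:
    """"rank/total" for the given formula, e.g. ``"5/14"``."""
    for c in ranked:
        if c.formula.hill() == formula_hill:
            return f"{c.rank}/{len(ranked)}"
    raise ValueError(f"{formula_hill} not among the ranked candidates")


_COLUMNS = ("rank", "formula", "exact_mz", "delta_m_mda", "rdbe", "sa")


def report(ranked: list[Candidate], path=None, fmt: str = "tsv"):
    """Render the ranked table as TSV text or a JSON-able list of dicts.

    Returns the artifact (string for TSV, list for JSON); writes it to
    *path* when given.
    """
    rows = [
        {
            "rank": c.rank,
            "formula": c.formula.hill(),
            "exact_mz": round(c.exact_mz, 4),
            "delta_m_mda": round(c.delta_m_mda, 1),
            "rdbe": c.rdbe,
            "sa": None if c.sa is None else round(c.sa, 1),
        }
        for c in ranked
    ]
    if fmt == "json":
        artifact = rows
        text = __import__("json").dumps(rows, indent=2)
    elif fmt == "tsv":
        lines = ["\t".join(_COLUMNS)]
        for r in rows:
            lines.append(
                "\t".join("" if r[c] is None else str(r[c]) for c in _COLUMNS)
            )
        artifact = text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return artifact


def parse_report_tsv(text: str) -> list[dict]:
    """Parse a TSV report back into row dicts (inverse of :func:`report`)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    out = []
    for ln in lines[1:]:
        vals = ln.split("\t")
        row = dict(zip(header, vals))
        row["rank"] = int(row["rank"])
        for k in ("exact_mz", "delta_m_mda", "rdbe", "sa"):
            row[k] = float(row[k]) if row[k] != "" else None
        out.append(row)
    return out
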