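"""Exhaustive molecular-formula candidate enumeration.

Given a target m/z, a mass tolerance and per-element count ranges, this
enumerates every ion composition in the constraint box whose exact m/z falls
inside the tolerance and whose RDBE and electron configuration pass. Ion
compositions are enumerated directly (adduct atoms included, electron mass
applied per charge), matching how candidate tables list sodiated species.

The enumerator is a depth-first scan over elements in order of decreasing
atomic mass with branch-and-bound pruning on the achievable mass of the
remaining elements; it is exact (no heuristics) and fast at small-molecule
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .elements import ELECTRON_MASS, ElementIsotopeTable, default_table
from .formula import Formula, rdbe

__all__ = [
    "SearchConstraints",
    "Candidate",
    "CandidateSet",
    "enumerate_candidates",
    "electron_parity",
    "qqq2018_constraints",
]


@dataclass(frozen=True)
class SearchConstraints:
    """Element ranges and filters for formula search.

    The defaults are the standard ESI+ small-molecule search box used with
    triple-quadrupole accurate-mass work: C 2–25, H 0–50, N 0–10, O 0–10,
    Na 0–1, Cl 0–5, tolerance ±10 mDa, charge +1, RDBE −0.5 to 20,
    even-electron ions only.
    """

    elements: tuple[tuple[str, int, int], ...] = (
        ("C", 2, 25),
        ("H", 0, 50),
        ("N", 0, 10),
        ("O", 0, 10),
        ("Na", 0, 1),
        ("Cl", 0, 5),
    )
    tolerance_mda: float = 10.0
    charge: int = 1
    rdbe_min: float = -0.5
    rdbe_max: float = 20.0
    electron: str = "even"  # even | odd | both
    max_candidates: int = 100_000

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("element box is empty")
        for sym, lo, hi in self.elements:
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid range {lo}-{hi} for element {sym}")
        if self.tolerance_mda <= 0:
            raise ValueError("tolerance must be positive")
        if self.electron not in ("even", "odd", "both"):
            raise ValueError("electron must be 'even', 'odd' or 'both'")

    @classmethod
    def from_element_string(cls, spec: str, **kwargs) -> "SearchConstraints":
        """Parse ranges like ``"C2-25,H0-50,N0-10,O0-10,Na0-1,Cl0-5"``."""
        import re

        elements = []
        for part in spec.split(","):
            m = re.fullmatch(r"\s*([A-Z][a-z]?)(\d+)-(\d+)\s*", part)
            if not m:
                raise ValueError(f"cannot parse element range {part!r}")
            elements.append((m.group(1), int(m.group(2)), int(m.group(3))))
        return cls(elements=tuple(elements), **kwargs)


def qqq2018_constraints(**overrides) -> SearchConstraints:
    """The package's default search preset (see :class:`SearchConstraints`)."""
    return replace(SearchConstraints(), **overrides) if overrides else SearchConstraints()


@dataclass
class Candidate:
    """One candidate ion formula with its exact mass and scores."""

    formula: Formula
    exact_mz: float
    delta_m_mda: float
    rdbe: float
    sa: float | None = None
    sa_undefined: bool = False
    rank: int | None = None


@dataclass
class CandidateSet:
    target_mz: float
    constraints: SearchConstraints
    candidates: list[Candidate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def formulas(self) -> set[str]:
        return {c.formula.hill() for c in self.candidates}


def electron_parity(ion: Formula) -> str:
    """``"even"`` or ``"odd"`` electron configuration of an ion.

    Under the fixed valence model, a singly charged (odd |z|) cation is
    even-electron iff its RDBE is half-integer; neutrals and even-|z| ions
    are even-electron iff RDBE is integer.
    """
    r = rdbe(ion)
    half_integer = abs((2 * r) % 2) == 1
    if abs(ion.charge) % 2 == 1:
        return "even" if half_integer else "odd"
    return "even" if not half_integer else "odd"


def enumerate_candidates(
    target_mz: float,
    constraints: SearchConstraints | None = None,
    table: ElementIsotopeTable | None = None,
) -> CandidateSet:
    """All ion formulas in the constraint box within the mass tolerance.

    Exhaustive and deterministic: results are ordered by ascending \\|Δm\\|,
    ties broken by Hill string. Raises if the search would exceed
    ``constraints.max_candidates``.
    """
    if target_mz <= 0:
        raise ValueError("target m/z must be positive")
    cons = constraints or SearchConstraints()
    t = table or default_table()
    z = cons.charge
    if z == 0:
        raise ValueError("charge must be nonzero")

    # Target neutral-atom mass sum for the ion composition.
    target_sum = target_mz * abs(z) + z * ELECTRON_MASS
    tol = cons.tolerance_mda / 1000.0 * abs(z)

    order = sorted(cons.elements, key=lambda e: -t.monoisotopic(e[0]))
    masses = [t.monoisotopic(sym) for sym, _, _ in order]
    # min/max achievable mass of the tail starting at element i
    n = len(order)
    min_tail = [0.0] * (n + 1)
    max_tail = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        _, lo, hi = order[i]
        min_tail[i] = min_tail[i + 1] + lo * masses[i]
        max_tail[i] = max_tail[i + 1] + hi * masses[i]

    found: list[Candidate] = []
    counts: dict[str, int] = {}

    def visit(i: int, acc: float) -> None:
        if i == n:
            if not any(counts.values()):
                return
            mz = (acc - z * ELECTRON_MASS) / abs(z)
            ion = Formula.from_counts(counts, z)
            r = rdbe(ion)
            if not (cons.rdbe_min <= r <= cons.rdbe_max):
                return
            if cons.electron != "both" and electron_parity(ion) != cons.electron:
                return
            delta = (mz - target_mz) * 1000.0
            found.append(Candidate(ion, mz, delta, r))
            if len(found) > cons.max_candidates:
                raise ValueError(
                    "candidate cap exceeded; narrow the tolerance or element box"
                )
            return
        sym, lo, hi = order[i]
        m = masses[i]
        for c in range(lo, hi + 1):
            mass_here = acc + c * m
            if mass_here + min_tail[i + 1] > target_sum + tol:
                break  # heavier counts only overshoot further
            if mass_here + max_tail[i + 1] < target_sum - tol:
                continue
            counts[sym] = c
            visit(i + 1, mass_here)
        counts.pop(sym, None)

    visit(0, 0.0)
    found.sort(key=lambda c: (abs(c.delta_m_mda), c.formula.hill()))
    return CandidateSet(target_mz, cons, found)
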