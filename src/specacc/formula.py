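"""Molecular-formula algebra: parsing, Hill notation, exact masses, adducts,
RDBE, and mass-accuracy arithmetic.

Conventions used throughout:

* monoisotopic mass is the neutral-atom sum over the most abundant isotope of
  each element (charge ignored);
* ion m/z subtracts one electron mass per positive charge (adds per negative),
  then divides by |z|;
* RDBE of C_c H_h N_n O_o Na_na Cl_cl is ``c + 1 + (n - h - cl - na)/2`` —
  the standard valence model with O contributing zero and Na treated like H,
  so fully saturated protonated/cationised even-electron species reach the
  -0.5 floor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .elements import ELECTRON_MASS, ElementIsotopeTable, default_table

__all__ = [
    "Formula",
    "AdductSpec",
    "ADDUCTS",
    "monoisotopic_mass",
    "ion_mz",
    "rdbe",
    "mass_accuracy",
    "VALENCES",
]

# Valences for ring/double-bond counting. O contributes (2-2)/2 = 0;
# monovalent atoms (H, Cl, Na, F) each remove half an equivalent.
VALENCES: dict[str, int] = {
    "C": 4, "H": 1, "N": 3, "O": 2, "Na": 1, "Cl": 1, "P": 3, "S": 2, "F": 1,
}

_HILL_FIRST = ("C", "H")

# Strip the decorations of typeset formulas ("C_13_H_20_NO^+^", unicode
# sub/superscripts) before tokenising.
_SUBSCRIPTS = str.maketrans("₀₁₂₃₄₅₆₇₈₉⁰¹²³⁴⁵⁶⁷⁸⁹⁺⁻", "01234567890123456789+-")
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
# Charge is a trailing run of identical signs ("+", "--"); a digit before the
# sign always belongs to the preceding element count, so "NH4+" is H4, z=+1.
_CHARGE = re.compile(r"([+-]+)•?$")


@dataclass(frozen=True)
class Formula:
    """Element-count map with an integer charge.

    Immutable; counts are nonnegative and at least one must be positive.
    """

    counts: tuple[tuple[str, int], ...]
    charge: int = 0
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if any(n < 0 for _, n in self.counts):
            raise ValueError("element counts must be nonnegative")
        if not any(n > 0 for _, n in self.counts):
            raise ValueError("formula must contain at least one atom")

    @classmethod
    def from_counts(
        cls, counts: dict[str, int], charge: int = 0, label: str | None = None
    ) -> "Formula":
        items = tuple(sorted((e, n) for e, n in counts.items() if n > 0))
        return cls(items, charge, label)

    @classmethod
    def parse(cls, text: str, label: str | None = None) -> "Formula":
        """Parse a Hill-style formula string, e.g. ``"C13H20NO+"``.

        Also accepts typeset variants like ``"C_13_H_20_NO^+^"`` by
        normalising underscores, carets and unicode sub/superscripts.
        """
        s = text.translate(_SUBSCRIPTS).replace("_", "").replace("^", "").strip()
        charge = 0
        m = _CHARGE.search(s)
        if m:
            signs = m.group(1)
            if len(set(signs)) > 1:
                raise ValueError(f"mixed charge signs in {text!r}")
            charge = len(signs) if signs[0] == "+" else -len(signs)
            s = s[: m.start()]
        if not s:
            raise ValueError(f"cannot parse formula from {text!r}")
        counts: dict[str, int] = {}
        pos = 0
        for m in _TOKEN.finditer(s):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} near {s[pos:]!r}")
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(s):
            raise ValueError(f"cannot parse formula {text!r} near {s[pos:]!r}")
        return cls.from_counts(counts, charge, label)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def count(self, symbol: str) -> int:
        return dict(self.counts).get(symbol, 0)

    @property
    def atom_count(self) -> int:
        return sum(n for _, n in self.counts)

    def hill(self) -> str:
        """Canonical Hill rendering: C, H, then alphabetical; charge suffix."""
        d = self.as_dict()
        parts = []
        for sym in _HILL_FIRST:
            if d.get(sym):
                n = d.pop(sym)
                parts.append(sym + (str(n) if n > 1 else ""))
        for sym in sorted(d):
            if d[sym]:
                parts.append(sym + (str(d[sym]) if d[sym] > 1 else ""))
        body = "".join(parts)
        z = self.charge
        if z == 0:
            return body
        return body + ("+" if z > 0 else "-") * abs(z)

    def __str__(self) -> str:
        return self.hill()

    def __add__(self, other: "Formula") -> "Formula":
        d = self.as_dict()
        for e, n in other.counts:
            d[e] = d.get(e, 0) + n
        return Formula.from_counts(d, self.charge + other.charge)

    def __sub__(self, other: "Formula") -> "Formula":
        d = self.as_dict()
        for e, n in other.counts:
            d[e] = d.get(e, 0) - n
            if d[e] < 0:
                raise ValueError(f"cannot remove {n} {e} from {self.hill()}")
        return Formula.from_counts(d, self.charge - other.charge)

    def with_charge(self, charge: int) -> "Formula":
        return Formula(self.counts, charge, self.label)


@dataclass(frozen=True)
class AdductSpec:
    """An ESI adduct: atoms added to the neutral and the charge it carries."""

    name: str
    delta: tuple[tuple[str, int], ...]
    charge_delta: int

    @classmethod
    def make(cls, name: str, delta: dict[str, int], charge_delta: int) -> "AdductSpec":
        return cls(name, tuple(sorted(delta.items())), charge_delta)

    def apply(self, neutral: Formula) -> Formula:
        d = neutral.as_dict()
        for e, n in self.delta:
            d[e] = d.get(e, 0) + n
        return Formula.from_counts(d, neutral.charge + self.charge_delta)

    def remove(self, ion: Formula) -> Formula:
        d = ion.as_dict()
        for e, n in self.delta:
            d[e] = d.get(e, 0) - n
            if d[e] < 0:
                raise ValueError(f"ion {ion.hill()} lacks the {self.name} atoms")
        return Formula.from_counts(d, ion.charge - self.charge_delta)


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec.make("[M+H]+", {"H": 1}, +1),
    "[M+Na]+": AdductSpec.make("[M+Na]+", {"Na": 1}, +1),
    "[M-H]-": AdductSpec.make("[M-H]-", {"H": -1}, -1),
}


def monoisotopic_mass(
    formula: Formula, table: ElementIsotopeTable | None = None
) -> float:
    """Neutral-atom monoisotopic mass in Da (charge ignored)."""
    t = table or default_table()
    total = 0.0
    for sym, n in formula.counts:
        if sym not in t:
            raise KeyError(f"unknown element symbol {sym!r}")
        total += n * t.monoisotopic(sym)
    return total


def ion_mz(
    neutral: Formula,
    adduct: AdductSpec,
    table: ElementIsotopeTable | None = None,
) -> float:
    """m/z of the adduct ion, with electron-mass correction.

    ``(mass(neutral + adduct atoms) - z * m_e) / z`` for positive z;
    electrons are added back for negative ions.
    """
    ion = adduct.apply(neutral)
    return ion_formula_mz(ion, table)


def ion_formula_mz(ion: Formula, table: ElementIsotopeTable | None = None) -> float:
    """m/z of an ion given directly as its full atomic composition."""
    z = ion.charge
    if z == 0:
        raise ValueError("ion has zero charge; m/z undefined")
    m = monoisotopic_mass(ion, table) - z * ELECTRON_MASS
    return m / abs(z)


def rdbe(ion: Formula) -> float:
    """Rings-plus-double-bonds equivalent under the fixed valence model.

    Half-integer for even-electron singly charged CHNONaCl cations, integer
    for neutrals. Raises for elements without an assigned valence.
    """
    total = 1.0
    for sym, n in ion.counts:
        try:
            v = VALENCES[sym]
        except KeyError:
            raise ValueError(f"no valence assigned for element {sym!r}") from None
        total += n * (v - 2) / 2.0
    return total


def mass_accuracy(measured_mz: float, exact_mz: float) -> float:
    """Mass error Δm = (measured − exact) in mDa, reported to 0.1 mDa."""
    import math

    if not (math.isfinite(measured_mz) and math.isfinite(exact_mz)):
        raise ValueError("m/z values must be finite")
    return round((measured_mz - exact_mz) * 1000.0, 1)
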