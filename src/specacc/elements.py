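"""Element and isotope reference data.

A pinned isotope table (monoisotopic masses and natural abundances) is
vendored as JSON so that exact-mass results are reproducible independent of
whatever reference tables other installed libraries carry. The table covers
the CHNONaCl chemistry of ESI+ small-molecule work plus P and S.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["Isotope", "ElementIsotopeTable", "default_table", "ELECTRON_MASS"]


@dataclass(frozen=True)
class Isotope:
    mass: float  # Da
    abundance: float  # fraction in [0, 1]


@dataclass
class ElementIsotopeTable:
    """Symbol -> isotopes (mass-ascending), plus the electron mass constant."""

    isotopes: dict[str, tuple[Isotope, ...]]
    electron_mass: float
    version: str = "unversioned"
    _mono: dict[str, float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for sym, isos in self.isotopes.items():
            if not isos:
                raise ValueError(f"element {sym!r} has no isotopes")
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"abundances for {sym!r} sum to {total}, expected 1 within 1e-6"
                )
            masses = [i.mass for i in isos]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"isotope masses for {sym!r} not strictly increasing")
            self._mono[sym] = max(isos, key=lambda i: i.abundance).mass

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.isotopes

    def monoisotopic(self, symbol: str) -> float:
        """Mass of the most abundant isotope of *symbol*, in Da."""
        try:
            return self._mono[symbol]
        except KeyError:
            raise KeyError(f"unknown element symbol {symbol!r}") from None

    def distribution(self, symbol: str) -> tuple[Isotope, ...]:
        try:
            return self.isotopes[symbol]
        except KeyError:
            raise KeyError(f"unknown element symbol {symbol!r}") from None


def _load() -> ElementIsotopeTable:
    text = resources.files("specacc.data").joinpath("isotopes.json").read_text()
    raw = json.loads(text)
    isotopes = {
        sym: tuple(Isotope(m, a) for m, a in entries)
        for sym, entries in raw["elements"].items()
    }
    return ElementIsotopeTable(
        isotopes=isotopes,
        electron_mass=raw["electron_mass_da"],
        version=raw["version"],
    )


_DEFAULT = _load()

ELECTRON_MASS: float = _DEFAULT.electron_mass


def default_table() -> ElementIsotopeTable:
    """The vendored reference table shipped with the package."""
    return _DEFAULT
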