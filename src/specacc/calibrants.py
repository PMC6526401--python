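"""Registry of internal mass calibrants.

Ships the six routine ESI+ calibrants (caffeine, atrazine, cyclophosphamide,
metoprolol, avobenzone, benzylbutyl phthalate) with their neutral formulas
and default adducts; additional registries load from the same CSV layout
(columns ``name,neutral_formula,adduct``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .formula import ADDUCTS, AdductSpec, Formula, ion_mz, monoisotopic_mass

__all__ = ["Calibrant", "load_calibrants", "default_calibrants"]


@dataclass(frozen=True)
class Calibrant:
    name: str
    neutral: Formula
    adduct: AdductSpec

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.neutral)

    @property
    def ion_mz(self) -> float:
        return ion_mz(self.neutral, self.adduct)

    @property
    def ion(self) -> Formula:
        return self.adduct.apply(self.neutral)


def _parse_rows(rows) -> list[Calibrant]:
    out = []
    for row in rows:
        adduct = ADDUCTS[row["adduct"].strip()]
        out.append(
            Calibrant(
                row["name"].strip(),
                Formula.parse(row["neutral_formula"].strip()),
                adduct,
            )
        )
    if not out:
        raise ValueError("calibrant file contains no rows")
    return out


def load_calibrants(path) -> list[Calibrant]:
    with open(Path(path), newline="") as fh:
        return _parse_rows(csv.DictReader(fh))


def default_calibrants() -> list[Calibrant]:
    text = resources.files("specacc.data").joinpath("calibrants.csv").read_text()
    return _parse_rows(csv.DictReader(text.splitlines()))
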