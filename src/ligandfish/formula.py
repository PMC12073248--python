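"""Exact-mass chemistry arithmetic.

Everything downstream of a molecular formula lives here: parsing, monoisotopic
and average mass, ESI adduct m/z, ppm mass error, double-bond equivalents
(DBE), and mg/mL -> µM conversion.  All mass constants used anywhere in the
package are defined in this module so every consumer shares one table.

The formula grammar is deliberately narrow: element symbols from the CHNOSP
set, each optionally followed by a positive integer count.  Isotope labels,
charges and parenthesised groups are rejected loudly rather than guessed at.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "ATOMIC_WEIGHT",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ADDUCTS",
    "FormulaError",
    "ElementalComposition",
    "AdductSpec",
    "MassAssignment",
    "parse_formula",
    "monoisotopic_mass",
    "average_mass",
    "adduct_mz",
    "ppm_error",
    "dbe",
    "mass_conc_to_molar",
]

#: Mass of the most abundant isotope of each supported element (Da).
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}

#: IUPAC 2021 conventional atomic weights (Da), used for molarity conversion.
ATOMIC_WEIGHT: Mapping[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

ELECTRON_MASS = 0.00054858
#: Mass of the charge carrier (H atom minus an electron); the single constant
#: from which both adduct shifts are derived so that
#: mz([M+H]+) - mz([M-H]-) == 2 * PROTON_MASS holds exactly.
PROTON_MASS = 1.00727646


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


@dataclass(frozen=True)
class ElementalComposition:
    """An element -> count map in canonical (Hill) order.

    Hill order puts carbon first, then hydrogen, then all remaining elements
    alphabetically; for carbon-free formulas all elements sort alphabetically.
    """

    items: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise FormulaError("empty composition")
        for element, count in self.items:
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element {element!r}")
            if count <= 0:
                raise FormulaError(f"non-positive count for element {element!r}")
        object.__setattr__(self, "items", _hill_sorted(dict(self.items)))

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ElementalComposition":
        return cls(tuple(counts.items()))

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.items)

    def get(self, element: str) -> int:
        return dict(self.items).get(element, 0)

    def __str__(self) -> str:
        out = []
        for element, count in self.items:
            out.append(element if count == 1 else f"{element}{count}")
        return "".join(out)


def _hill_sorted(counts: Mapping[str, int]) -> tuple[tuple[str, int], ...]:
    elements = sorted(counts)
    ordered: list[str] = []
    if "C" in counts:
        ordered.append("C")
        if "H" in counts:
            ordered.append("H")
        ordered.extend(e for e in elements if e not in ("C", "H"))
    else:
        ordered = elements
    return tuple((e, int(counts[e])) for e in ordered)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalComposition:
    """Parse a molecular formula such as ``"C6H12O7"``.

    Counts accumulate if an element repeats.  Unknown element symbols, zero
    counts and any other leftover characters raise :class:`FormulaError`
    naming the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"unexpected token {text[pos:match.start()]!r} in {text!r}")
        element, digits = match.groups()
        if not element:
            continue
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element {element!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for element {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
        if pos == len(text):
            break
    if pos != len(text):
        raise FormulaError(f"unexpected token {text[pos:]!r} in {text!r}")
    return ElementalComposition.from_counts(counts)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Exact (monoisotopic) neutral mass in Da."""
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in comp.items)


def average_mass(comp: ElementalComposition) -> float:
    """Average molecular weight in Da from conventional atomic weights."""
    return sum(ATOMIC_WEIGHT[e] * n for e, n in comp.items)


@dataclass(frozen=True)
class AdductSpec:
    """An ESI adduct: name, ion-mode polarity, and signed mass shift (Da)."""

    name: str
    polarity: str
    mass_shift: float


#: The two adducts the screen works with.  Electron mass is accounted for:
#: the shift is the mass of the charge carrier (proton), not of a hydrogen atom.
ADDUCTS: Mapping[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", "negative", -PROTON_MASS),
    "[M+H]+": AdductSpec("[M+H]+", "positive", +PROTON_MASS),
}

# Unicode minus signs as they appear in the literature.
_ADDUCT_ALIASES = {
    "[M−H]−": "[M-H]-",
    "[M−H]-": "[M-H]-",
    "[M-H]−": "[M-H]-",
    "[M + H]+": "[M+H]+",
    "[M + H]+": "[M+H]+",
}


def resolve_adduct(adduct: "str | AdductSpec") -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    name = _ADDUCT_ALIASES.get(adduct, adduct)
    try:
        return ADDUCTS[name]
    except KeyError:
        raise FormulaError(f"unknown adduct {adduct!r}") from None


def adduct_mz(neutral_mass: float, adduct: "str | AdductSpec") -> float:
    """m/z of a singly charged adduct of a neutral of the given exact mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return neutral_mass + resolve_adduct(adduct).mass_shift


def ppm_error(theoretical: float, experimental: float) -> float:
    """Relative mass error in parts per million.

    Sign convention: (theoretical - experimental) / theoretical * 1e6, so an
    experimental mass above the theoretical one yields a negative error — the
    dominant sign pattern in QTOF accuracy tables.
    """
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (theoretical - experimental) / theoretical * 1e6


def dbe(comp: ElementalComposition) -> float:
    """Double-bond equivalents (rings plus double bonds).

    DBE = C - H/2 + N/2 + 1.  Oxygen and sulfur are divalent and do not
    contribute; phosphorus is treated as trivalent (+1/2 each).  Half-integer
    results (odd-electron species) are returned as-is.
    """
    value = (
        comp.get("C")
        - comp.get("H") / 2.0
        + comp.get("N") / 2.0
        + comp.get("P") / 2.0
        + 1.0
    )
    return value


@dataclass(frozen=True)
class MassAssignment:
    """Bookkeeping for one theoretical-vs-measured mass comparison."""

    theoretical_mz: float
    experimental_mz: float
    error_ppm: float
    dbe: float

    @classmethod
    def from_masses(
        cls, theoretical_mz: float, experimental_mz: float, comp: ElementalComposition
    ) -> "MassAssignment":
        return cls(
            theoretical_mz=theoretical_mz,
            experimental_mz=experimental_mz,
            error_ppm=ppm_error(theoretical_mz, experimental_mz),
            dbe=dbe(comp),
        )


def mass_conc_to_molar(conc_mg_per_ml: float, comp: ElementalComposition) -> float:
    """Convert a mass concentration (mg/mL) to µM via the average mass."""
    if conc_mg_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_mg_per_ml * 1e6 / average_mass(comp)
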