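"""Molecular formulas, monoisotopic masses and m/z bookkeeping.

All masses are neutral monoisotopic masses in daltons: the sum, over the
atoms of a molecule, of the exact mass of each element's lightest stable
isotope.  Features acquired in negative electrospray are observed as the
deprotonated ion [M-H]-, so the neutral mass of a feature is its m/z plus
the mass of a proton (the electron stays on the ion, hence the proton
mass rather than the hydrogen-atom mass).

The isotope masses are bundled as a small delimited text table
(``data/isotope_masses.tsv``) so that mass computation never depends on a
runtime lookup; only the elements C, H, N, O, P and S are supported, which
covers every compound in the bundled willow-bark library.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping

__all__ = [
    "PROTON_MASS",
    "Formula",
    "FormulaError",
    "isotope_masses",
    "parse_formula",
    "monoisotopic_mass",
    "neutral_from_negmode_mz",
    "mz_from_neutral",
    "ppm_delta",
]

#: Mass of a proton in Da (CODATA).  Used for [M-H]- neutralization.
PROTON_MASS = 1.00727646688

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


def isotope_masses() -> Dict[str, float]:
    """Load the bundled lightest-isotope exact-mass table (element -> Da)."""
    text = (
        resources.files("salixfate.data").joinpath("isotope_masses.tsv").read_text()
    )
    masses: Dict[str, float] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        element, mass = line.split("\t")
        masses[element] = float(mass)
    return masses


_ISOTOPE_MASSES: Dict[str, float] | None = None


def _masses() -> Dict[str, float]:
    global _ISOTOPE_MASSES
    if _ISOTOPE_MASSES is None:
        _ISOTOPE_MASSES = isotope_masses()
    return _ISOTOPE_MASSES


@dataclass(frozen=True)
class Formula:
    """An elemental composition, e.g. ``{"C": 13, "H": 18, "O": 7}``.

    Only C, H, N, O, P and S are accepted; every stored count is >= 1 and
    an empty composition is invalid.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        if not counts:
            raise FormulaError("empty formula")
        supported = _masses()
        for element, count in counts.items():
            if element not in supported:
                raise FormulaError(f"unsupported element {element!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"invalid count {count!r} for element {element!r}")
        object.__setattr__(self, "element_counts", counts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.element_counts)
        for element, count in other.element_counts.items():
            merged[element] = merged.get(element, 0) + count
        return Formula(merged)

    def __str__(self) -> str:
        # Hill order: C, H, then the rest alphabetically.
        parts = []
        counts = dict(self.element_counts)
        for element in ["C", "H"] + sorted(set(counts) - {"C", "H"}):
            if element in counts:
                n = counts[element]
                parts.append(element + (str(n) if n > 1 else ""))
        return "".join(parts)


def parse_formula(text: str) -> Formula:
    """Parse a molecular-formula string such as ``"C13H18O7"``.

    An omitted count means 1 (``"H2O"`` -> {H: 2, O: 1}); element order is
    irrelevant and repeated symbols accumulate.  Unsupported elements,
    explicit zero counts and stray characters raise :class:`FormulaError`
    naming the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token {text[pos:match.start()]!r}"
            )
        pos = match.end()
        element, digits = match.groups()
        if element not in _masses():
            raise FormulaError(f"unsupported element {element!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for element {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + count
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r}: trailing {text[pos:]!r}")
    return Formula(counts)


def monoisotopic_mass(formula: Formula) -> float:
    """Neutral monoisotopic mass in Da of a :class:`Formula`."""
    masses = _masses()
    return sum(masses[el] * n for el, n in formula.element_counts.items())


def neutral_from_negmode_mz(mz: float) -> float:
    """Neutral mass (Da) of a feature observed as [M-H]- at ``mz`` (Th)."""
    if mz <= PROTON_MASS:
        raise ValueError(f"m/z {mz} is at or below the proton mass")
    return mz + PROTON_MASS


def mz_from_neutral(mass: float) -> float:
    """[M-H]- m/z (Th) for a neutral monoisotopic mass in Da."""
    if mass <= PROTON_MASS:
        raise ValueError(f"neutral mass {mass} is at or below the proton mass")
    return mass - PROTON_MASS


def ppm_delta(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical
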