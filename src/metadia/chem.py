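"""Exact-mass arithmetic for small-molecule annotation.

Monoisotopic masses from molecular formulas, adduct and isotopologue m/z,
fragment-cation m/z, and ppm mass errors.  All masses are in Da, all m/z in
Da per unit charge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Formula",
    "AdductSpec",
    "ADDUCTS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_OFFSET",
    "monoisotopic_mass",
    "adduct_mz",
    "isotopologue_mz",
    "fragment_cation_mz",
    "ppm_error",
]

# IUPAC 2013 monoisotopic atomic masses (most abundant isotope), Da.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.0078250319,
    "D": 2.0141017781,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "Mg": 23.9850417000,
    "Si": 27.9769265350,
    "P": 30.9737619984,
    "S": 31.9720711744,
    "Cl": 34.9688526820,
    "K": 38.9637064864,
    "Ca": 39.9625909000,
    "Fe": 55.9349363000,
    "Se": 79.9165218000,
    "Br": 78.9183376000,
    "I": 126.9044719000,
}

PROTON_MASS = 1.007276467  # Da, mass of H+
ELECTRON_MASS = 0.000548580  # Da
C13_OFFSET = 1.003355  # Da, 13C - 12C; the +1 isotopologue channel for CHNO compounds

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element-count map, e.g. ``Formula.parse("C5H10N2O3")`` for glutamine.

    At least one element count must be positive; unknown element symbols
    are rejected at construction.
    """

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts or all(n == 0 for _, n in self.counts):
            raise ValueError("formula must contain at least one atom")
        for elem, n in self.counts:
            if elem not in ATOMIC_MASSES:
                raise ValueError(f"unknown element symbol: {elem!r}")
            if n < 0:
                raise ValueError(f"negative count for element {elem}")

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``"C9H11NO2"``."""
        text = text.strip()
        if not text:
            raise ValueError("empty formula")
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            pos = m.end()
            elem = m.group(1)
            if elem not in ATOMIC_MASSES:
                raise ValueError(f"unknown element symbol: {elem!r} in {text!r}")
            counts[elem] = counts.get(elem, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(tuple(sorted(counts.items())))

    def __getitem__(self, elem: str) -> int:
        return dict(self.counts).get(elem, 0)

    def __contains__(self, elem: str) -> bool:
        return self[elem] > 0

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for elem, n in other.counts:
            merged[elem] = merged.get(elem, 0) + n
        return Formula(tuple(sorted(merged.items())))

    def __str__(self) -> str:
        return "".join(
            f"{e}{n if n != 1 else ''}" for e, n in self.counts if n > 0
        )


@dataclass(frozen=True)
class AdductSpec:
    """An ionized form of a neutral molecule: label, mass delta, charge."""

    label: str
    mass_delta: float  # Da added to the neutral monoisotopic mass
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"


#: Built-in adduct registry.  Deltas already account for the electron, e.g.
#: [M+H]+ adds a bare proton.  Extensible via :func:`register_adduct` or the
#: batch configuration file.
ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", +1.007276, +1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", +18.033823, +1),
    "[M+Na]+": AdductSpec("[M+Na]+", +22.989218, +1),
    "[M-H]-": AdductSpec("[M-H]-", -1.007276, -1),
}


def register_adduct(label: str, mass_delta: float, charge: int) -> AdductSpec:
    """Add a user-defined adduct to the registry and return it."""
    spec = AdductSpec(label, mass_delta, charge)
    ADDUCTS[label] = spec
    return spec


def _resolve_adduct(adduct: str | AdductSpec) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        known = ", ".join(sorted(ADDUCTS))
        raise KeyError(f"unknown adduct {adduct!r}; known adducts: {known}") from None


def monoisotopic_mass(formula: Formula | str) -> float:
    """Neutral monoisotopic mass in Da of a molecular formula."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    return sum(ATOMIC_MASSES[e] * n for e, n in formula.counts)


def adduct_mz(neutral_mass: float, adduct: str | AdductSpec) -> float:
    """m/z of an adduct ion of a neutral molecule.

    ``adduct_mz(146.06914, "[M+H]+")`` -> 147.0764 (glutamine).
    """
    if neutral_mass < 0:
        raise ValueError("neutral mass must be non-negative")
    spec = _resolve_adduct(adduct)
    return (neutral_mass + spec.mass_delta) / abs(spec.charge)


def isotopologue_mz(mz: float, k: int = 1, charge: int = 1) -> float:
    """m/z of the +k heavy isotopologue, using the 13C-12C offset per charge."""
    return mz + k * C13_OFFSET / abs(charge)


def fragment_cation_mz(formula: Formula | str) -> float:
    """m/z of a singly charged even-electron cation with the given atom count.

    The electron mass is subtracted so that e.g. C4H6NO+ -> 84.0444, the
    iminium fragment of glutamine.
    """
    return monoisotopic_mass(formula) - ELECTRON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def within_tolerance(observed: float, theoretical: float,
                     ppm_tol: float = 5.0, mz_window: float = 0.005) -> bool:
    """True if |observed - theoretical| is inside both the relative ppm
    tolerance and the absolute Da window (the window binds only above
    m/z ~1000 at 5 ppm / 0.005 Da)."""
    da_tol = min(ppm_tol * 1e-6 * theoretical, mz_window)
    return abs(observed - theoretical) <= da_tol
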