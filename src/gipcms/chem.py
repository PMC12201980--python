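"""Elemental-formula arithmetic and m/z math for high-resolution MS.

All masses are monoisotopic. Charged-species m/z uses the proton mass
(1.007276 Da, i.e. electron-corrected) rather than the hydrogen atom mass,
which matters at the 5 ppm accuracy the annotation pipeline works at.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

# CODATA/IUPAC monoisotopic atomic masses, Da.  Single authoritative table;
# every m/z printed anywhere in the package derives from these five values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.00727646...

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Invalid elemental composition (unknown element or negative count)."""


@dataclass(frozen=True)
class Formula:
    """Immutable elemental composition over the supported element table.

    Supports element-wise ``+`` and ``-``; subtraction that would drive any
    count negative raises :class:`FormulaError` (fragments cannot contain
    atoms their precursor lacks).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for elem, n in self.counts.items():
            if elem not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {elem!r}")
            if not isinstance(n, int) or isinstance(n, bool):
                raise FormulaError(f"count for {elem} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for {elem}: {n}")
            if n > 0:
                clean[elem] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``"C6H13O9P"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos or not match.group(0):
                break
            elem, digits = match.group(1), match.group(2)
            counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula: {text!r}")
        return cls(counts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for elem, n in other.counts.items():
            merged[elem] = merged.get(elem, 0) + n
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for elem, n in other.counts.items():
            new = merged.get(elem, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction makes {elem} count negative: {self} - {other}"
                )
            merged[elem] = new
        return Formula(merged)

    def __mul__(self, k: int) -> "Formula":
        if k < 0:
            raise FormulaError("cannot multiply a formula by a negative integer")
        return Formula({e: n * k for e, n in self.counts.items()})

    __rmul__ = __mul__

    def __contains__(self, other: "Formula") -> bool:
        """True iff *other* is an element-wise subset of this formula."""
        return all(self.counts.get(e, 0) >= n for e, n in other.counts.items())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Formula) and self.counts == dict(other.counts)

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self.counts.items()))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(
            f"{e}{self.counts[e]}" if self.counts[e] != 1 else e for e in order
        )


def monoisotopic_mass(f: Formula) -> float:
    """Monoisotopic mass of a neutral composition, Da (0.0 for the empty formula)."""
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in f.counts.items())


@dataclass(frozen=True)
class Adduct:
    """Ionisation transform: hydrogens gained (+) or lost (-) and the charge.

    ``delta_h`` is the signed number of hydrogen *atoms* exchanged; the
    electron imbalance implied by ``charge`` is corrected separately, so
    [M+H]+ adds exactly one proton mass.
    """

    name: str
    delta_h: int
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")

    @property
    def polarity(self) -> str:
        return "+" if self.charge > 0 else "-"

    def mz(self, neutral_mass: float) -> float:
        ion = (
            neutral_mass
            + self.delta_h * MONOISOTOPIC_MASS["H"]
            - self.charge * ELECTRON_MASS
        )
        return ion / abs(self.charge)


PROTONATED = Adduct("[M+H]+", +1, +1)
DEPROTONATED = Adduct("[M-H]-", -1, -1)
DOUBLY_DEPROTONATED = Adduct("[M-2H]2-", -2, -2)

ADDUCTS: dict[str, Adduct] = {
    a.name: a for a in (PROTONATED, DEPROTONATED, DOUBLY_DEPROTONATED)
}


def mz_of(f: Formula, adduct: Adduct) -> float:
    """m/z of formula *f* under *adduct*; raises if the transform strips
    more hydrogens than the formula carries."""
    if adduct.delta_h < 0 and f.counts.get("H", 0) < -adduct.delta_h:
        raise FormulaError(
            f"{adduct.name} removes {-adduct.delta_h} H from {f} "
            f"which has only {f.counts.get('H', 0)}"
        )
    return adduct.mz(monoisotopic_mass(f))


def nominal_mz(mz: float) -> int:
    """Integer m/z as conventionally quoted for diagnostic fragments (259,
    421, 622...): the integer part of the monoisotopic m/z.  Truncation,
    not rounding — lipid-derived ions carry a large positive mass defect
    (Z0 at 622.61 is quoted as 622), while for the low-defect glycan ions
    the two conventions coincide."""
    return int(math.floor(mz)) if mz >= 0 else -int(math.floor(-mz))


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million (theoretical in the
    denominator — the one-sided convention; symmetric to well below 1 ppm
    for any tolerance used here)."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return (observed - theoretical) / theoretical * 1e6


def ppm_match(observed: float, theoretical: float, tol_ppm: float) -> bool:
    """True iff the two m/z values agree within *tol_ppm*."""
    return abs(ppm_error(observed, theoretical)) <= tol_ppm


def ppm_window(theoretical: float, tol_ppm: float) -> tuple[float, float]:
    """Absolute (low, high) m/z window corresponding to a ppm tolerance."""
    half = theoretical * tol_ppm * 1e-6
    return theoretical - half, theoretical + half


# Small shared vocabulary of neutral building blocks
H2O = Formula({"H": 2, "O": 1})
HPO3 = Formula({"H": 1, "P": 1, "O": 3})
INOSITOL = Formula({"C": 6, "H": 12, "O": 6})
# inositol + HPO3: the inositol-phosphate diagnostic head, C6H13O9P
INOSITOL_PHOSPHATE = INOSITOL + HPO3
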