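"""GIPC nomenclature and structural model.

A glycosyl inositol phospho ceramide (GIPC) is a ceramide linked through a
phosphodiester to myo-inositol carrying a glycan chain.  The glycan series
letter encodes chain length: series 0 is the bare inositol phospho ceramide
(IPC), series A carries two saccharides (HexA proximal, then the R-group
sugar), and each further letter adds one residue up to seven for series F.
The R-group names the second saccharide: OH = hexose, NH = glucosamine
(HexN), NAc = N-acetylglucosamine (HexNAc).

Ceramides are written in shorthand at two levels: *molecular species*
resolves the sphingoid base / fatty acid split (``18:0;O3/24:1``) while
*species* gives only the summed composition (``42:1;O3``).  ``;O`` with no
digit means one hydroxyl; a missing ``;O`` term means none.

Names used throughout — e.g. ``B-NH-18:0;O3/24:1`` or ``C-Hex-NH-40:0;O3``
— are ``SERIES[-SUGARTAGS]-RGROUP-CHAINS``; optional sugar tags such as
``Hex`` or ``2Hex-Pen`` append extra residues distal to the series' base
glycan.  Series 0 names carry no R-group (``0-42:0;O3``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .chem import (
    H2O,
    HPO3,
    INOSITOL,
    Formula,
    monoisotopic_mass,
)

__all__ = [
    "RESIDUE_FORMULAS",
    "SERIES_ORDER",
    "ChainSpec",
    "CeramideSpec",
    "GipcSpecies",
    "NameError_",
    "parse_name",
    "format_name",
    "formula_of",
    "ecn_of",
    "species_table",
    "write_species_table",
    "read_species_table",
]

# Anhydro (in-chain) residue compositions
RESIDUE_FORMULAS: dict[str, Formula] = {
    "Hex": Formula({"C": 6, "H": 10, "O": 5}),
    "HexA": Formula({"C": 6, "H": 8, "O": 6}),
    "HexN": Formula({"C": 6, "H": 11, "N": 1, "O": 4}),
    "HexNAc": Formula({"C": 8, "H": 13, "N": 1, "O": 5}),
    "Pen": Formula({"C": 5, "H": 8, "O": 4}),
}

SERIES_ORDER = "0ABCDEF"

# Second-saccharide identity per R-group code
_RGROUP_RESIDUE = {"OH": "Hex", "NH": "HexN", "NAc": "HexNAc"}
_RGROUP_CANON = {"oh": "OH", "nh": "NH", "nac": "NAc"}


class NameError_(ValueError):
    """Malformed or internally inconsistent GIPC name."""


def base_residues(series: str, r_group: Optional[str]) -> tuple[str, ...]:
    """Base glycan residue sequence, proximal (inositol side) to distal.

    Series A = (HexA, R2); B adds Hex; C adds another Hex; D adds a terminal
    pentose; E and F add further hexoses (the default for series beyond D).
    """
    if series not in SERIES_ORDER:
        raise NameError_(f"unknown series letter: {series!r}")
    if series == "0":
        if r_group is not None:
            raise NameError_("series 0 (IPC) takes no R-group")
        return ()
    if r_group not in _RGROUP_RESIDUE:
        raise NameError_(f"unknown R-group code: {r_group!r}")
    seq = ["HexA", _RGROUP_RESIDUE[r_group]]
    extra = SERIES_ORDER.index(series) - 1  # residues beyond the A core
    for i in range(extra):
        # third and fourth residues are hexoses; the fifth (series D) is a
        # pentose; E/F append hexoses
        seq.append("Pen" if i == 2 else "Hex")
    return tuple(seq)


_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:;O(\d*))?$")


@dataclass(frozen=True)
class ChainSpec:
    """One ceramide chain: carbon count, double bonds, hydroxyls, role.

    SPB (sphingoid base) composition: C_n H_(2n+3-2db) N O_oh.
    FA  (fatty acid)      composition: C_n H_(2n-2db)   O_(2+oh).
    """

    carbons: int
    double_bonds: int
    hydroxyls: int
    role: str  # "SPB" | "FA"

    def __post_init__(self) -> None:
        if self.role not in ("SPB", "FA"):
            raise ValueError(f"chain role must be SPB or FA, got {self.role!r}")
        if self.carbons < 12:
            raise ValueError(f"chain carbons must be >= 12, got {self.carbons}")
        if self.double_bonds < 0 or self.hydroxyls < 0:
            raise ValueError("double bonds and hydroxyls must be non-negative")

    @property
    def formula(self) -> Formula:
        n, db, oh = self.carbons, self.double_bonds, self.hydroxyls
        if self.role == "SPB":
            return Formula({"C": n, "H": 2 * n + 3 - 2 * db, "N": 1, "O": oh})
        return Formula({"C": n, "H": 2 * n - 2 * db, "O": 2 + oh})

    @property
    def shorthand(self) -> str:
        return _chain_shorthand(self.carbons, self.double_bonds, self.hydroxyls)


def _chain_shorthand(c: int, db: int, oh: int) -> str:
    s = f"{c}:{db}"
    if oh == 1:
        s += ";O"
    elif oh > 1:
        s += f";O{oh}"
    return s


def _parse_chain_token(token: str) -> tuple[int, int, int]:
    m = _CHAIN_RE.match(token)
    if not m:
        raise NameError_(f"malformed chain descriptor: {token!r}")
    c, db = int(m.group(1)), int(m.group(2))
    og = m.group(3)
    oh = 0 if og is None else (1 if og == "" else int(og))
    return c, db, oh


@dataclass(frozen=True)
class CeramideSpec:
    """Ceramide at species (sum composition) or molecular-species level.

    The elemental composition depends only on the totals:
    C_T H_(2T+1-2DB) N O_(OH+1) — so species-level records have a
    well-defined formula even though the chain split is unknown.
    """

    level: str  # "species" | "molecular_species"
    spb: Optional[ChainSpec] = None
    fa: Optional[ChainSpec] = None
    total_carbons: int = 0
    total_db: int = 0
    total_oh: int = 0

    def __post_init__(self) -> None:
        if self.level == "molecular_species":
            if self.spb is None or self.fa is None:
                raise ValueError("molecular_species level requires spb and fa chains")
            object.__setattr__(
                self, "total_carbons", self.spb.carbons + self.fa.carbons
            )
            object.__setattr__(
                self, "total_db", self.spb.double_bonds + self.fa.double_bonds
            )
            object.__setattr__(
                self, "total_oh", self.spb.hydroxyls + self.fa.hydroxyls
            )
        elif self.level == "species":
            if self.total_carbons <= 0:
                raise ValueError("species level requires positive total_carbons")
        else:
            raise ValueError(f"unknown ceramide level: {self.level!r}")

    @classmethod
    def molecular(cls, spb_c, spb_db, spb_oh, fa_c, fa_db, fa_oh) -> "CeramideSpec":
        return cls(
            "molecular_species",
            spb=ChainSpec(spb_c, spb_db, spb_oh, "SPB"),
            fa=ChainSpec(fa_c, fa_db, fa_oh, "FA"),
        )

    @classmethod
    def species(cls, carbons: int, db: int, oh: int) -> "CeramideSpec":
        return cls("species", total_carbons=carbons, total_db=db, total_oh=oh)

    @property
    def formula(self) -> Formula:
        if self.level == "molecular_species":
            return self.spb.formula + self.fa.formula - H2O
        t, db, oh = self.total_carbons, self.total_db, self.total_oh
        return Formula({"C": t, "H": 2 * t + 1 - 2 * db, "N": 1, "O": oh + 1})

    @property
    def ecn(self) -> int:
        """Equivalent carbon number: carbons minus twice the double bonds."""
        return self.total_carbons - 2 * self.total_db

    def to_species_level(self) -> "CeramideSpec":
        if self.level == "species":
            return self
        return CeramideSpec.species(self.total_carbons, self.total_db, self.total_oh)

    @property
    def shorthand(self) -> str:
        if self.level == "molecular_species":
            return f"{self.spb.shorthand}/{self.fa.shorthand}"
        return _chain_shorthand(self.total_carbons, self.total_db, self.total_oh)


@dataclass(frozen=True)
class GipcSpecies:
    """A GIPC (or series-0 IPC) candidate: glycan series + R-group +
    optional extra sugar tags + ceramide.

    ``branched`` marks a terminal hexose attached directly to the inositol
    (the structural feature evidenced by the 421/403 fragments); by default
    it is set for series B and beyond, where branching was observed, and
    unset for series 0/A.
    """

    series: str
    r_group: Optional[str]
    ceramide: CeramideSpec
    extra_residues: tuple[str, ...] = ()
    branched: Optional[bool] = None

    def __post_init__(self) -> None:
        base_residues(self.series, self.r_group)  # validates series/R pairing
        for r in self.extra_residues:
            if r not in RESIDUE_FORMULAS:
                raise NameError_(f"unknown residue code: {r!r}")
        if self.branched is None:
            object.__setattr__(self, "branched", self.series not in ("0", "A"))

    @property
    def residues(self) -> tuple[str, ...]:
        """Full residue sequence, proximal to distal."""
        return base_residues(self.series, self.r_group) + self.extra_residues

    @property
    def level(self) -> str:
        return self.ceramide.level

    @property
    def formula(self) -> Formula:
        f = self.ceramide.formula + INOSITOL + HPO3 - H2O
        for r in self.residues:
            f = f + RESIDUE_FORMULAS[r]
        return f

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def name(self) -> str:
        return format_name(self)

    def to_species_level(self) -> "GipcSpecies":
        return replace(self, ceramide=self.ceramide.to_species_level())

    def __str__(self) -> str:
        return self.name


def formula_of(sp: GipcSpecies) -> Formula:
    """Elemental composition of the neutral species (element-conserving
    assembly: ceramide + inositol + HPO3 - H2O + glycan residues)."""
    return sp.formula


def ecn_of(sp: GipcSpecies) -> int:
    """Equivalent carbon number of the ceramide, both chains combined."""
    return sp.ceramide.ecn


# --- name grammar -----------------------------------------------------------

_TAG_RE = re.compile(r"^(\d*)(hex|pen|hexa|hexn|hexnac)$", re.IGNORECASE)
_TAG_CANON = {"hex": "Hex", "pen": "Pen", "hexa": "HexA", "hexn": "HexN",
              "hexnac": "HexNAc"}


def _parse_tag(token: str) -> Optional[list[str]]:
    m = _TAG_RE.match(token)
    if not m:
        return None
    count = int(m.group(1)) if m.group(1) else 1
    return [_TAG_CANON[m.group(2).lower()]] * count


def parse_name(name: str) -> GipcSpecies:
    """Parse a GIPC shorthand name into a :class:`GipcSpecies`.

    Grammar: ``SERIES[-SUGARTAGS]-RGROUP-CHAINS`` (no R-group for series 0),
    where CHAINS is ``C:D;On`` (species level) or ``C:D;On/C:D[;On]``
    (molecular species, sphingoid base first).  Sugar tags (``Hex``,
    ``2Hex-Pen``...) are parsed case-insensitively and appended as extra
    distal residues.
    """
    tokens = name.strip().split("-")
    if len(tokens) < 2:
        raise NameError_(f"not a GIPC name: {name!r}")
    series = tokens[0].upper() if tokens[0] != "0" else "0"
    if series not in SERIES_ORDER:
        raise NameError_(f"unknown series letter: {tokens[0]!r}")
    chains_token = tokens[-1]
    middle = tokens[1:-1]

    r_group: Optional[str] = None
    tag_tokens = middle
    if series != "0":
        if not middle:
            raise NameError_(f"missing R-group in {name!r}")
        r_code = middle[-1].lower()
        if r_code not in _RGROUP_CANON:
            raise NameError_(f"unknown R-group code: {middle[-1]!r}")
        r_group = _RGROUP_CANON[r_code]
        tag_tokens = middle[:-1]
    elif middle:
        raise NameError_(f"series 0 names take no sugar tags or R-group: {name!r}")

    extra: list[str] = []
    for tok in tag_tokens:
        residues = _parse_tag(tok)
        if residues is None:
            raise NameError_(f"unknown sugar tag {tok!r} in {name!r}")
        extra.extend(residues)

    if "/" in chains_token:
        spb_tok, fa_tok = chains_token.split("/", 1)
        sc, sdb, soh = _parse_chain_token(spb_tok)
        fc, fdb, foh = _parse_chain_token(fa_tok)
        cer = CeramideSpec.molecular(sc, sdb, soh, fc, fdb, foh)
    else:
        c, db, oh = _parse_chain_token(chains_token)
        cer = CeramideSpec.species(c, db, oh)

    return GipcSpecies(series, r_group, cer, tuple(extra))


def format_name(sp: GipcSpecies) -> str:
    """Canonical name; inverse of :func:`parse_name` on canonical names."""
    parts = [sp.series]
    # run-length encode the extra residues in order
    i = 0
    extras = sp.extra_residues
    while i < len(extras):
        j = i
        while j < len(extras) and extras[j] == extras[i]:
            j += 1
        n = j - i
        parts.append(extras[i] if n == 1 else f"{n}{extras[i]}")
        i = j
    if sp.series != "0":
        parts.append(sp.r_group)
    parts.append(sp.ceramide.shorthand)
    return "-".join(parts)


# --- species tables ---------------------------------------------------------

def species_table(species: Iterable[GipcSpecies]) -> pd.DataFrame:
    rows = [
        {
            "name": sp.name,
            "series": sp.series,
            "r_group": sp.r_group or "",
            "level": sp.level,
            "formula": str(sp.formula),
            "neutral_mass": sp.neutral_mass,
        }
        for sp in species
    ]
    return pd.DataFrame(rows, columns=[
        "name", "series", "r_group", "level", "formula", "neutral_mass"
    ])


def write_species_table(species: Sequence[GipcSpecies], path: str | Path) -> None:
    species_table(species).to_csv(path, index=False)


def read_species_table(path: str | Path) -> list[GipcSpecies]:
    df = pd.read_csv(path)
    return [parse_name(n) for n in df["name"]]
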