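"""In-silico prediction of diagnostic MS2/MS3 fragments for GIPC.

Glycan fragments follow Domon-Costello nomenclature: B/C ions retain the
non-reducing (distal) end, Y/Z the reducing (ceramide) end; V/W ions are
ceramide chain cleavages (V from the fatty acid, W from the sphingoid
base).  Cleavage sites are numbered from the ceramide: site 0 is the
phosphodiester (Y0 = ceramide, Z0 = Y0 - H2O), site k >= 1 the k-th
glycosidic bond counting the inositol-phosphate as the first ring.

Class-diagnostic ions are the inositol-phosphate (IP) family — nominal
259/241 in negative mode, 261 in positive — and, for glycans branched at
the inositol, IP+Hex at 421/403 (negative).  Head-group ions ("HG{j}" =
IP plus the j proximal residues, e.g. the C-series ion at nominal 760)
serve as MS3 precursors for the glycan ladder.

Sphingoid-base (W) and fatty-acid (V) ion compositions are not settled
chemistry; they are read from an editable definition table
(``data/chain_fragments.csv``) rather than hard-coded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .chem import (
    H2O,
    INOSITOL_PHOSPHATE,
    PROTON_MASS,
    Formula,
    FormulaError,
    monoisotopic_mass,
    nominal_mz,
)
from .model import RESIDUE_FORMULAS, GipcSpecies

__all__ = [
    "FragmentIon",
    "predict_fragments",
    "complementary_pair_check",
    "load_chain_fragment_table",
    "fragments_table",
]

HEX = RESIDUE_FORMULAS["Hex"]


@dataclass(frozen=True)
class FragmentIon:
    """A named singly charged product ion.

    Exactly one of ``formula`` (neutral composition; m/z derived by adding
    or removing a proton according to polarity) or ``raw_mz`` (composition-
    unassigned diagnostics such as the 535 branching marker) is set.
    """

    label: str
    polarity: str  # "+" | "-"
    ms_level: int
    diagnostic_class: str  # glycan | ceramide | inositol_phosphate | branching
    formula: Optional[Formula] = None
    raw_mz: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.formula is None) == (self.raw_mz is None):
            raise ValueError("exactly one of formula / raw_mz must be set")
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")

    @property
    def mz(self) -> float:
        if self.raw_mz is not None:
            return self.raw_mz
        m = monoisotopic_mass(self.formula)
        return m + PROTON_MASS if self.polarity == "+" else m - PROTON_MASS

    @property
    def nominal(self) -> int:
        return nominal_mz(self.mz)


# --- chain-ion definition table --------------------------------------------

_DELTA_TOKEN = re.compile(r"([+-])([A-Za-z0-9]+)")


def _apply_delta(base: Formula, delta: str) -> Formula:
    f = base
    pos = 0
    for m in _DELTA_TOKEN.finditer(delta):
        if m.start() != pos:
            raise ValueError(f"cannot parse delta expression {delta!r}")
        term = Formula.parse(m.group(2))
        f = f + term if m.group(1) == "+" else f - term
        pos = m.end()
    if pos != len(delta):
        raise ValueError(f"cannot parse delta expression {delta!r}")
    return f


def load_chain_fragment_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the editable V/W chain-ion definitions (label, basis chain,
    delta-formula expression, polarity, diagnostic class)."""
    if path is None:
        source = resources.files("gipcms").joinpath("data/chain_fragments.csv")
        with resources.as_file(source) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


_CHAIN_TABLE: Optional[pd.DataFrame] = None


def _chain_table() -> pd.DataFrame:
    global _CHAIN_TABLE
    if _CHAIN_TABLE is None:
        _CHAIN_TABLE = load_chain_fragment_table()
    return _CHAIN_TABLE


# --- prediction -------------------------------------------------------------

def _glycan_ladders(sp: GipcSpecies, polarity: str, ms_level: int) -> list[FragmentIon]:
    """B/C (distal) and Y/Z (proximal) ladders over every glycosidic bond
    and the phosphodiester, plus the head-group (HG) ladder."""
    residues = [RESIDUE_FORMULAS[r] for r in sp.residues]
    n = len(residues)
    cer = sp.ceramide.formula
    total = sp.formula
    out: list[FragmentIon] = []

    def ion(label, formula, cls) -> FragmentIon:
        return FragmentIon(label, polarity, ms_level, cls, formula=formula)

    # phosphodiester site: ceramide-side ions
    out.append(ion("Y0", cer, "ceramide"))
    out.append(ion("Z0", cer - H2O, "ceramide"))

    # glycosidic sites: Yk retains IP plus (k-1) proximal residues
    yk = cer + INOSITOL_PHOSPHATE - H2O
    for k in range(1, n + 1):
        out.append(ion(f"Y{k}", yk, "glycan"))
        out.append(ion(f"Z{k}", yk - H2O, "glycan"))
        if k <= n - 1:
            yk = yk + residues[k - 1]

    # B/C ladder: Bk = k distal residues (complementary to Y(n-k+1))
    bk = Formula()
    for k in range(1, n + 1):
        bk = bk + residues[n - k]
        out.append(ion(f"B{k}", bk, "glycan"))
        out.append(ion(f"C{k}", bk + H2O, "glycan"))

    # head-group ladder: IP plus the j proximal residues
    hg = INOSITOL_PHOSPHATE
    for j in range(1, n + 1):
        hg = hg + residues[j - 1]
        out.append(ion(f"HG{j}", hg, "glycan"))
    return out


def _ip_family(sp: GipcSpecies, polarity: str, ms_level: int) -> list[FragmentIon]:
    out = [
        FragmentIon("IP", polarity, ms_level, "inositol_phosphate",
                    formula=INOSITOL_PHOSPHATE),
        FragmentIon("IP-H2O", polarity, ms_level, "inositol_phosphate",
                    formula=INOSITOL_PHOSPHATE - H2O),
    ]
    if polarity == "-" and sp.branched:
        out.append(FragmentIon("IP+Hex", polarity, ms_level, "branching",
                               formula=INOSITOL_PHOSPHATE + HEX))
        out.append(FragmentIon("IP+Hex-H2O", polarity, ms_level, "branching",
                               formula=INOSITOL_PHOSPHATE + HEX - H2O))
        if len(sp.residues) >= 4:
            # composition-unassigned branching marker seen in C-series
            # spectra; matched by nominal m/z window only
            out.append(FragmentIon("BR535", polarity, ms_level, "branching",
                                   raw_mz=535.0))
    return out


def _chain_ions(sp: GipcSpecies, polarity: str, ms_level: int) -> list[FragmentIon]:
    if sp.ceramide.level != "molecular_species":
        return []
    bases = {"SPB": sp.ceramide.spb.formula, "FA": sp.ceramide.fa.formula}
    out = []
    for row in _chain_table().itertuples(index=False):
        if row.polarity != polarity:
            continue
        try:
            formula = _apply_delta(bases[row.basis], row.delta)
        except FormulaError:
            # loss not feasible for this chain composition (e.g. a second
            # water loss from a dihydroxylated base) — no such ion exists
            continue
        out.append(
            FragmentIon(row.label, polarity, ms_level, row.diagnostic_class,
                        formula=formula)
        )
    return out


def predict_fragments(
    sp: GipcSpecies,
    polarity: str,
    ms_level: int = 2,
    precursor_label: Optional[str] = None,
) -> list[FragmentIon]:
    """Predict the diagnostic product ions of *sp* for one polarity and MS
    stage.

    MS2 yields the IP family, the branching diagnostics (negative mode,
    branched glycans only), the full B/C + Y/Z glycan ladders, the head-
    group ladder, and the ceramide Y0/Z0 pair.  MS3 requires the precursor
    fragment label: ``"Z0"`` yields the sphingoid-base (W) and fatty-acid
    (V) chain ions for molecular-species candidates; a head-group label
    (``"HG3"``...) yields the glycan B/C ladder restricted to its residues.
    """
    if ms_level == 2:
        return _ip_family(sp, polarity, 2) + _glycan_ladders(sp, polarity, 2)
    if ms_level == 3:
        if precursor_label is None:
            raise ValueError("MS3 prediction requires a precursor fragment label")
        if precursor_label.startswith("Z0") or precursor_label.startswith("Y0"):
            return _chain_ions(sp, polarity, 3)
        if precursor_label.startswith("HG"):
            frags = _ip_family(sp, polarity, 3) + [
                f for f in _glycan_ladders(sp, polarity, 3)
                if f.label[0] in "BC" or f.label.startswith("HG")
            ]
            # keep only ions contained in the selected head-group precursor
            j = int(precursor_label[2:])
            residues = [RESIDUE_FORMULAS[r] for r in sp.residues][:j]
            prec = INOSITOL_PHOSPHATE
            for r in residues:
                prec = prec + r
            return [f for f in frags if f.raw_mz is not None or f.formula in prec]
        raise ValueError(f"unsupported MS3 precursor label: {precursor_label!r}")
    raise ValueError(f"unsupported MS level: {ms_level}")


def complementary_pair_check(
    b_mz: float,
    y_mz: float,
    precursor_mz: float,
    polarity: str = "+",
    tol: float = 1e-4,
) -> bool:
    """Consistency check on a B/Y (or C/Z) pair from the same cleavage:
    for singly charged positive ions m(B+) + m(Y+) = m([M+H]+) + m(proton);
    in negative mode the proton term flips sign."""
    shift = PROTON_MASS if polarity == "+" else -PROTON_MASS
    return abs((b_mz + y_mz) - (precursor_mz + shift)) <= tol


def fragments_table(frags: Sequence[FragmentIon]) -> pd.DataFrame:
    """Predicted fragment list as an exportable table."""
    return pd.DataFrame(
        {
            "label": [f.label for f in frags],
            "mz": [f.mz for f in frags],
            "nominal": [f.nominal for f in frags],
            "polarity": [f.polarity for f in frags],
            "ms_level": [f.ms_level for f in frags],
            "class": [f.diagnostic_class for f in frags],
            "formula": [str(f.formula) if f.formula is not None else "" for f in frags],
        }
    )
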