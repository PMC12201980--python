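"""Combinatorial generation of theoretical GIPC target lists.

The target list serves two roles: as the acquisition inclusion list (the
precursor m/z values the instrument schedules for fragmentation) and as the
annotation search space.  Enumeration happens at molecular-species level —
MS1 cannot distinguish chain splits but MS3 can — and can be projected to
species level for MS1 matching.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .chem import Adduct, ADDUCTS, mz_of
from .model import CeramideSpec, GipcSpecies

__all__ = [
    "ChainSpace",
    "TargetEntry",
    "generate_targets",
    "write_inclusion_list",
    "read_inclusion_list",
    "DEFAULT_SERIES_SET",
]

# The series/R-group combinations observed in barley grains
DEFAULT_SERIES_SET: tuple[tuple[str, Optional[str]], ...] = (
    ("A", "NH"), ("A", "NAc"),
    ("B", "NH"), ("B", "NAc"),
    ("C", "NH"),
    ("D", "NH"),
)


@dataclass(frozen=True)
class ChainSpace:
    """Bounds of the ceramide chain combinatorics.

    Defaults mirror the barley findings: sphingoid bases of 18 carbons, 0-1
    double bonds, di- or tri-hydroxylated; fatty acids of 16-26 carbons
    (odd included), 0-2 double bonds, non- or singly hydroxylated; total
    hydroxylation capped at 2-4 as a post-filter.
    """

    spb_carbons: tuple[int, ...] = (18,)
    spb_db: tuple[int, ...] = (0, 1)
    spb_oh: tuple[int, ...] = (2, 3)
    fa_carbons: tuple[int, ...] = tuple(range(16, 27))
    fa_db: tuple[int, ...] = (0, 1, 2)
    fa_oh: tuple[int, ...] = (0, 1)
    total_oh_range: tuple[int, int] = (2, 4)

    def __post_init__(self) -> None:
        for name in ("spb_carbons", "spb_db", "spb_oh",
                     "fa_carbons", "fa_db", "fa_oh"):
            if not getattr(self, name):
                raise ValueError(f"chain-space set {name} is empty")

    def ceramides(self) -> list[CeramideSpec]:
        lo, hi = self.total_oh_range
        out = []
        for sc, sdb, soh, fc, fdb, foh in itertools.product(
            self.spb_carbons, self.spb_db, self.spb_oh,
            self.fa_carbons, self.fa_db, self.fa_oh,
        ):
            if not (lo <= soh + foh <= hi):
                continue
            out.append(CeramideSpec.molecular(sc, sdb, soh, fc, fdb, foh))
        return out


@dataclass(frozen=True)
class TargetEntry:
    """One scheduled precursor: a species under a specific adduct.

    ``variants`` lists every molecular species collapsed into this row by
    the (formula, adduct) deduplication — isobaric chain splits share a
    precursor m/z but are distinguished later by MS3 chain ions, so the
    annotator needs them all.  Empty means the species itself is the only
    variant.
    """

    species: GipcSpecies
    adduct: Adduct
    mz: float
    in_scan_range: bool = True
    variants: tuple[GipcSpecies, ...] = ()

    @property
    def polarity(self) -> str:
        return self.adduct.polarity

    @property
    def name(self) -> str:
        return self.species.name

    @property
    def all_species(self) -> tuple[GipcSpecies, ...]:
        return self.variants if self.variants else (self.species,)


def generate_targets(
    space: ChainSpace,
    series_set: Sequence[tuple[str, Optional[str]]] = DEFAULT_SERIES_SET,
    adducts: Sequence[Adduct] = (
        ADDUCTS["[M+H]+"], ADDUCTS["[M-H]-"], ADDUCTS["[M-2H]2-"],
    ),
    scan_range: tuple[float, float] = (500.0, 2000.0),
) -> list[TargetEntry]:
    """Cartesian product of series x R-group x ceramide space x adducts,
    deduplicated on (formula, adduct) and sorted by polarity then m/z.

    Targets outside *scan_range* are flagged ``in_scan_range=False`` rather
    than dropped, so the caller decides what the instrument can see.
    """
    if not series_set:
        raise ValueError("series_set is empty")
    if not adducts:
        raise ValueError("adducts is empty")
    ceramides = space.ceramides()
    if not ceramides:
        raise ValueError("chain space produced no ceramides under the OH cap")

    # collect the isobaric chain splits behind each (formula, adduct) row
    by_formula: dict = {}
    for (series, r_group), cer in itertools.product(series_set, ceramides):
        sp = GipcSpecies(series, r_group, cer)
        group = by_formula.setdefault(sp.formula, [])
        if sp.name not in {v.name for v in group}:
            group.append(sp)

    targets: list[TargetEntry] = []
    for f in by_formula:
        variants = tuple(by_formula[f])
        for adduct in adducts:
            mz = mz_of(f, adduct)
            in_range = scan_range[0] <= mz <= scan_range[1]
            targets.append(
                TargetEntry(variants[0], adduct, mz, in_range, variants)
            )
    targets.sort(key=lambda t: (t.polarity, t.mz, t.name))
    return targets


def targets_for_species(
    species: Sequence[GipcSpecies],
    adducts: Sequence[Adduct] = (ADDUCTS["[M+H]+"], ADDUCTS["[M-H]-"]),
    scan_range: tuple[float, float] = (500.0, 2000.0),
) -> list[TargetEntry]:
    """Targets for an explicit species list (no combinatorial enumeration);
    same dedup and ordering contract as :func:`generate_targets`."""
    seen: set[tuple] = set()
    out = []
    for sp in species:
        f = sp.formula
        for adduct in adducts:
            key = (f, adduct.name, sp.name)
            if key in seen:
                continue
            seen.add(key)
            mz = mz_of(f, adduct)
            out.append(TargetEntry(sp, adduct, mz,
                                   scan_range[0] <= mz <= scan_range[1]))
    out.sort(key=lambda t: (t.polarity, t.mz, t.name))
    return out


def write_inclusion_list(targets: Sequence[TargetEntry], path: str | Path) -> None:
    """Vendor-neutral CSV inclusion list; stable ordering, lossless reread."""
    if not targets:
        raise ValueError("no targets to write")
    df = pd.DataFrame(
        {
            "mz": [round(t.mz, 5) for t in targets],
            "z": [t.adduct.charge for t in targets],
            "polarity": [t.polarity for t in targets],
            "name": [t.name for t in targets],
            "formula": [str(t.species.formula) for t in targets],
            "adduct": [t.adduct.name for t in targets],
            "in_scan_range": [t.in_scan_range for t in targets],
            "variants": ["|".join(sp.name for sp in t.all_species)
                         for t in targets],
        }
    )
    df.to_csv(path, index=False)


def read_inclusion_list(path: str | Path) -> list[TargetEntry]:
    from .model import parse_name

    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        sp = parse_name(row.name)
        variants = ()
        raw = getattr(row, "variants", "")
        if isinstance(raw, str) and raw:
            variants = tuple(parse_name(n) for n in raw.split("|"))
        out.append(
            TargetEntry(sp, ADDUCTS[row.adduct], float(row.mz),
                        bool(row.in_scan_range), variants)
        )
    return out
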