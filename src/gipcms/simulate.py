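"""Seeded synthetic dual-polarity MS1/MS2/MS3 runs with known ground truth.

The generator emulates the acquisition the annotator expects: Gaussian MS1
elution profiles for each species' [M+H]+ and [M-H]- precursors at
retention times drawn from a linear ECN model, MS2 spectra at the peak
apex carrying the predicted diagnostic fragments, and positive-mode MS3
spectra of the Z0 ceramide fragment carrying the chain ions — plus uniform
noise peaks and decoy species engineered to violate exactly one acceptance
criterion each (single-polarity, RT-shifted off the ECN line, or
fragment-free).

Everything is drawn from a single pseudo-random stream keyed by the seed,
in a fixed order, so a given configuration reproduces byte-identical runs
and mzML files.  It does not attempt realistic chemical noise, isotope
envelopes, or in-source fragmentation.
"""

from __future__ import annotations

import base64
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence
from xml.sax.saxutils import escape

import numpy as np

from .chem import ADDUCTS, mz_of
from .fragments import predict_fragments
from .masslist import ChainSpace, TargetEntry, targets_for_species
from .model import GipcSpecies
from .spectra import SpectrumRecord

__all__ = [
    "SimConfig",
    "TruthEntry",
    "GroundTruth",
    "simulate_run",
    "write_mzml",
    "write_runs",
]

# the barley series proportions (share of the 102-species inventory)
DEFAULT_SERIES_MIX: tuple[tuple[str, str, float], ...] = (
    ("A", "NH", 25), ("A", "NAc", 13),
    ("B", "NH", 35), ("B", "NAc", 12),
    ("C", "NH", 11), ("D", "NH", 6),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic acquisition.

    Retention follows rt = rt_intercept + rt_slope * ECN (one global line;
    per-(series, R, OH) groups share it, which keeps every group on a
    fittable line) with Gaussian jitter; the polarity RT offset SD is well
    below a third of the 0.1 min linking tolerance.  Peak shape is Gaussian
    with 0.1 min FWHM, giving a closed-form area for the XIC oracle.
    """

    seed: int = 0
    n_true: int = 20
    series_mix: tuple[tuple[str, str, float], ...] = DEFAULT_SERIES_MIX
    chain_space: ChainSpace = field(default_factory=ChainSpace)
    species_level_fraction: float = 0.2
    rt_intercept: float = 2.0
    rt_slope: float = 0.35  # minutes per ECN unit
    rt_jitter_sd: float = 0.02
    polarity_offset_sd: float = 0.02
    peak_fwhm: float = 0.1  # minutes
    cycle_time: float = 0.02  # minutes between MS1 scans
    height_range: tuple[float, float] = (1e5, 1e6)
    mz_jitter_ppm: float = 1.0
    ms2_mz_jitter_ppm: float = 2.0
    ms3_mz_jitter_da: float = 0.05
    n_noise_peaks_ms1: int = 5
    n_noise_peaks_msn: int = 10
    n_decoys_single_polarity: int = 0
    n_decoys_rt_shifted: int = 0
    n_decoys_fragment_free: int = 0
    rt_shift: float = 2.0  # decoy displacement off the ECN line, minutes

    def __post_init__(self) -> None:
        if self.rt_jitter_sd < 0 or self.polarity_offset_sd < 0:
            raise ValueError("jitter SDs must be non-negative")
        if self.peak_fwhm <= 2 * self.cycle_time:
            raise ValueError("peak FWHM must span several MS1 cycles")


@dataclass(frozen=True)
class TruthEntry:
    species: GipcSpecies
    rt_pos: float
    rt_neg: float
    mz_pos: float
    mz_neg: float
    height: float
    decoy_class: Optional[str] = None  # None = true species

    @property
    def expected_name(self) -> str:
        return self.species.name

    @property
    def expected_level(self) -> str:
        return self.species.level


@dataclass(frozen=True)
class GroundTruth:
    entries: tuple[TruthEntry, ...]
    peak_sigma: float  # minutes

    @property
    def true_entries(self) -> tuple[TruthEntry, ...]:
        return tuple(e for e in self.entries if e.decoy_class is None)

    @property
    def decoys(self) -> tuple[TruthEntry, ...]:
        return tuple(e for e in self.entries if e.decoy_class is not None)

    def injected_area(self, entry: TruthEntry) -> float:
        """Closed-form Gaussian area of the injected MS1 profile."""
        return entry.height * self.peak_sigma * math.sqrt(2 * math.pi)

    def targets(self) -> list[TargetEntry]:
        """Annotation targets covering every simulated species (truths and
        decoys alike, so decoys are actively searched for)."""
        return targets_for_species([e.species for e in self.entries])


def _draw_species(cfg: SimConfig, rng: np.random.Generator) -> list[GipcSpecies]:
    """Distinct species drawn from the series mix and chain space."""
    combos = [(s, r) for s, r, _ in cfg.series_mix]
    weights = np.array([w for _, _, w in cfg.series_mix], dtype=float)
    weights /= weights.sum()
    ceramides = cfg.chain_space.ceramides()
    n_needed = (cfg.n_true + cfg.n_decoys_single_polarity
                + cfg.n_decoys_rt_shifted + cfg.n_decoys_fragment_free)
    out: list[GipcSpecies] = []
    seen: set = set()
    guard = 0
    while len(out) < n_needed:
        guard += 1
        if guard > 100 * n_needed:
            raise ValueError("chain space too small for the requested count")
        series, r_group = combos[rng.choice(len(combos), p=weights)]
        cer = ceramides[rng.integers(len(ceramides))]
        sp = GipcSpecies(series, r_group, cer)
        if len(out) < round(cfg.n_true * cfg.species_level_fraction):
            sp = sp.to_species_level()
        # dedup on elemental formula, not just name: isobaric chain splits
        # co-elute under the ECN retention model, so sharing a formula
        # would entangle one entity's evidence with another's (decoys must
        # violate exactly one criterion on their own)
        if sp.formula in seen:
            continue
        seen.add(sp.formula)
        out.append(sp)
    return out


def _jitter_ppm(mz: float, sd_ppm: float, rng: np.random.Generator) -> float:
    return mz * (1.0 + rng.normal(0.0, sd_ppm) * 1e-6)


def _noise_peaks(n: int, lo: float, hi: float, max_intensity: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    mz = rng.uniform(lo, hi, size=n)
    inten = rng.uniform(0.0, max_intensity, size=n)
    return mz, inten


def _ms2_peaks(sp: GipcSpecies, polarity: str, base: float,
               cfg: SimConfig, rng: np.random.Generator):
    """Diagnostic fragments scaled by a simple intensity profile: class
    ions strong, ladder ions weaker; plus uniform noise."""
    mzs, intens = [], []
    for frag in predict_fragments(sp, polarity, 2):
        if frag.raw_mz is not None:
            mz = frag.raw_mz
        else:
            mz = _jitter_ppm(frag.mz, cfg.ms2_mz_jitter_ppm, rng)
        if frag.label in ("IP", "IP-H2O", "Y0", "Z0"):
            rel = rng.uniform(0.4, 1.0)
        elif frag.diagnostic_class == "branching":
            rel = rng.uniform(0.1, 0.4)
        else:
            rel = rng.uniform(0.02, 0.15)
        mzs.append(mz)
        intens.append(rel * base)
    nmz, nint = _noise_peaks(cfg.n_noise_peaks_msn, 150.0, 1500.0,
                             0.05 * base, rng)
    return np.concatenate([mzs, nmz]), np.concatenate([intens, nint])


def _ms3_peaks(sp: GipcSpecies, base: float, cfg: SimConfig,
               rng: np.random.Generator):
    mzs, intens = [], []
    for frag in predict_fragments(sp, "+", 3, precursor_label="Z0"):
        mzs.append(frag.mz + rng.normal(0.0, cfg.ms3_mz_jitter_da))
        intens.append(rng.uniform(0.3, 1.0) * base)
    nmz, nint = _noise_peaks(cfg.n_noise_peaks_msn, 100.0, 700.0,
                             0.05 * base, rng)
    return np.concatenate([mzs, nmz]), np.concatenate([intens, nint])


def simulate_run(
    cfg: SimConfig,
) -> tuple[GroundTruth, dict[str, list[SpectrumRecord]]]:
    """Generate ground truth and per-polarity spectrum lists.

    Draw order (fixed for reproducibility): species, retention times and
    heights, then spectra in time order per polarity.
    """
    rng = np.random.default_rng(cfg.seed)
    species = _draw_species(cfg, rng)
    sigma = cfg.peak_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    classes = ([None] * cfg.n_true
               + ["single_polarity"] * cfg.n_decoys_single_polarity
               + ["rt_shifted"] * cfg.n_decoys_rt_shifted
               + ["fragment_free"] * cfg.n_decoys_fragment_free)
    entries: list[TruthEntry] = []
    for sp, decoy_class in zip(species, classes):
        rt = (cfg.rt_intercept + cfg.rt_slope * sp.ceramide.ecn
              + rng.normal(0.0, cfg.rt_jitter_sd))
        if decoy_class == "rt_shifted":
            rt += cfg.rt_shift
        rt_neg = rt + rng.normal(0.0, cfg.polarity_offset_sd)
        height = rng.uniform(*cfg.height_range)
        entries.append(
            TruthEntry(
                species=sp,
                rt_pos=rt,
                rt_neg=rt_neg,
                mz_pos=mz_of(sp.formula, ADDUCTS["[M+H]+"]),
                mz_neg=mz_of(sp.formula, ADDUCTS["[M-H]-"]),
                height=height,
                decoy_class=decoy_class,
            )
        )
    truth = GroundTruth(tuple(entries), sigma)
    return truth, build_runs(entries, cfg, rng)


def build_runs(
    entries: Sequence[TruthEntry],
    cfg: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> dict[str, list[SpectrumRecord]]:
    """Render spectra for an explicit entry list (used directly by
    constructed fixtures such as the isomer-pair scenario; *rng* may be a
    Generator, a seed, or None for cfg.seed)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)
    sigma = cfg.peak_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    rts_all = [e.rt_pos for e in entries] + [e.rt_neg for e in entries]
    t_lo = min(rts_all) - 0.3
    t_hi = max(rts_all) + 0.3
    grid = np.arange(t_lo, t_hi, cfg.cycle_time)

    runs: dict[str, list[SpectrumRecord]] = {}
    for polarity in ("+", "-"):
        spectra: list[SpectrumRecord] = []
        for t in grid:
            mzs, intens = [], []
            for e in entries:
                if polarity == "-" and e.decoy_class == "single_polarity":
                    continue
                rt_e = e.rt_pos if polarity == "+" else e.rt_neg
                h = e.height * math.exp(-0.5 * ((t - rt_e) / sigma) ** 2)
                if h < e.height * 1e-3:
                    continue
                mz_theo = e.mz_pos if polarity == "+" else e.mz_neg
                mzs.append(_jitter_ppm(mz_theo, cfg.mz_jitter_ppm, rng))
                intens.append(h)
            nmz, nint = _noise_peaks(cfg.n_noise_peaks_ms1, 500.0, 2000.0,
                                     0.01 * cfg.height_range[1], rng)
            spectra.append(
                SpectrumRecord(1, polarity, float(t),
                               np.concatenate([mzs, nmz]),
                               np.concatenate([intens, nint]))
            )
        # fragmentation spectra at each entry's apex
        for e in entries:
            if polarity == "-" and e.decoy_class == "single_polarity":
                continue
            rt_e = e.rt_pos if polarity == "+" else e.rt_neg
            prec = e.mz_pos if polarity == "+" else e.mz_neg
            base = 0.5 * e.height
            if e.decoy_class == "fragment_free":
                mz2, in2 = _noise_peaks(cfg.n_noise_peaks_msn, 150.0, 1500.0,
                                        base, rng)
            else:
                mz2, in2 = _ms2_peaks(e.species, polarity, base, cfg, rng)
            spectra.append(
                SpectrumRecord(2, polarity, rt_e + cfg.cycle_time / 3,
                               mz2, in2, precursor_chain=(prec,),
                               precursor_charge=1 if polarity == "+" else -1)
            )
            if (polarity == "+" and e.decoy_class != "fragment_free"
                    and e.species.level == "molecular_species"):
                z0 = next(f for f in predict_fragments(e.species, "+", 2)
                          if f.label == "Z0")
                mz3, in3 = _ms3_peaks(e.species, 0.3 * e.height, cfg, rng)
                spectra.append(
                    SpectrumRecord(3, "+", rt_e + 2 * cfg.cycle_time / 3,
                                   mz3, in3,
                                   precursor_chain=(prec, z0.mz),
                                   precursor_charge=1)
                )
        spectra.sort(key=lambda s: (s.rt, s.ms_level))
        runs[polarity] = spectra
    return runs


# --- minimal mzML writer ----------------------------------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}" defaultDataProcessingRef="dp">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64_doubles(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack("<" + "d" * len(values), *values)
    ).decode("ascii")


def _binary_array(values: np.ndarray, kind: str) -> str:
    if kind == "mz":
        name_param = ('<cvParam cvRef="MS" accession="MS:1000514" '
                      'name="m/z array" unitCvRef="MS" '
                      'unitAccession="MS:1000040" unitName="m/z"/>')
    else:
        name_param = ('<cvParam cvRef="MS" accession="MS:1000515" '
                      'name="intensity array" unitCvRef="MS" '
                      'unitAccession="MS:1000131" '
                      'unitName="number of detector counts"/>')
    payload = _b64_doubles(values)
    return (
        f'          <binaryDataArray encodedLength="{len(payload)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" '
        'name="64-bit float"/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" '
        'name="no compression"/>\n'
        f"            {name_param}\n"
        f"            <binary>{payload}</binary>\n"
        "          </binaryDataArray>\n"
    )


def write_mzml(spectra: Sequence[SpectrumRecord], path: str | Path,
               run_id: str = "synthetic") -> None:
    """Write spectra as plain (non-indexed) mzML 1.1.0.

    Peak lists are uncompressed little-endian 64-bit floats, so the
    round trip through any compliant reader is lossless to float
    precision; polarity, MS level, retention time (minutes) and the full
    precursor chain are carried as cvParams.
    """
    if not spectra:
        raise ValueError("no spectra to write")
    parts = [_MZML_HEADER.format(run_id=escape(run_id), count=len(spectra))]
    for idx, s in enumerate(spectra):
        pol = (
            '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan"/>'
            if s.polarity == "+"
            else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan"/>'
        )
        parts.append(
            f'      <spectrum index="{idx}" id="scan={idx + 1}" '
            f'defaultArrayLength="{len(s.mz)}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" '
            f'name="ms level" value="{s.ms_level}"/>\n'
            f"        {pol}\n"
            '        <cvParam cvRef="MS" accession="MS:1000127" '
            'name="centroid spectrum"/>\n'
            '        <scanList count="1">\n'
            '          <scan>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000016" '
            f'name="scan start time" value="{s.rt:.6f}" unitCvRef="UO" '
            'unitAccession="UO:0000031" unitName="minute"/>\n'
            "          </scan>\n"
            "        </scanList>\n"
        )
        if s.ms_level >= 2:
            parts.append(
                f'        <precursorList count="{len(s.precursor_chain)}">\n'
            )
            for pmz in s.precursor_chain:
                charge = ""
                if s.precursor_charge is not None:
                    charge = (
                        '<cvParam cvRef="MS" accession="MS:1000041" '
                        f'name="charge state" value="{abs(s.precursor_charge)}"/>'
                    )
                parts.append(
                    "          <precursor>\n"
                    '            <selectedIonList count="1">\n'
                    "              <selectedIon>\n"
                    f'                <cvParam cvRef="MS" accession="MS:1000744" '
                    f'name="selected ion m/z" value="{pmz:.6f}" unitCvRef="MS" '
                    'unitAccession="MS:1000040" unitName="m/z"/>\n'
                    f"                {charge}\n"
                    "              </selectedIon>\n"
                    "            </selectedIonList>\n"
                    "          </precursor>\n"
                )
            parts.append("        </precursorList>\n")
        parts.append('        <binaryDataArrayList count="2">\n')
        parts.append(_binary_array(s.mz, "mz"))
        parts.append(_binary_array(s.intensity, "intensity"))
        parts.append("        </binaryDataArrayList>\n")
        parts.append("      </spectrum>\n")
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


def write_runs(
    runs: Mapping[str, Sequence[SpectrumRecord]], base_path: str | Path
) -> dict[str, Path]:
    """Write one mzML file per polarity: <base>_pos.mzml / <base>_neg.mzml."""
    base = Path(base_path)
    paths = {}
    for polarity, suffix in (("+", "pos"), ("-", "neg")):
        if polarity not in runs or not runs[polarity]:
            continue
        p = base.with_name(f"{base.name}_{suffix}.mzml")
        write_mzml(runs[polarity], p, run_id=f"{base.name}_{suffix}")
        paths[polarity] = p
    return paths
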