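"""Decision-rule annotation of GIPC from dual-polarity MS1/MS2/MS3 runs.

A candidate is reported only when it meets all three acceptance criteria:

1. fragmentation spectra contain characteristic fragments for both the
   sugar part (inositol-phosphate / glycan ions) and the ceramide part
   (Y0/Z0 or chain ions), in at least one ion mode each;
2. an MS1 feature exists within the accurate-mass tolerance (5 ppm) at the
   same retention time (+-0.1 min) in both positive and negative mode;
3. its retention time satisfies the equivalent-carbon-number (ECN) model —
   within a reversed-phase subclass, RT is linear in carbons minus twice
   the double bonds.

Confidence is assigned at *molecular species* level only when MS3 chain
ions (sphingoid-base W and fatty-acid V families) confirm the chain split;
otherwise the candidate is reported at *species* (sum-composition) level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .chem import ppm_error, ppm_window
from .fragments import FragmentIon, predict_fragments
from .masslist import TargetEntry
from .model import GipcSpecies, SERIES_ORDER
from .spectra import FeatureRecord, SpectrumRecord, XicParams, extract_xic, spectra_near

__all__ = [
    "DecisionRule",
    "MatchedFragment",
    "MatchResult",
    "AnnotationRecord",
    "EcnModel",
    "AnnotateConfig",
    "DEFAULT_RULES",
    "load_rules",
    "write_rules",
    "match_spectrum",
    "dual_polarity_link",
    "fit_ecn_filter",
    "annotate_run",
    "consolidate_replicates",
    "annotations_table",
]


@dataclass(frozen=True)
class DecisionRule:
    """One rule block: which spectra it covers and which fragment labels it
    demands.  ``mandatory`` is a tuple of any-of groups — the rule verdict
    is true iff every group has at least one matched label."""

    series: str  # a series letter or "*"
    polarity: str
    ms_level: int
    mandatory: tuple[tuple[str, ...], ...]
    optional: tuple[str, ...] = ()
    min_relative_intensity: float = 0.01

    def applies_to(self, series: str, polarity: str, ms_level: int) -> bool:
        return (
            self.series in ("*", series)
            and self.polarity == polarity
            and self.ms_level == ms_level
        )


# Default rules encode the published criteria and the figure-level fragment
# assignments: negative MS2 is anchored on the IP family, positive MS2 on
# the ceramide Y0/Z0 pair, and MS3 of Z0 on both chain-ion families.
DEFAULT_RULES: tuple[DecisionRule, ...] = (
    DecisionRule(
        "*", "-", 2,
        mandatory=(("IP", "IP-H2O"),),
        optional=("IP+Hex", "IP+Hex-H2O", "BR535", "Y1", "Z1", "B1", "C1"),
    ),
    DecisionRule(
        "*", "+", 2,
        mandatory=(("Y0", "Z0"),),
        optional=("IP", "IP-H2O", "Y1", "Z1", "B1", "C1", "HG1", "HG2", "HG3"),
    ),
    DecisionRule(
        "*", "+", 3,
        mandatory=(("W", "W-H2O", "W-2H2O"), ("V", "V-H2O")),
    ),
)


@dataclass(frozen=True)
class MatchedFragment:
    fragment: FragmentIon
    observed_mz: float
    intensity: float
    relative_intensity: float


@dataclass(frozen=True)
class MatchResult:
    matched: tuple[MatchedFragment, ...]
    verdict: bool
    reason: str
    rule: Optional[DecisionRule] = None


def _match_fragment_list(
    spec: SpectrumRecord,
    frags: Sequence[FragmentIon],
    tol_ppm: Optional[float],
    tol_mz: Optional[float],
    min_rel: float,
) -> list[MatchedFragment]:
    base = spec.base_peak_intensity
    if base <= 0:
        return []
    out = []
    for frag in frags:
        if frag.raw_mz is not None:
            lo, hi = frag.raw_mz - 0.5, frag.raw_mz + 0.5
        elif tol_mz is not None:
            lo, hi = frag.mz - tol_mz, frag.mz + tol_mz
        else:
            lo, hi = ppm_window(frag.mz, tol_ppm)
        total, wmz = spec.matched_peaks(lo, hi)
        if total > 0 and total / base >= min_rel:
            out.append(MatchedFragment(frag, wmz, total, total / base))
    return out


def _select_ms3_pathway(
    spec: SpectrumRecord, candidate: GipcSpecies
) -> Optional[str]:
    """Which MS3 pathway does this spectrum's precursor correspond to:
    the ceramide Z0 ion or a head-group (HG) ion?"""
    prec = spec.precursor_mz
    if prec is None:
        return None
    for frag in predict_fragments(candidate, spec.polarity, 2):
        if frag.raw_mz is not None:
            continue
        if frag.label == "Z0" or frag.label.startswith("HG"):
            if abs(frag.mz - prec) <= 1.0:
                return frag.label
    return None


def match_spectrum(
    spec: SpectrumRecord,
    candidate: GipcSpecies,
    rules: Sequence[DecisionRule] = DEFAULT_RULES,
    tol_ppm: float = 10.0,
    tol_mz_ms3: float = 0.3,
) -> MatchResult:
    """Evaluate one fragmentation spectrum against the rule covering the
    candidate's series, polarity and MS level.

    MS2 matching is ppm-based (Orbitrap detection); MS3 matching uses an
    absolute m/z tolerance (ion-trap detection).  A fragment counts as
    matched when a peak lies within tolerance at or above the rule's
    relative-intensity floor.
    """
    rule = next(
        (r for r in rules
         if r.applies_to(candidate.series, spec.polarity, spec.ms_level)),
        None,
    )
    if rule is None:
        return MatchResult((), False, "no applicable rule")

    if spec.ms_level == 2:
        frags = predict_fragments(candidate, spec.polarity, 2)
        tolp, tolm = tol_ppm, None
    else:
        pathway = _select_ms3_pathway(spec, candidate)
        if pathway is None:
            return MatchResult((), False, "MS3 precursor matches no predicted ion",
                               rule)
        frags = predict_fragments(candidate, spec.polarity, 3,
                                  precursor_label=pathway)
        tolp, tolm = None, tol_mz_ms3
    matched = _match_fragment_list(spec, frags, tolp, tolm,
                                   rule.min_relative_intensity)
    labels = {m.fragment.label for m in matched}
    ok = all(any(lbl in labels for lbl in group) for group in rule.mandatory)
    reason = "" if ok else "mandatory fragment group unmatched"
    return MatchResult(tuple(matched), ok, reason, rule)


# --- dual-polarity MS1 linking ---------------------------------------------

def dual_polarity_link(
    features_pos: Sequence[FeatureRecord],
    features_neg: Sequence[FeatureRecord],
    rt_tol: float = 0.1,
) -> list[tuple[FeatureRecord, FeatureRecord]]:
    """Pair positive and negative MS1 features of the same neutral species
    by nearest retention time within *rt_tol* minutes; each feature is used
    at most once, ties broken by smaller ppm error of the pair."""
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")

    def pair_ppm(p: FeatureRecord, q: FeatureRecord) -> float:
        err = 0.0
        for f in (p, q):
            if f.observed_mz > 0:
                err += abs(ppm_error(f.observed_mz, f.target.mz))
        return err

    candidates = [
        (abs(p.rt_apex - q.rt_apex), pair_ppm(p, q), i, j)
        for (i, p), (j, q) in itertools.product(
            enumerate(features_pos), enumerate(features_neg)
        )
        if abs(p.rt_apex - q.rt_apex) <= rt_tol
    ]
    candidates.sort()
    used_p: set[int] = set()
    used_q: set[int] = set()
    pairs = []
    for _, _, i, j in candidates:
        if i in used_p or j in used_q:
            continue
        used_p.add(i)
        used_q.add(j)
        pairs.append((features_pos[i], features_neg[j]))
    return pairs


# --- ECN retention filter ---------------------------------------------------

def _lad_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-absolute-deviation straight line via an exact linear program."""
    n = len(x)
    # variables: a+, a-, b+, b-, e_1..e_n ; minimise sum(e)
    c = np.concatenate([np.zeros(4), np.ones(n)])
    rows = []
    rhs = []
    for sign in (1.0, -1.0):
        block = np.zeros((n, 4 + n))
        block[:, 0] = sign
        block[:, 1] = -sign
        block[:, 2] = sign * x
        block[:, 3] = -sign * x
        block[:, 4:] = -np.eye(n)
        rows.append(block)
        rhs.append(sign * y)
    res = linprog(
        c,
        A_ub=np.vstack(rows),
        b_ub=np.concatenate(rhs),
        bounds=[(None, None)] * 4 + [(0, None)] * n,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"LAD fit failed: {res.message}")
    a = res.x[0] - res.x[1]
    b = res.x[2] - res.x[3]
    return float(a), float(b)


@dataclass
class EcnModel:
    """Per-group linear retention model rt = a + b * ECN.

    Groups are (series, R-group, total hydroxylations) — the structural
    drivers of reversed-phase retention within a subclass.  Groups smaller
    than ``min_group_size`` (or without ECN spread) are not fitted; their
    records pass the filter with a not-evaluated marker.
    """

    residual_tolerance: float = 0.5
    min_group_size: int = 4
    fits: dict[tuple, tuple[float, float, int]] = field(default_factory=dict)

    @staticmethod
    def group_key(sp: GipcSpecies) -> tuple:
        return (sp.series, sp.r_group, sp.ceramide.total_oh)

    def predict(self, sp: GipcSpecies) -> Optional[float]:
        fit = self.fits.get(self.group_key(sp))
        if fit is None:
            return None
        a, b, _ = fit
        return a + b * sp.ceramide.ecn

    def check(self, sp: GipcSpecies, rt: float) -> tuple[bool, bool]:
        """(passes, evaluated) for one record."""
        pred = self.predict(sp)
        if pred is None:
            return True, False
        return abs(rt - pred) <= self.residual_tolerance, True


def fit_ecn_filter(
    records: Sequence[tuple[GipcSpecies, float]],
    residual_tolerance: float = 0.5,
    min_group_size: int = 4,
) -> tuple[EcnModel, list[tuple[bool, bool]]]:
    """Fit the ECN model on provisional (species, rt) records and flag each.

    Returns the fitted model and, per input record, (c3 flag, evaluated
    flag).  Fitting is robust (least absolute deviations), so a single
    shifted record fails its own check without dragging the line along.
    """
    model = EcnModel(residual_tolerance, min_group_size)
    groups: dict[tuple, list[int]] = {}
    for idx, (sp, _rt) in enumerate(records):
        groups.setdefault(EcnModel.group_key(sp), []).append(idx)
    for key, idxs in groups.items():
        if len(idxs) < min_group_size:
            continue
        x = np.array([records[i][0].ceramide.ecn for i in idxs], dtype=float)
        y = np.array([records[i][1] for i in idxs], dtype=float)
        if len(np.unique(x)) < 2:
            continue
        a, b = _lad_line(x, y)
        model.fits[key] = (a, b, len(idxs))
    flags = [model.check(sp, rt) for sp, rt in records]
    return model, flags


# --- end-to-end annotation --------------------------------------------------

@dataclass(frozen=True)
class AnnotateConfig:
    ms1_tol_ppm: float = 5.0
    rt_tol: float = 0.1
    ms2_tol_ppm: float = 10.0
    ms3_tol_mz: float = 0.3
    msn_rt_window: float = 0.2
    min_points: int = 3
    ecn_residual_tolerance: float = 0.5
    ecn_min_group_size: int = 4

    def __post_init__(self) -> None:
        if self.rt_tol <= 0 or self.ms1_tol_ppm <= 0 or self.msn_rt_window <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class AnnotationRecord:
    species: GipcSpecies
    level: str
    rt_pos: float
    rt_neg: float
    ppm_pos: float
    ppm_neg: float
    area_pos: float
    area_neg: float
    matched_fragments: tuple[MatchedFragment, ...]
    c1_fragments: bool
    c2_dual_polarity: bool
    c3_ecn: bool
    ecn_evaluated: bool
    branching_evidence: bool
    ambiguous: bool = False

    @property
    def name(self) -> str:
        return self.species.name

    @property
    def rt(self) -> float:
        return 0.5 * (self.rt_pos + self.rt_neg)


def _split_runs(
    runs: Mapping[str, Sequence[SpectrumRecord]] | Sequence[SpectrumRecord],
) -> dict[str, list[SpectrumRecord]]:
    if isinstance(runs, Mapping):
        return {"+": list(runs.get("+", [])), "-": list(runs.get("-", []))}
    split: dict[str, list[SpectrumRecord]] = {"+": [], "-": []}
    for s in runs:
        split[s.polarity].append(s)
    return split


def annotate_run(
    runs: Mapping[str, Sequence[SpectrumRecord]] | Sequence[SpectrumRecord],
    targets: Sequence[TargetEntry],
    rules: Sequence[DecisionRule] = DEFAULT_RULES,
    cfg: AnnotateConfig = AnnotateConfig(),
) -> tuple[list[AnnotationRecord], list[dict]]:
    """Full annotation pipeline over one dual-polarity acquisition.

    Targets sharing a neutral formula (isobaric chain splits) are extracted
    once per polarity; every baseline-separated XIC peak is a candidate
    site.  Sites must link across polarities (criterion 2), accumulate
    fragment evidence from MS2/MS3 spectra near the apex (criterion 1), and
    survive the ECN retention filter (criterion 3).  Returns the accepted
    records (sorted by series, name, RT) and a rejection log.

    Deterministic: identical inputs and config give identical output.
    """
    by_pol = _split_runs(runs)
    if not by_pol["+"] or not by_pol["-"]:
        raise ValueError("annotation requires MS1 runs in both polarities")
    rejections: list[dict] = []

    # group molecular-species targets by neutral formula
    formula_groups: dict = {}
    for t in targets:
        formula_groups.setdefault(t.species.formula, []).append(t)

    xic = XicParams(tol_ppm=cfg.ms1_tol_ppm, min_points=cfg.min_points,
                    multi_peak=True)

    provisional: list[dict] = []
    for formula in sorted(formula_groups, key=str):
        group = formula_groups[formula]
        species_variants = []
        seen_names = set()
        for t in group:
            for sp in t.all_species:
                if sp.name not in seen_names:
                    seen_names.add(sp.name)
                    species_variants.append(sp)
        pos_targets = [t for t in group if t.polarity == "+"]
        neg_targets = [t for t in group if t.polarity == "-"]
        if not pos_targets or not neg_targets:
            continue
        # one representative target per polarity per adduct (they share m/z)
        feats_pos: list[FeatureRecord] = []
        for t in {t.adduct.name: t for t in pos_targets}.values():
            feats_pos.extend(extract_xic(by_pol["+"], t, xic))
        feats_neg: list[FeatureRecord] = []
        for t in {t.adduct.name: t for t in neg_targets}.values():
            feats_neg.extend(extract_xic(by_pol["-"], t, xic))

        if feats_pos and not feats_neg or feats_neg and not feats_pos:
            only = feats_pos or feats_neg
            for f in only:
                rejections.append({
                    "name": species_variants[0].to_species_level().name,
                    "rt": f.rt_apex,
                    "reason": "c2: feature in one polarity only",
                })
            continue
        pairs = dual_polarity_link(feats_pos, feats_neg, cfg.rt_tol)
        linked_pos = {id(p) for p, _ in pairs}
        linked_neg = {id(q) for _, q in pairs}
        for f in feats_pos:
            if id(f) not in linked_pos:
                rejections.append({
                    "name": species_variants[0].to_species_level().name,
                    "rt": f.rt_apex,
                    "reason": "c2: no negative-mode partner within rt_tol",
                })
        for f in feats_neg:
            if id(f) not in linked_neg:
                rejections.append({
                    "name": species_variants[0].to_species_level().name,
                    "rt": f.rt_apex,
                    "reason": "c2: no positive-mode partner within rt_tol",
                })

        for fpos, fneg in pairs:
            site_rt = 0.5 * (fpos.rt_apex + fneg.rt_apex)
            msn = []
            for pol in ("+", "-"):
                msn.extend(spectra_near(by_pol[pol], site_rt,
                                        cfg.msn_rt_window, 2, pol))
                msn.extend(spectra_near(by_pol[pol], site_rt,
                                        cfg.msn_rt_window, 3, pol))
            # restrict to spectra whose precursor chain starts at this
            # formula's precursor m/z
            prec_mzs = [t.mz for t in group]
            msn = [
                s for s in msn
                if any(abs(s.precursor_chain[0] - m) <= 0.7 for m in prec_mzs)
            ]
            evidence = _evaluate_site(msn, species_variants, rules, cfg)
            for sp, ev in evidence:
                provisional.append({
                    "species": sp,
                    "fpos": fpos,
                    "fneg": fneg,
                    "rt": site_rt,
                    **ev,
                })
            if not any(ev["c1"] for _, ev in evidence):
                rejections.append({
                    "name": species_variants[0].to_species_level().name,
                    "rt": site_rt,
                    "reason": "c1: characteristic fragments missing",
                })

    # ECN filter over provisional c1-passers
    passers = [p for p in provisional if p["c1"]]
    model, flags = fit_ecn_filter(
        [(p["species"], p["rt"]) for p in passers],
        cfg.ecn_residual_tolerance,
        cfg.ecn_min_group_size,
    )
    records: list[AnnotationRecord] = []
    for p, (c3, evaluated) in zip(passers, flags):
        if not c3:
            rejections.append({
                "name": p["species"].name,
                "rt": p["rt"],
                "reason": "c3: outside ECN retention model",
            })
            continue
        fpos, fneg = p["fpos"], p["fneg"]
        records.append(
            AnnotationRecord(
                species=p["species"],
                level=p["species"].level,
                rt_pos=fpos.rt_apex,
                rt_neg=fneg.rt_apex,
                ppm_pos=(ppm_error(fpos.observed_mz, fpos.target.mz)
                         if fpos.observed_mz > 0 else 0.0),
                ppm_neg=(ppm_error(fneg.observed_mz, fneg.target.mz)
                         if fneg.observed_mz > 0 else 0.0),
                area_pos=fpos.area,
                area_neg=fneg.area,
                matched_fragments=p["matched"],
                c1_fragments=True,
                c2_dual_polarity=True,
                c3_ecn=True,
                ecn_evaluated=evaluated,
                branching_evidence=p["branching"],
                ambiguous=p.get("ambiguous", False),
            )
        )
    records.sort(key=lambda r: (SERIES_ORDER.index(r.species.series),
                                r.name, r.rt))
    return records, rejections


def _evaluate_site(
    msn: Sequence[SpectrumRecord],
    species_variants: Sequence[GipcSpecies],
    rules: Sequence[DecisionRule],
    cfg: AnnotateConfig,
) -> list[tuple[GipcSpecies, dict]]:
    """Accumulate fragment evidence at one chromatographic site and decide
    the reporting level.

    Chain splits with MS3 chain-ion confirmation each yield a molecular-
    species candidate; when none is confirmed but MS2 evidence stands, a
    single species-level (sum composition) candidate is produced.
    """
    ms2 = [s for s in msn if s.ms_level == 2]
    ms3 = [s for s in msn if s.ms_level == 3]

    # variants sharing a formula may still differ in series/R-group (e.g.
    # an NAc glycan against an NH glycan with a longer ceramide), so MS2
    # evidence is gathered per distinct species-level projection
    projections: dict[str, GipcSpecies] = {}
    members: dict[str, list[GipcSpecies]] = {}
    for sp in species_variants:
        proj = sp.to_species_level()
        projections.setdefault(proj.name, proj)
        members.setdefault(proj.name, []).append(sp)

    ms2_evidence: dict[str, dict] = {}
    for pname, proj in projections.items():
        glycan_ok = ceramide_ok = branching = False
        matches: list[MatchedFragment] = []
        for s in ms2:
            res = match_spectrum(s, proj, rules, cfg.ms2_tol_ppm,
                                 cfg.ms3_tol_mz)
            matches.extend(res.matched)
            for m in res.matched:
                if m.fragment.diagnostic_class in ("glycan",
                                                   "inositol_phosphate"):
                    glycan_ok = True
                if m.fragment.diagnostic_class == "ceramide":
                    ceramide_ok = True
                if m.fragment.diagnostic_class == "branching":
                    branching = True
        ms2_evidence[pname] = {
            "c1": glycan_ok and ceramide_ok,
            "matched": tuple(matches),
            "branching": branching,
        }

    out: list[tuple[GipcSpecies, dict]] = []
    any_molecular = False
    for pname, proj in projections.items():
        ev = ms2_evidence[pname]
        for sp in members[pname]:
            if sp.level != "molecular_species":
                continue
            chain_matches: list[MatchedFragment] = []
            chain_ok = False
            for s in ms3:
                res = match_spectrum(s, sp, rules, cfg.ms2_tol_ppm,
                                     cfg.ms3_tol_mz)
                if res.verdict:
                    chain_ok = True
                    chain_matches.extend(res.matched)
            if chain_ok:
                any_molecular = True
                out.append((sp, {
                    "c1": ev["c1"],
                    "matched": ev["matched"] + tuple(chain_matches),
                    "branching": ev["branching"],
                    "ambiguous": False,
                }))
    if not any_molecular:
        # no chain-split confirmation: report at species level, choosing
        # the projection with the most matched fragments; unresolved ties
        # are emitted flagged as ambiguous rather than dropped
        best = max(len(ms2_evidence[p]["matched"]) for p in projections)
        winners = [
            p for p in projections
            if len(ms2_evidence[p]["matched"]) == best
        ]
        passing = [p for p in winners if ms2_evidence[p]["c1"]] or winners[:1]
        for pname in sorted(passing):
            ev = ms2_evidence[pname]
            out.append((projections[pname], {
                "c1": ev["c1"],
                "matched": ev["matched"],
                "branching": ev["branching"],
                "ambiguous": len(passing) > 1,
            }))
    return out


def consolidate_replicates(
    per_run: Sequence[Sequence[AnnotationRecord]],
    min_runs: int = 2,
) -> list[str]:
    """Cross-replicate consolidation: species names annotated in at least
    *min_runs* of the replicate runs (the replicate-agreement rule)."""
    counts: dict[str, int] = {}
    for records in per_run:
        for name in {r.name for r in records}:
            counts[name] = counts.get(name, 0) + 1
    return sorted(n for n, c in counts.items() if c >= min_runs)


def annotations_table(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Annotation results as an exportable table (one row per record)."""
    return pd.DataFrame(
        {
            "name": [r.name for r in records],
            "series": [r.species.series for r in records],
            "r_group": [r.species.r_group or "" for r in records],
            "level": [r.level for r in records],
            "rt_pos": [round(r.rt_pos, 4) for r in records],
            "rt_neg": [round(r.rt_neg, 4) for r in records],
            "ppm_pos": [round(r.ppm_pos, 3) for r in records],
            "ppm_neg": [round(r.ppm_neg, 3) for r in records],
            "area_pos": [r.area_pos for r in records],
            "area_neg": [r.area_neg for r in records],
            "branching_evidence": [r.branching_evidence for r in records],
            "ecn_evaluated": [r.ecn_evaluated for r in records],
            "ambiguous": [r.ambiguous for r in records],
            "n_matched_fragments": [len(r.matched_fragments) for r in records],
        }
    )


# --- rule file I/O ----------------------------------------------------------

def write_rules(rules: Sequence[DecisionRule], path: str | Path) -> None:
    """Write rules as a human-editable text file, one ``[rule]`` block each;
    any-of groups are ``a | b``, multiple mandatory groups separated by ';'."""
    lines = []
    for r in rules:
        lines.append("[rule]")
        lines.append(f"series = {r.series}")
        lines.append(f"polarity = {r.polarity}")
        lines.append(f"ms_level = {r.ms_level}")
        lines.append(
            "mandatory = " + " ; ".join(" | ".join(g) for g in r.mandatory)
        )
        if r.optional:
            lines.append("optional = " + " , ".join(r.optional))
        lines.append(f"min_relative_intensity = {r.min_relative_intensity}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def load_rules(path: str | Path) -> list[DecisionRule]:
    rules = []
    block: dict[str, str] = {}

    def flush():
        if not block:
            return
        mandatory = tuple(
            tuple(lbl.strip() for lbl in grp.split("|") if lbl.strip())
            for grp in block["mandatory"].split(";")
        )
        optional = tuple(
            lbl.strip() for lbl in block.get("optional", "").split(",")
            if lbl.strip()
        )
        rules.append(
            DecisionRule(
                block["series"],
                block["polarity"],
                int(block["ms_level"]),
                mandatory,
                optional,
                float(block.get("min_relative_intensity", 0.01)),
            )
        )

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line == "[rule]":
            flush()
            block = {}
            continue
        key, _, value = line.partition("=")
        block[key.strip()] = value.strip()
    flush()
    return rules
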