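"""Decision-rule matching, dual-polarity linking, ECN filter, pipeline."""

import numpy as np
import pytest

from gipcms.annotate import (
    AnnotateConfig,
    DEFAULT_RULES,
    annotate_run,
    dual_polarity_link,
    fit_ecn_filter,
    load_rules,
    match_spectrum,
    write_rules,
)
from gipcms.chem import ADDUCTS, mz_of
from gipcms.masslist import TargetEntry, targets_for_species
from gipcms.model import GipcSpecies, CeramideSpec, parse_name
from gipcms.simulate import SimConfig, simulate_run
from gipcms.spectra import FeatureRecord, SpectrumRecord
from tests.conftest import compact_config

B_SP = parse_name("B-NH-18:0;O3/22:0")


def neg_ms2(peaks, precursor=1379.7822, rt=10.0):
    mz, inten = zip(*peaks)
    return SpectrumRecord(2, "-", rt, np.array(mz), np.array(inten),
                          precursor_chain=(precursor,))


class TestMatchSpectrum:
    def test_ip_anchored_negative_rule(self):
        spec = neg_ms2([(259.0226, 1e5), (241.0120, 5e4), (421.0750, 2e4)])
        res = match_spectrum(spec, B_SP)
        assert res.verdict
        labels = {m.fragment.label for m in res.matched}
        assert {"IP", "IP-H2O", "IP+Hex"} <= labels

    def test_missing_mandatory_fragments(self):
        spec = neg_ms2([(421.0750, 2e4), (800.0, 1e5)])
        res = match_spectrum(spec, B_SP)
        assert not res.verdict
        assert "mandatory" in res.reason

    def test_no_applicable_rule(self):
        spec = neg_ms2([(259.0226, 1e5)])
        res = match_spectrum(spec, B_SP, rules=[])
        assert not res.verdict
        assert "no applicable rule" in res.reason

    def test_intensity_floor_suppresses_trace_matches(self):
        spec = neg_ms2([(259.0226, 1.0), (800.0, 1e6)])  # IP at 1e-6 of base
        assert not match_spectrum(spec, B_SP).verdict

    def test_ms3_chain_evidence_is_split_specific(self):
        sp_a = parse_name("B-NH-18:0;O3/24:1")
        sp_b = parse_name("B-NH-18:1;O3/24:0")
        prec = mz_of(sp_a.formula, ADDUCTS["[M+H]+"])
        from gipcms.fragments import predict_fragments

        z0 = next(f for f in predict_fragments(sp_a, "+", 2)
                  if f.label == "Z0")
        ions = predict_fragments(sp_a, "+", 3, precursor_label="Z0")
        spec = SpectrumRecord(
            3, "+", 10.0,
            np.array([f.mz for f in ions]),
            np.full(len(ions), 1e4),
            precursor_chain=(prec, z0.mz),
        )
        assert match_spectrum(spec, sp_a).verdict
        assert not match_spectrum(spec, sp_b).verdict


class TestDualPolarityLink:
    def _feat(self, rt, polarity, mz_err_ppm=0.0):
        adduct = ADDUCTS["[M+H]+"] if polarity == "+" else ADDUCTS["[M-H]-"]
        t = TargetEntry(B_SP, adduct, mz_of(B_SP.formula, adduct))
        return FeatureRecord(t, rt, 1e5, polarity,
                             observed_mz=t.mz * (1 + mz_err_ppm * 1e-6))

    def test_within_tolerance_pairs(self):
        pairs = dual_polarity_link([self._feat(10.00, "+")],
                                   [self._feat(10.05, "-")], rt_tol=0.1)
        assert len(pairs) == 1

    def test_beyond_tolerance_rejected(self):
        pairs = dual_polarity_link([self._feat(10.00, "+")],
                                   [self._feat(10.25, "-")], rt_tol=0.1)
        assert pairs == []

    def test_nearest_wins_other_left_unpaired(self):
        pos = [self._feat(10.00, "+")]
        neg = [self._feat(10.08, "-"), self._feat(10.02, "-")]
        pairs = dual_polarity_link(pos, neg, rt_tol=0.1)
        assert len(pairs) == 1
        assert pairs[0][1].rt_apex == 10.02

    def test_rt_tie_broken_by_ppm(self):
        pos = [self._feat(10.00, "+")]
        neg = [self._feat(10.02, "-", mz_err_ppm=4.0),
               self._feat(9.98, "-", mz_err_ppm=0.5)]
        pairs = dual_polarity_link(pos, neg, rt_tol=0.1)
        assert pairs[0][1].observed_mz == pytest.approx(
            neg[1].observed_mz, abs=1e-6
        )


def _line_records(slope=0.35, intercept=2.0, n=6):
    records = []
    for fa_c in range(20, 20 + n):
        sp = GipcSpecies("B", "NH", CeramideSpec.molecular(18, 0, 3, fa_c, 0, 0))
        records.append((sp, intercept + slope * sp.ceramide.ecn))
    return records


class TestEcnFilter:
    def test_exact_line_recovered(self):
        records = _line_records()
        model, flags = fit_ecn_filter(records)
        (a, b, n), = model.fits.values()
        assert b == pytest.approx(0.35, abs=1e-6)
        assert a == pytest.approx(2.0, abs=1e-4)
        assert all(ok and evaluated for ok, evaluated in flags)

    def test_single_shifted_record_fails_alone(self):
        records = _line_records()
        sp, rt = records[2]
        records[2] = (sp, rt + 2.0)
        model, flags = fit_ecn_filter(records, residual_tolerance=0.5)
        assert [ok for ok, _ in flags] == [True, True, False, True, True, True]

    def test_undersized_group_not_evaluated(self):
        records = _line_records(n=2)
        model, flags = fit_ecn_filter(records, min_group_size=4)
        assert flags == [(True, False), (True, False)]
        assert model.fits == {}

    def test_groups_fit_independently(self):
        high = [
            (GipcSpecies("B", "NH",
                         CeramideSpec.molecular(18, 0, 3, fa_c, 0, 1)), rt)
            for (sp, rt), fa_c in zip(_line_records(slope=0.30), range(20, 26))
        ]
        model, flags = fit_ecn_filter(_line_records() + high)
        assert len(model.fits) == 2


class TestAnnotateRun:
    def test_clean_run_full_recovery(self, clean_run):
        cfg, truth, runs = clean_run
        records, rejected = annotate_run(runs, truth.targets())
        assert {r.name for r in records} == \
               {e.expected_name for e in truth.true_entries}
        assert all(r.c1_fragments and r.c2_dual_polarity and r.c3_ecn
                   for r in records)
        assert all(r.level == "molecular_species" for r in records)

    def test_rt_shifted_decoys_rejected_with_c3(self):
        cfg = compact_config(seed=21, n_decoys_rt_shifted=3)
        truth, runs = simulate_run(cfg)
        records, rejected = annotate_run(runs, truth.targets())
        names = {r.name for r in records}
        decoy_names = {e.expected_name for e in truth.decoys}
        assert not names & decoy_names
        c3_rejects = {r["name"] for r in rejected if r["reason"].startswith("c3")}
        assert decoy_names <= c3_rejects

    def test_single_polarity_decoys_fail_c2(self):
        cfg = compact_config(seed=22, n_decoys_single_polarity=3)
        truth, runs = simulate_run(cfg)
        records, rejected = annotate_run(runs, truth.targets())
        decoy_names = {e.expected_name for e in truth.decoys}
        assert not {r.name for r in records} & decoy_names

    def test_fragment_free_decoys_fail_c1(self):
        cfg = compact_config(seed=23, n_decoys_fragment_free=3)
        truth, runs = simulate_run(cfg)
        records, rejected = annotate_run(runs, truth.targets())
        decoy_proj = {e.species.to_species_level().name for e in truth.decoys}
        record_proj = {r.species.to_species_level().name for r in records}
        assert not record_proj & decoy_proj
        assert any(r["reason"].startswith("c1") for r in rejected)

    def test_removing_ms3_demotes_to_species_level(self, clean_run):
        cfg, truth, runs = clean_run
        no_ms3 = {p: [s for s in specs if s.ms_level != 3]
                  for p, specs in runs.items()}
        records, _ = annotate_run(no_ms3, truth.targets())
        assert records, "MS2 evidence alone must still annotate"
        assert all(r.level == "species" for r in records)
        expected = {e.species.to_species_level().name
                    for e in truth.true_entries}
        assert {r.name for r in records} == expected

    def test_tolerance_monotonicity(self, clean_run):
        cfg, truth, runs = clean_run
        targets = truth.targets()
        base = annotate_run(runs, targets)[0]
        for tighter in (
            AnnotateConfig(ms1_tol_ppm=2.0),
            AnnotateConfig(rt_tol=0.02),
            AnnotateConfig(ms2_tol_ppm=4.0),
            AnnotateConfig(ecn_residual_tolerance=0.1),
        ):
            tightened = annotate_run(runs, targets, cfg=tighter)[0]
            assert {r.name for r in tightened} <= {r.name for r in base}

    def test_deterministic_output_order(self, clean_run):
        cfg, truth, runs = clean_run
        a = annotate_run(runs, truth.targets())[0]
        b = annotate_run(runs, truth.targets())[0]
        assert [(r.name, r.rt_pos) for r in a] == [(r.name, r.rt_pos) for r in b]
        keys = [(r.species.series, r.name, r.rt) for r in a]
        assert keys == sorted(keys)

    def test_soundness_of_emitted_records(self, clean_run):
        cfg, truth, runs = clean_run
        records, _ = annotate_run(runs, truth.targets())
        for r in records:
            assert r.c1_fragments and r.c2_dual_polarity and r.c3_ecn
            assert abs(r.ppm_pos) <= 5.0 and abs(r.ppm_neg) <= 5.0
            assert abs(r.rt_pos - r.rt_neg) <= 0.1

    def test_requires_both_polarities(self, clean_run):
        cfg, truth, runs = clean_run
        with pytest.raises(ValueError):
            annotate_run({"+": runs["+"], "-": []}, truth.targets())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AnnotateConfig(rt_tol=0.0)


class TestIsomerResolution:
    def test_isobaric_pair_resolved_at_distinct_rts(self):
        """Chromatographically separated isobaric chain splits yield two
        molecular-species records at their own retention times."""
        from tests.conftest import isomer_pair_scenario

        entries, runs, iso_a, iso_b = isomer_pair_scenario()
        targets = targets_for_species([e.species for e in entries])
        records, _ = annotate_run(runs, targets)
        by_name = {r.name: r for r in records}
        assert iso_a.name in by_name and iso_b.name in by_name
        assert by_name[iso_a.name].level == "molecular_species"
        assert by_name[iso_b.name].level == "molecular_species"
        assert by_name[iso_b.name].rt - by_name[iso_a.name].rt == \
               pytest.approx(0.4, abs=0.05)


class TestFullSearchSpace:
    def test_annotation_against_full_combinatorial_list(self):
        """Annotating against the entire combinatorial inclusion list —
        where isobaric rows collapse chain splits and even different
        series/R-group glycans can share one formula — still recovers
        exactly the simulated species at their correct levels."""
        from gipcms.masslist import ChainSpace, generate_targets

        truth, runs = simulate_run(SimConfig(seed=5, n_true=6))
        targets = generate_targets(ChainSpace())
        records, _ = annotate_run(runs, targets)
        assert {(r.name, r.level) for r in records} == {
            (e.expected_name, e.expected_level) for e in truth.true_entries
        }
        assert not any(r.ambiguous for r in records)


class TestRuleFiles:
    def test_rules_round_trip(self, tmp_path):
        path = tmp_path / "rules.txt"
        write_rules(DEFAULT_RULES, path)
        back = load_rules(path)
        assert tuple(back) == DEFAULT_RULES
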