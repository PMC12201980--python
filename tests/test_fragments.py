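"""In-silico fragment prediction: diagnostic masses, ladders, chain ions."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gipcms.chem import ADDUCTS, mz_of
from gipcms.fragments import (
    complementary_pair_check,
    fragments_table,
    load_chain_fragment_table,
    predict_fragments,
)
from gipcms.masslist import ChainSpace
from gipcms.model import GipcSpecies, parse_name


def frag_map(sp, polarity, ms_level=2, precursor=None):
    return {f.label: f for f in predict_fragments(sp, polarity, ms_level,
                                                  precursor_label=precursor)}


class TestDiagnostics:
    def test_ip_family_negative(self):
        frags = frag_map(parse_name("B-NH-18:0;O3/22:0"), "-")
        assert frags["IP"].mz == pytest.approx(259.0224, abs=5e-4)
        assert frags["IP"].nominal == 259
        assert frags["IP-H2O"].mz == pytest.approx(241.0118, abs=5e-4)
        assert frags["IP-H2O"].nominal == 241

    def test_ip_positive(self):
        frags = frag_map(parse_name("C-Hex-NH-18:0;O3/24:0"), "+")
        assert frags["IP"].mz == pytest.approx(261.0370, abs=5e-4)
        assert frags["IP"].nominal == 261

    def test_branching_ions_negative_only(self):
        neg = frag_map(parse_name("B-NH-18:0;O3/22:0"), "-")
        assert neg["IP+Hex"].mz == pytest.approx(421.0753, abs=5e-4)
        assert neg["IP+Hex"].nominal == 421
        assert neg["IP+Hex-H2O"].mz == pytest.approx(403.0647, abs=5e-4)
        assert neg["IP+Hex-H2O"].nominal == 403
        pos = frag_map(parse_name("B-NH-18:0;O3/22:0"), "+")
        assert "IP+Hex" not in pos

    def test_series_zero_lacks_branching_ions(self):
        frags = frag_map(parse_name("0-18:0;O3/22:0"), "-")
        assert frags["IP"].nominal == 259
        assert "IP+Hex" not in frags
        assert "IP+Hex-H2O" not in frags

    def test_535_marker_only_for_four_plus_residues(self):
        c_series = frag_map(parse_name("C-NH-18:0;O3/24:0"), "-")
        assert c_series["BR535"].raw_mz == 535.0
        b_series = frag_map(parse_name("B-NH-18:0;O3/22:0"), "-")
        assert "BR535" not in b_series

    @pytest.mark.parametrize(
        "name, z0_nominal", [("B-NH-18:0;O3/22:0", 622),
                             ("C-Hex-NH-18:0;O3/24:0", 650)]
    )
    def test_z0_ceramide_fragment(self, name, z0_nominal):
        frags = frag_map(parse_name(name), "+")
        assert frags["Z0"].nominal == z0_nominal
        assert frags["Y0"].mz - frags["Z0"].mz == pytest.approx(18.0106, abs=1e-3)

    def test_head_group_ion_760(self):
        # IP + HexA + HexN + Hex, positive: the C-series head-group ion
        frags = frag_map(parse_name("C-Hex-NH-18:0;O3/24:0"), "+")
        assert frags["HG3"].mz == pytest.approx(760.1907, abs=5e-4)
        assert frags["HG3"].nominal == 760


class TestMs3:
    def test_requires_precursor_label(self):
        with pytest.raises(ValueError):
            predict_fragments(parse_name("B-NH-18:0;O3/22:0"), "+", 3)

    def test_z0_pathway_chain_ions(self):
        sp = parse_name("B-NH-18:0;O3/22:0")
        frags = frag_map(sp, "+", 3, precursor="Z0")
        assert {"W", "W-H2O", "W-2H2O", "V"} <= set(frags)
        # W = dehydrated protonated sphingoid base; successive water losses
        assert frags["W"].mz - frags["W-H2O"].mz == pytest.approx(18.0106,
                                                                  abs=1e-3)

    def test_isobaric_splits_give_distinct_chain_ions(self):
        a = frag_map(parse_name("B-NH-18:0;O3/24:1"), "+", 3, precursor="Z0")
        b = frag_map(parse_name("B-NH-18:1;O3/24:0"), "+", 3, precursor="Z0")
        assert abs(a["W"].mz - b["W"].mz) > 1.0
        assert abs(a["V"].mz - b["V"].mz) > 1.0

    def test_species_level_has_no_chain_ions(self):
        sp = parse_name("B-NH-40:0;O3")
        assert predict_fragments(sp, "+", 3, precursor_label="Z0") == []

    def test_head_group_pathway_restricted_to_precursor(self):
        sp = parse_name("C-NH-18:0;O3/24:0")
        frags = predict_fragments(sp, "+", 3, precursor_label="HG3")
        hg3 = frag_map(sp, "+")["HG3"]
        for f in frags:
            if f.formula is not None:
                assert f.mz <= hg3.mz + 0.01


class TestInvariants:
    def test_fragments_subset_of_precursor_elements(self):
        for name in ("B-NH-18:0;O3/22:0", "C-Hex-NH-18:0;O3/24:0",
                     "D-NH-18:1;O3/24:0;O", "A-NAc-18:0;O2/16:0"):
            sp = parse_name(name)
            total = sp.formula
            for pol in "+-":
                for f in predict_fragments(sp, pol, 2):
                    if f.formula is not None:
                        assert f.formula in total, (name, f.label)

    def test_chain_table_is_editable_data(self):
        table = load_chain_fragment_table()
        assert {"label", "basis", "delta", "polarity"} <= set(table.columns)
        assert "W" in set(table["label"])

    def test_fragments_table_export(self):
        frags = predict_fragments(parse_name("B-NH-18:0;O3/22:0"), "-", 2)
        df = fragments_table(frags)
        assert len(df) == len(frags)
        assert (df.loc[df.label == "IP", "nominal"] == 259).all()


_CERAMIDES = ChainSpace().ceramides()


@settings(max_examples=50, deadline=None)
@given(
    st.sampled_from(["A", "B", "C", "D"]),
    st.sampled_from(["OH", "NH", "NAc"]),
    st.sampled_from(_CERAMIDES),
)
def test_complementary_ion_sum_rule(series, r_group, cer):
    """B/Y and C/Z pairs from the same cleavage sum to the precursor in
    both polarities."""
    sp = GipcSpecies(series, r_group, cer)
    n = len(sp.residues)
    for pol, adduct in (("+", ADDUCTS["[M+H]+"]), ("-", ADDUCTS["[M-H]-"])):
        prec = mz_of(sp.formula, adduct)
        frags = frag_map(sp, pol)
        for k in range(1, n + 1):
            b, y = frags[f"B{k}"], frags[f"Y{n - k + 1}"]
            c, z = frags[f"C{k}"], frags[f"Z{n - k + 1}"]
            assert complementary_pair_check(b.mz, y.mz, prec, pol)
            assert complementary_pair_check(c.mz, z.mz, prec, pol)


def test_mismatched_pair_fails():
    a = parse_name("B-NH-18:0;O3/22:0")
    b = parse_name("B-NH-18:0;O3/24:0")
    prec = mz_of(a.formula, ADDUCTS["[M+H]+"])
    fa, fb = frag_map(a, "+"), frag_map(b, "+")
    assert not complementary_pair_check(fa["B1"].mz, fb["Y3"].mz, prec, "+")
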