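"""Spectrum model, mzML round trip, XIC extraction."""

import math

import numpy as np
import pytest

from gipcms.chem import ADDUCTS
from gipcms.masslist import TargetEntry
from gipcms.model import parse_name
from gipcms.simulate import write_mzml
from gipcms.spectra import (
    SpectrumRecord,
    XicParams,
    centroid_profile,
    extract_xic,
    read_run,
)

SP = parse_name("B-NH-18:0;O3/22:0")
TARGET = TargetEntry(SP, ADDUCTS["[M+H]+"], 1381.7967)


def gaussian_run(rt0=10.0, height=1e6, sigma=0.04, cycle=0.02, mz=1381.7967,
                 polarity="+", rng=None):
    spectra = []
    for i in range(101):
        t = rt0 - 1.0 + i * cycle
        h = height * math.exp(-0.5 * ((t - rt0) / sigma) ** 2)
        if h < height * 1e-4:
            peaks = ([500.0], [10.0])
        else:
            peaks = ([500.0, mz], [10.0, h])
        spectra.append(SpectrumRecord(1, polarity, t, np.array(peaks[0]),
                                      np.array(peaks[1])))
    return spectra


class TestSpectrumRecord:
    def test_peaks_sorted_on_construction(self):
        s = SpectrumRecord(1, "+", 1.0, np.array([300.0, 100.0, 200.0]),
                           np.array([3.0, 1.0, 2.0]))
        assert list(s.mz) == [100.0, 200.0, 300.0]
        assert list(s.intensity) == [1.0, 2.0, 3.0]

    def test_msn_requires_precursor(self):
        with pytest.raises(ValueError):
            SpectrumRecord(2, "+", 1.0, np.array([100.0]), np.array([1.0]))

    def test_centroid_profile_picks_local_maxima(self):
        mz = np.linspace(100, 101, 11)
        inten = np.array([0, 1, 5, 1, 0, 0, 2, 8, 2, 0, 0], dtype=float)
        cmz, cint = centroid_profile(mz, inten, min_intensity=3.0)
        assert list(cint) == [5, 8]
        cmz, cint = centroid_profile(mz, inten, min_intensity=6.0)
        assert list(cint) == [8]


class TestXic:
    def test_gaussian_area_within_two_percent(self):
        sigma, height = 0.04, 1e6
        run = gaussian_run(sigma=sigma, height=height)
        feats = extract_xic(run, TARGET, XicParams(tol_ppm=5))
        assert len(feats) == 1
        expected = height * sigma * math.sqrt(2 * math.pi)
        assert feats[0].area == pytest.approx(expected, rel=0.02)
        assert feats[0].rt_apex == pytest.approx(10.0, abs=0.02)

    def test_no_matching_points_is_absent(self):
        run = gaussian_run(mz=900.0)
        assert extract_xic(run, TARGET, XicParams(tol_ppm=5)) == []

    def test_min_points_threshold(self):
        run = gaussian_run()
        feats = extract_xic(run, TARGET, XicParams(tol_ppm=5, min_points=500))
        assert feats == []

    def test_two_baseline_separated_peaks(self):
        # two isomer elution peaks of the same m/z, 1 min apart
        run = gaussian_run(rt0=10.0)
        shifted = gaussian_run(rt0=11.0)
        merged = []
        for a, b in zip(run, shifted):
            mz = np.concatenate([a.mz, b.mz])
            inten = np.concatenate([a.intensity, b.intensity])
            merged.append(SpectrumRecord(1, "+", a.rt, mz, inten))
        # extend time axis so the second peak is covered
        merged += gaussian_run(rt0=11.0)[51:]
        feats = extract_xic(merged, TARGET, XicParams(tol_ppm=5))
        apexes = sorted(f.rt_apex for f in feats)
        assert len(feats) == 2
        assert apexes[0] == pytest.approx(10.0, abs=0.03)
        assert apexes[1] == pytest.approx(11.0, abs=0.03)
        single = extract_xic(merged, TARGET,
                             XicParams(tol_ppm=5, multi_peak=False))
        assert len(single) == 1

    def test_area_invariant_under_peak_permutation(self):
        run = gaussian_run()
        shuffled = []
        rng = np.random.default_rng(0)
        for s in run:
            order = rng.permutation(len(s.mz))
            shuffled.append(SpectrumRecord(1, "+", s.rt, s.mz[order],
                                           s.intensity[order]))
        a = extract_xic(run, TARGET, XicParams())[0].area
        b = extract_xic(shuffled, TARGET, XicParams())[0].area
        assert a == b

    def test_halving_tolerance_never_increases_area(self):
        run = gaussian_run()
        for tol in (20.0, 10.0, 5.0, 2.5):
            wide = extract_xic(run, TARGET, XicParams(tol_ppm=tol))
            narrow = extract_xic(run, TARGET, XicParams(tol_ppm=tol / 2))
            wide_area = sum(f.area for f in wide)
            narrow_area = sum(f.area for f in narrow)
            assert narrow_area <= wide_area + 1e-9


class TestMzmlRoundTrip:
    def test_write_read_preserves_everything(self, tmp_path):
        spectra = [
            SpectrumRecord(1, "+", 1.5, np.array([500.0, 1381.79671]),
                           np.array([10.0, 1e6])),
            SpectrumRecord(2, "+", 1.51, np.array([261.03700, 622.61327]),
                           np.array([5e4, 2e5]),
                           precursor_chain=(1381.7967,), precursor_charge=1),
            SpectrumRecord(3, "+", 1.52, np.array([283.2, 300.28955]),
                           np.array([1e4, 9e4]),
                           precursor_chain=(1381.7967, 622.6133),
                           precursor_charge=1),
            SpectrumRecord(1, "-", 1.53, np.array([1379.78215]),
                           np.array([8e5])),
        ]
        path = tmp_path / "run.mzml"
        write_mzml(spectra, path)
        back = read_run(path)
        assert len(back) == len(spectra)
        for orig, rt in zip(spectra, back):
            assert rt.ms_level == orig.ms_level
            assert rt.polarity == orig.polarity
            assert rt.rt == pytest.approx(orig.rt, abs=1e-6)
            np.testing.assert_allclose(rt.mz, orig.mz, atol=1e-4)
            np.testing.assert_allclose(rt.intensity, orig.intensity, rtol=1e-9)
        # MS3 exposes the full ancestor chain
        ms3 = back[2]
        assert len(ms3.precursor_chain) == 2
        assert ms3.precursor_chain[0] == pytest.approx(1381.7967, abs=1e-4)
        assert ms3.precursor_mz == pytest.approx(622.6133, abs=1e-4)

    def test_corrupted_file_raises(self, tmp_path):
        path = tmp_path / "broken.mzml"
        path.write_text("<mzML><spectrumList><spectrum>")
        with pytest.raises(ValueError):
            read_run(path)

    def test_rt_seconds_converted_to_minutes(self, tmp_path):
        path = tmp_path / "run.mzml"
        spectra = [SpectrumRecord(1, "+", 2.0, np.array([500.0]),
                                  np.array([1.0]))]
        write_mzml(spectra, path)
        text = path.read_text().replace(
            'value="2.000000" unitCvRef="UO" unitAccession="UO:0000031" '
            'unitName="minute"',
            'value="120.000000" unitCvRef="UO" unitAccession="UO:0000010" '
            'unitName="second"',
        )
        path.write_text(text)
        assert read_run(path)[0].rt == pytest.approx(2.0)
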