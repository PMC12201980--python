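"""Uniform spectrum model, mzML reading, and MS1 ion-chromatogram extraction.

Retention times are minutes everywhere; unit conversion happens at the mzML
boundary.  Polarity is taken from per-spectrum metadata, never from file
names, so mixed-polarity runs and paired single-polarity files both work.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .chem import ppm_window
from .masslist import TargetEntry

__all__ = [
    "SpectrumRecord",
    "FeatureRecord",
    "XicParams",
    "read_run",
    "extract_xic",
    "centroid_profile",
    "spectra_near",
]


@dataclass
class SpectrumRecord:
    """One centroided spectrum with acquisition metadata.

    ``precursor_chain`` lists every isolation step that led to this
    spectrum, outermost first; for an MS3 scan it is (MS2 precursor m/z
    selected from MS1, fragment m/z selected from MS2) and ``precursor_mz``
    is its last element.
    """

    ms_level: int
    polarity: str  # "+" | "-"
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    precursor_chain: tuple[float, ...] = ()
    precursor_charge: Optional[int] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must be parallel")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.ms_level >= 2 and not self.precursor_chain:
            raise ValueError(f"MS{self.ms_level} spectrum lacks precursor metadata")

    @property
    def precursor_mz(self) -> Optional[float]:
        return self.precursor_chain[-1] if self.precursor_chain else None

    def intensity_in(self, lo: float, hi: float) -> float:
        """Summed intensity of peaks with lo <= m/z <= hi."""
        i = np.searchsorted(self.mz, lo, side="left")
        j = np.searchsorted(self.mz, hi, side="right")
        return float(self.intensity[i:j].sum())

    def matched_peaks(self, lo: float, hi: float) -> tuple[float, float]:
        """(summed intensity, intensity-weighted mean m/z) within a window;
        the mean is 0.0 when nothing matches."""
        i = np.searchsorted(self.mz, lo, side="left")
        j = np.searchsorted(self.mz, hi, side="right")
        total = float(self.intensity[i:j].sum())
        if total <= 0:
            return 0.0, 0.0
        wmz = float((self.mz[i:j] * self.intensity[i:j]).sum() / total)
        return total, wmz

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0


@dataclass(frozen=True)
class FeatureRecord:
    """An MS1 chromatographic feature for one target."""

    target: TargetEntry
    rt_apex: float
    area: float
    polarity: str
    rt_start: float = 0.0
    rt_end: float = 0.0
    n_points: int = 0
    observed_mz: float = 0.0


@dataclass(frozen=True)
class XicParams:
    """Extraction settings: ppm tolerance, optional RT window (minutes,
    centred on ``rt_center``), minimum matched points per peak, and whether
    baseline-separated peaks are reported separately (isomer resolution)."""

    tol_ppm: float = 5.0
    rt_center: Optional[float] = None
    rt_window: Optional[float] = None
    min_points: int = 3
    multi_peak: bool = True

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")


def centroid_profile(
    mz: np.ndarray, intensity: np.ndarray, min_intensity: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Local-maximum peak picking for profile spectra: keep points higher
    than both neighbours and above the intensity floor."""
    if len(mz) < 3:
        keep = intensity >= min_intensity
        return mz[keep], intensity[keep]
    inner = (intensity[1:-1] >= intensity[:-2]) & (intensity[1:-1] > intensity[2:])
    keep = np.zeros(len(mz), dtype=bool)
    keep[1:-1] = inner
    keep &= intensity >= min_intensity
    return mz[keep], intensity[keep]


# mzML parsing is accession-driven so files from any writer are accepted
# regardless of cvParam name spellings.
_ACC_MS_LEVEL = "MS:1000511"
_ACC_POSITIVE = "MS:1000130"
_ACC_NEGATIVE = "MS:1000129"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, dict]:
    """accession -> {value, unit} for cvParams directly under *elem*."""
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession")] = {
                "value": child.get("value", ""),
                "unit": child.get("unitName", ""),
            }
    return out


def _decode_binary_array(bda) -> np.ndarray:
    import base64
    import zlib

    params = _cv_params(bda)
    payload = ""
    for child in bda:
        if _local(child.tag) == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_FLOAT32 in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float), params


def _parse_spectrum_elem(elem, min_intensity: float) -> SpectrumRecord:
    params = _cv_params(elem)
    if _ACC_MS_LEVEL not in params:
        raise ValueError(f"spectrum {elem.get('id')!r} lacks an ms level")
    ms_level = int(params[_ACC_MS_LEVEL]["value"])
    if _ACC_POSITIVE in params:
        polarity = "+"
    elif _ACC_NEGATIVE in params:
        polarity = "-"
    else:
        raise ValueError(f"spectrum {elem.get('id')!r} lacks polarity metadata")

    rt_min = None
    mz = inten = None
    chain: list[float] = []
    charge = None
    for sub in elem.iter():
        tag = _local(sub.tag)
        if tag == "scan":
            sp = _cv_params(sub)
            if _ACC_SCAN_START in sp:
                value = float(sp[_ACC_SCAN_START]["value"])
                unit = sp[_ACC_SCAN_START]["unit"]
                rt_min = value / 60.0 if unit == "second" else value
        elif tag == "selectedIon":
            sp = _cv_params(sub)
            if _ACC_SELECTED_MZ in sp:
                chain.append(float(sp[_ACC_SELECTED_MZ]["value"]))
            if _ACC_CHARGE in sp:
                charge = int(sp[_ACC_CHARGE]["value"])
        elif tag == "binaryDataArray":
            arr, aparams = _decode_binary_array(sub)
            if _ACC_MZ_ARRAY in aparams:
                mz = arr
            elif _ACC_INTENSITY_ARRAY in aparams:
                inten = arr
    if rt_min is None:
        raise ValueError(f"spectrum {elem.get('id')!r} lacks a scan start time")
    if mz is None or inten is None:
        raise ValueError(f"spectrum {elem.get('id')!r} lacks peak arrays")
    if _ACC_PROFILE in params:
        mz, inten = centroid_profile(mz, inten, min_intensity)
    if ms_level >= 2 and not chain:
        raise ValueError(
            f"MS{ms_level} spectrum {elem.get('id')!r} lacks precursor metadata"
        )
    return SpectrumRecord(ms_level, polarity, rt_min, mz, inten,
                          tuple(chain), charge)


def read_run(path: str | Path, min_intensity: float = 0.0) -> list[SpectrumRecord]:
    """Read an mzML file into SpectrumRecords in file order.

    Plain and indexed mzML are both accepted; peak arrays may be 32- or
    64-bit floats, zlib-compressed or not.  Profile spectra are centroided
    by local-maximum picking with *min_intensity* as the floor.  MS2/MS3
    spectra without precursor metadata raise; a structurally broken file
    raises rather than silently returning a partial read.
    """
    import xml.etree.ElementTree as ET

    records: list[SpectrumRecord] = []
    try:
        for event, elem in ET.iterparse(str(path), events=("end",)):
            if _local(elem.tag) == "spectrum":
                records.append(_parse_spectrum_elem(elem, min_intensity))
                elem.clear()
    except ET.ParseError as exc:
        raise ValueError(f"unreadable mzML file {path}: {exc}") from exc
    return records


def extract_xic(
    run: Sequence[SpectrumRecord],
    target: TargetEntry,
    params: XicParams = XicParams(),
) -> list[FeatureRecord]:
    """Extract MS1 features for one target; an empty list means absent.

    The ion chromatogram sums peak intensities within the ppm window per
    MS1 spectrum of the target's polarity; contiguous non-zero stretches
    are integrated trapezoidally and the max-intensity point is the apex.
    With ``multi_peak`` unset only the largest-area peak is returned.
    """
    lo, hi = ppm_window(target.mz, params.tol_ppm)
    rts, heights, wmzs = [], [], []
    for spec in run:
        if spec.ms_level != 1 or spec.polarity != target.polarity:
            continue
        if params.rt_center is not None and params.rt_window is not None:
            if abs(spec.rt - params.rt_center) > params.rt_window:
                continue
        total, wmz = spec.matched_peaks(lo, hi)
        rts.append(spec.rt)
        heights.append(total)
        wmzs.append(wmz)
    if not rts:
        return []
    rts_arr = np.asarray(rts)
    order = np.argsort(rts_arr, kind="stable")
    rts_arr = rts_arr[order]
    heights_arr = np.asarray(heights)[order]
    wmz_arr = np.asarray(wmzs)[order]

    features: list[FeatureRecord] = []
    nz = heights_arr > 0
    i = 0
    n = len(rts_arr)
    while i < n:
        if not nz[i]:
            i += 1
            continue
        j = i
        while j < n and nz[j]:
            j += 1
        if j - i >= params.min_points:
            seg_rt = rts_arr[i:j]
            seg_h = heights_arr[i:j]
            apex = int(np.argmax(seg_h))
            features.append(
                FeatureRecord(
                    target=target,
                    rt_apex=float(seg_rt[apex]),
                    area=float(np.trapezoid(seg_h, seg_rt)),
                    polarity=target.polarity,
                    rt_start=float(seg_rt[0]),
                    rt_end=float(seg_rt[-1]),
                    n_points=j - i,
                    observed_mz=float(wmz_arr[i:j][apex]),
                )
            )
        i = j
    if not params.multi_peak and len(features) > 1:
        features = [max(features, key=lambda f: f.area)]
    return features


def spectra_near(
    run: Sequence[SpectrumRecord],
    rt: float,
    window: float,
    ms_level: int,
    polarity: Optional[str] = None,
) -> list[SpectrumRecord]:
    """Fragmentation spectra acquired within an RT window of a feature apex."""
    return [
        s
        for s in run
        if s.ms_level == ms_level
        and abs(s.rt - rt) <= window
        and (polarity is None or s.polarity == polarity)
    ]
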