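"""Relative quantification and sample bookkeeping.

No commercial GIPC standards exist, so abundances are reported as ratios:
MS1 peak area divided by the internal-standard (C16-lactosyl ceramide,
LacCer 18:1;O2/16:0) peak area and by the sample's dry weight, giving a
per-gram relative measure.  Group means follow the replicate-agreement
rule: the mean over biological replicates, set to zero when only a single
replicate is non-zero.  Row-wise z-scores put species on a common scale
for profile comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "normalize",
    "group_average",
    "zscore_rows",
    "moisture_percent",
    "read_sample_manifest",
    "abundance_matrix",
    "group_mean_table",
]


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: grouping, weights, internal-standard area."""

    sample_id: str
    group: str
    replicate: int
    dry_weight_g: float
    is_area: float
    fresh_weight_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dry_weight_g <= 0:
            raise ValueError("dry weight must be positive")
        if self.is_area <= 0:
            raise ValueError("internal-standard area must be positive")
        if self.fresh_weight_g is not None and self.fresh_weight_g < self.dry_weight_g:
            raise ValueError("fresh weight cannot be below dry weight")


def normalize(area: float, meta: SampleMeta) -> float:
    """Normalized ratio per gram dry weight:
    area / internal-standard area / dry weight.  Linear in area."""
    if area < 0:
        raise ValueError("peak area must be non-negative")
    return area / meta.is_area / meta.dry_weight_g


def group_average(ratios: Sequence[float]) -> float:
    """Replicate group mean with the single-replicate guard: the arithmetic
    mean over all replicates, except the result is 0 when exactly one
    replicate is non-zero (a species seen once is not trusted)."""
    if len(ratios) == 0:
        raise ValueError("empty replicate group")
    arr = np.asarray(ratios, dtype=float)
    if np.count_nonzero(arr) == 1:
        return 0.0
    return float(arr.mean())


def zscore_rows(
    table: pd.DataFrame, ddof: int = 0
) -> tuple[pd.DataFrame, list]:
    """Row-wise z-score scaling: each non-constant row to mean 0, SD 1
    (population SD by default).  Constant rows cannot be scaled; they are
    emitted as zeros and their labels returned as flagged."""
    if table.shape[1] < 2:
        raise ValueError("z-scoring needs at least two columns")
    values = table.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sds == 0).ravel()
    safe_sds = np.where(sds == 0, 1.0, sds)
    scaled = (values - means) / safe_sds
    scaled[constant, :] = 0.0
    out = pd.DataFrame(scaled, index=table.index, columns=table.columns)
    return out, list(table.index[constant])


def moisture_percent(fresh_weight_g: float, dry_weight_g: float) -> int:
    """Grain moisture, percent of fresh weight, rounded to nearest integer
    for reporting."""
    if fresh_weight_g <= 0:
        raise ValueError("fresh weight must be positive")
    if fresh_weight_g < dry_weight_g:
        raise ValueError("fresh weight cannot be below dry weight")
    return int(round(100.0 * (fresh_weight_g - dry_weight_g) / fresh_weight_g))


def read_sample_manifest(path: str | Path) -> list[SampleMeta]:
    """Sample manifest CSV: sample_id, group, replicate, fresh_g (optional),
    dry_g, is_area."""
    df = pd.read_csv(path)
    metas = []
    for row in df.itertuples(index=False):
        fresh = getattr(row, "fresh_g", None)
        metas.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                group=str(row.group),
                replicate=int(row.replicate),
                dry_weight_g=float(row.dry_g),
                is_area=float(row.is_area),
                fresh_weight_g=None if fresh is None or pd.isna(fresh)
                else float(fresh),
            )
        )
    return metas


def abundance_matrix(
    areas: pd.DataFrame, metas: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Normalize a species x sample area table (missing = 0) into ratios
    per gram dry weight."""
    by_id = {m.sample_id: m for m in metas}
    missing = [c for c in areas.columns if c not in by_id]
    if missing:
        raise KeyError(f"samples missing from manifest: {missing}")
    filled = areas.fillna(0.0)
    out = filled.copy().astype(float)
    for col in out.columns:
        m = by_id[col]
        out[col] = filled[col] / m.is_area / m.dry_weight_g
    return out


def group_mean_table(
    ratios: pd.DataFrame, metas: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Collapse replicate columns to group means under the replicate-
    agreement rule, one column per sample group (stable group order of
    first appearance)."""
    by_id = {m.sample_id: m for m in metas}
    groups: dict[str, list[str]] = {}
    for col in ratios.columns:
        groups.setdefault(by_id[col].group, []).append(col)
    data = {
        g: [group_average(ratios.loc[idx, cols].to_numpy()) for idx in ratios.index]
        for g, cols in groups.items()
    }
    return pd.DataFrame(data, index=ratios.index)
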