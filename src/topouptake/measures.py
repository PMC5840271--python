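"""Standard aggregate uptake measures: %ID/g and the tumor-to-heart ratio.

%ID/g (percent injected dose per gram) is the fraction of the injected
activity found in a region, per gram of tissue (density of water assumed):

    %ID/g = (uptake / injected_dose * 100) / (volume / 1000)

with uptake the summed decay-corrected voxel intensity over the region in
µCi, injected dose in µCi, and volume in mm³.  The tumor-to-heart ratio
T:H = tumor %ID/g / heart %ID/g controls for blood clearance of antibody.

These whole-region averages are the baseline the topological diagrams are
compared against; to probe heterogeneity they are also computed on the
high and low sub-regions of the ROI, split at the per-image 95th
percentile of voxel values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import IntensityFunction, RoiMask

__all__ = [
    "UptakeMeasure",
    "THRatio",
    "percent_id_per_g",
    "pidg_from_mean",
    "roi_measures",
    "tumor_to_heart",
    "h24_normalize_measure",
]


@dataclass
class UptakeMeasure:
    pidg: float
    region: str  # "all" | "high" | "low"
    uptake_total: float  # µCi
    volume: float  # mm³
    injected_dose: float  # µCi
    subject_id: str = ""
    group_id: str = ""
    hour: float = 0.0
    degenerate: bool = False  # high region undefined (constant image)


@dataclass
class THRatio:
    value: float
    region: str = "all"
    subject_id: str = ""
    hour: float = 0.0


def percent_id_per_g(uptake: float, injected_dose: float, volume: float) -> float:
    """%ID/g from total uptake (µCi), injected dose (µCi), and volume (mm³)."""
    if injected_dose <= 0:
        raise ValueError("injected dose must be positive")
    if volume <= 0:
        raise ValueError("region volume must be positive")
    return (uptake / injected_dose * 100.0) / (volume / 1000.0)


def pidg_from_mean(mean_intensity: float, injected_dose: float, voxel_volume: float) -> float:
    """%ID/g of a region given only its mean voxel intensity.

    Since uptake = mean * N and volume = N * voxel_volume, the region size N
    cancels; this lets heart %ID/g be computed from a heart-mean scalar.
    """
    return percent_id_per_g(mean_intensity, injected_dose, voxel_volume)


def roi_measures(
    f: IntensityFunction,
    roi: RoiMask | None,
    injected_dose: float,
    voxel_volume: float | None = None,
    percentile: float = 95.0,
) -> dict[str, UptakeMeasure]:
    """All/high/low %ID/g for one image, split at the per-image voxel-value percentile.

    High voxels are those at or above the percentile (linear interpolation)
    of the ROI voxel values; low voxels are the rest.  For a constant ROI
    the split is undefined: the high region is flagged empty and low = all.
    Uptake and volume of high and low recompose exactly to the whole ROI.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    mask = roi.mask if roi is not None else f.mask
    if f.f.shape != mask.shape:
        raise ValueError("intensity function and ROI shapes differ")
    vals = f.f[mask]
    if vals.size == 0:
        raise ValueError("ROI mask is empty")
    if voxel_volume is None:
        voxel_volume = f.voxel_volume_mm3
    meta = dict(subject_id=f.subject_id, group_id=f.group_id, hour=f.hour)

    def measure(region: str, v: np.ndarray, degenerate: bool = False) -> UptakeMeasure:
        uptake = float(v.sum())
        volume = v.size * voxel_volume
        pidg = percent_id_per_g(uptake, injected_dose, volume) if v.size else 0.0
        return UptakeMeasure(
            pidg=pidg,
            region=region,
            uptake_total=uptake,
            volume=volume,
            injected_dose=injected_dose,
            degenerate=degenerate,
            **meta,
        )

    out = {"all": measure("all", vals)}
    if np.ptp(vals) == 0:
        # constant image: the high/low split is undefined
        out["high"] = UptakeMeasure(
            pidg=0.0,
            region="high",
            uptake_total=0.0,
            volume=0.0,
            injected_dose=injected_dose,
            degenerate=True,
            **meta,
        )
        out["low"] = measure("low", vals, degenerate=True)
        return out
    threshold = float(np.percentile(vals, percentile))
    out["high"] = measure("high", vals[vals >= threshold])
    out["low"] = measure("low", vals[vals < threshold])
    return out


def tumor_to_heart(tumor_pidg: float, heart_pidg: float) -> float:
    """T:H ratio; requires positive heart %ID/g."""
    if heart_pidg <= 0:
        raise ValueError("heart %ID/g must be positive for a T:H ratio")
    if tumor_pidg < 0:
        raise ValueError("tumor %ID/g must be nonnegative")
    return tumor_pidg / heart_pidg


def h24_normalize_measure(series: pd.DataFrame, value_col: str = "pidg") -> pd.DataFrame:
    """Normalize a per-subject measure series by its hour-24 value.

    ``series`` needs columns (subject, hour, region, <value_col>); within
    each (subject, region) the values are divided by that subject/region's
    hour-24 value, so the hour-24 entry becomes 1.
    """
    if "hour" not in series or value_col not in series:
        raise ValueError(f"series must have 'hour' and {value_col!r} columns")

    def norm(group: pd.DataFrame) -> pd.DataFrame:
        ref_rows = group.loc[group["hour"] == 24, value_col]
        if ref_rows.empty:
            raise ValueError("no hour-24 entry to normalize by")
        ref = float(ref_rows.iloc[0])
        if ref <= 0:
            raise ValueError("hour-24 reference value must be positive")
        out = group.copy()
        out[value_col] = out[value_col] / ref
        return out

    keys = [c for c in ("subject", "region") if c in series.columns]
    if keys:
        parts = [norm(g) for _, g in series.groupby(keys, sort=False)]
        return pd.concat(parts).sort_index()
    return norm(series)
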