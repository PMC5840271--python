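"""Persistence and childhood diagrams in transformed coordinates.

Each merge-tree leaf (a strict local maximum of uptake) yields one point
per diagram kind:

* persistence point: ``(x, y) = (b - d, (b + d)/2)`` from birth and
  elder-rule death — lifetime on the x-axis, mid-life intensity on the y;
* childhood point:  ``(x', y') = (b - d', (b + d')/2)`` from birth and
  childhood death — the height of the maximum above its *first* merge and
  the mean intensity of its private neighborhood.

The global maximum's persistence point is always ``(b, b/2)`` when the
terminal value is 0, so persistence diagrams carry no local information
about the hottest region; childhood points move those points up and to
the left, recovering it.

Points are held in pandas DataFrames with one row per point and columns
(subject, group, hour, normalization, kind, max_rank, max_value,
max_i, max_j, max_k, b, d, d_prime, x, y, segment) — the unit of the
time-series statistical analysis.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .topology import MergeTree

__all__ = [
    "POINT_COLUMNS",
    "persistence_points",
    "childhood_points",
    "diagram_points",
    "split_high_low",
    "aggregate_time_series",
]

POINT_COLUMNS = [
    "subject",
    "group",
    "hour",
    "normalization",
    "kind",
    "max_rank",
    "max_value",
    "max_i",
    "max_j",
    "max_k",
    "b",
    "d",
    "d_prime",
    "x",
    "y",
    "segment",
]


def _points(
    tree: MergeTree,
    kind: str,
    include_internal: bool,
    subject: str,
    group: str,
    hour: float,
    normalization: str,
    scale: float,
) -> pd.DataFrame:
    rows = []
    max_by_rank = {mx.rank: mx for mx in tree.maxima}
    for br in tree.branches:
        if not br.is_leaf and not include_internal:
            continue
        b = br.birth * scale
        d = br.elder_death * scale
        dp = br.childhood_death * scale
        death = d if kind == "persistence" else dp
        mx = max_by_rank[br.label_max]
        rows.append(
            {
                "subject": subject,
                "group": group,
                "hour": hour,
                "normalization": normalization,
                "kind": kind,
                "max_rank": br.label_max,
                "max_value": mx.value * scale,
                "max_i": mx.voxel[0],
                "max_j": mx.voxel[1],
                "max_k": mx.voxel[2],
                "b": b,
                "d": d,
                "d_prime": dp,
                "x": b - death,
                "y": 0.5 * (b + death),
                "segment": "",
            }
        )
    return pd.DataFrame(rows, columns=POINT_COLUMNS)


def persistence_points(
    tree: MergeTree,
    subject: str = "",
    group: str = "",
    hour: float = 0.0,
    normalization: str = "none",
    scale: float = 1.0,
) -> pd.DataFrame:
    """One persistence point (b - d, (b + d)/2) per leaf.

    ``scale`` multiplies all births/deaths before the transform; passing
    1/reference realizes a scalar normalization without rebuilding the
    tree (merge trees are homogeneous under positive scaling).
    """
    return _points(tree, "persistence", False, subject, group, hour, normalization, scale)


def childhood_points(
    tree: MergeTree,
    include_internal: bool = False,
    subject: str = "",
    group: str = "",
    hour: float = 0.0,
    normalization: str = "none",
    scale: float = 1.0,
) -> pd.DataFrame:
    """One childhood point (b - d', (b + d')/2) per leaf.

    Internal branches also carry (b, d') and can be included with
    ``include_internal=True``; the default diagram contains leaves only.
    """
    return _points(tree, "childhood", include_internal, subject, group, hour, normalization, scale)


def diagram_points(tree: MergeTree, **kwargs) -> pd.DataFrame:
    """Both diagram kinds for one tree, concatenated."""
    return pd.concat(
        [persistence_points(tree, **kwargs), childhood_points(tree, **kwargs)],
        ignore_index=True,
    )


def split_high_low(points: pd.DataFrame, percentile: float = 95.0) -> pd.DataFrame:
    """Assign each point of a single image to the high or low segment.

    A point is *high* iff its maximum's value is at or above the given
    percentile (linear interpolation between order statistics) of the
    image's local-maximum values; otherwise *low*.  With a single maximum
    any percentile equals its value, so it is high.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    if points.empty:
        return points.copy()
    if points[["subject", "hour", "normalization"]].drop_duplicates().shape[0] > 1:
        raise ValueError("split_high_low expects points from a single image")
    out = points.copy()
    leaf_values = (
        out.drop_duplicates("max_rank").set_index("max_rank")["max_value"].sort_index()
    )
    threshold = float(np.percentile(leaf_values.to_numpy(), percentile))
    out["segment"] = np.where(out["max_value"] >= threshold, "high", "low")
    return out


def aggregate_time_series(
    diagrams: Iterable[pd.DataFrame],
    exclude_hours: set[float] = frozenset({3}),
) -> pd.DataFrame:
    """Concatenate per-image diagram tables into one time-series table.

    Hour-3 acquisitions are excluded by default (the antibody is still
    distributing from blood into tissue then).  Segment labels must have
    been assigned per image *before* aggregation.  All rows must share one
    normalization scheme.
    """
    frames = [df for df in diagrams if not df.empty]
    if not frames:
        return pd.DataFrame(columns=POINT_COLUMNS)
    table = pd.concat(frames, ignore_index=True)
    norms = table["normalization"].unique()
    if len(norms) > 1:
        raise ValueError(f"mixed normalizations in one time-series table: {sorted(norms)}")
    if (table["segment"] == "").any():
        raise ValueError("segment labels must be assigned per image before aggregation")
    table = table[~table["hour"].isin(list(exclude_hours))].reset_index(drop=True)
    return table
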