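"""End-to-end pipeline: preprocess → merge trees → diagrams → measures → stats.

Orchestrates a whole cohort (synthetic, or real images listed in a JSON
manifest) through decay correction, smoothing, ROI restriction, merge-tree
construction, diagram extraction under both normalization schemes,
aggregate measures, and the time-series statistical comparison, producing
a single report bundle.

Scalar normalizations commute with the merge-tree sweep (all births and
deaths scale), so each image's tree is built once on the decay-corrected
smoothed intensity and the per-normalization diagrams are obtained by
scaling — exactly, not approximately.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagrams import aggregate_time_series, diagram_points, split_high_low
from .measures import h24_normalize_measure, pidg_from_mean, roi_measures, tumor_to_heart
from .preprocess import (
    IN111_HALF_LIFE_H,
    IntensityFunction,
    RawImage,
    RoiMask,
    apply_roi,
    decay_correct,
    decay_factor,
    gaussian_smooth,
    heart_reference,
)
from .stats import PropertyReport, TrendComparison, compare_trends, evaluate_properties, kruskal_wallis
from .synthetic import Cohort, CohortEntry
from .topology import MergeTree, build_merge_tree, tree_from_json, tree_to_json, tree_to_newick

__all__ = [
    "RunConfig",
    "ReportBundle",
    "process_image",
    "run_pipeline",
    "load_manifest",
    "save_cohort",
    "write_bundle",
]


@dataclass
class RunConfig:
    """Pipeline parameters; the defaults are the study's stated settings."""

    tau_half: float = IN111_HALF_LIFE_H  # In-111 half-life, hours
    sigma: float = 0.69  # Gaussian smoothing SD, voxels
    box: int = 3  # smoothing kernel box size
    percentile: float = 95.0  # high/low split percentile
    terminal_value: float = 0.0  # terminal filtration value
    normalizations: tuple[str, ...] = ("h24", "heart")
    exclude_hours: tuple[float, ...] = (3.0,)
    # which diagram coordinates are carried into trend comparisons, per scheme
    analysis_coords: dict = field(
        default_factory=lambda: {"h24": ("y",), "heart": ("x", "y")}
    )
    measure_on_smoothed: bool = True
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    config: RunConfig
    trees: dict  # (subject, hour) -> MergeTree
    points: pd.DataFrame  # all diagram points, all normalizations
    tables: dict  # (group, normalization, kind) -> time-series DataFrame
    measures: pd.DataFrame
    stats: pd.DataFrame  # one row per statistical test
    properties: list[PropertyReport]
    provenance: dict

    def property_report(self, method: str) -> PropertyReport:
        for rep in self.properties:
            if rep.method == method:
                return rep
        raise KeyError(f"no property report for method {method!r}")


def process_image(entry: CohortEntry, config: RunConfig) -> tuple[IntensityFunction, float]:
    """Decay-correct, smooth, and ROI-restrict one image; return (f, heart mean).

    The returned heart mean is decay-corrected with the same factor as the
    image so both normalization references live on the corrected scale.
    """
    img = decay_correct(entry.image, config.tau_half)
    img = gaussian_smooth(img, box=config.box, sigma=config.sigma)
    f = apply_roi(img, entry.roi)
    heart = entry.heart_mean * decay_factor(entry.image.hour, config.tau_half)
    return f, heart


def _stage(name: str, subject: str, hour: float):
    return f"stage '{name}' failed for subject {subject} hour {hour:g}"


def run_pipeline(cohort: Cohort, config: RunConfig | None = None) -> ReportBundle:
    """Run the full analysis over a cohort and assemble the report bundle."""
    config = config or RunConfig()
    trees: dict = {}
    processed: dict = {}
    hearts: dict = {}
    measure_rows = []
    point_frames = []

    # pass 1: preprocess, build one tree per image, compute measures
    for entry in cohort.entries:
        subj, hour = entry.image.subject_id, entry.image.hour
        try:
            f, heart = process_image(entry, config)
        except Exception as e:
            raise RuntimeError(_stage("preprocess", subj, hour)) from e
        processed[(subj, hour)] = (f, entry)
        hearts[(subj, hour)] = heart
        try:
            trees[(subj, hour)] = build_merge_tree(f, terminal_value=config.terminal_value)
        except Exception as e:
            raise RuntimeError(_stage("merge-tree", subj, hour)) from e

        by_region = roi_measures(
            f, entry.roi, injected_dose=entry.dose, percentile=config.percentile
        )
        heart_pidg = pidg_from_mean(heart, entry.dose, f.voxel_volume_mm3)
        for region, um in by_region.items():
            measure_rows.append(
                {
                    "subject": subj,
                    "group": entry.image.group_id,
                    "hour": hour,
                    "region": region,
                    "uptake": um.uptake_total,
                    "volume": um.volume,
                    "dose": um.injected_dose,
                    "pidg": um.pidg,
                    "heart_pidg": heart_pidg,
                    "th_ratio": tumor_to_heart(um.pidg, heart_pidg),
                    "degenerate": um.degenerate,
                }
            )

    measures_df = pd.DataFrame(measure_rows)
    try:
        pidg_h24 = h24_normalize_measure(measures_df, value_col="pidg")["pidg"]
    except ValueError as e:
        raise RuntimeError(f"H24 normalization of measures failed: {e}") from e
    measures_df["pidg_h24norm"] = pidg_h24

    # H24 references per subject (mean processed ROI intensity at hour 24)
    h24_ref: dict[str, float] = {}
    for (subj, hour), (f, _) in processed.items():
        if hour == 24:
            h24_ref[subj] = f.roi_mean

    # pass 2: diagrams per image under each normalization (exact rescaling)
    for (subj, hour), (f, entry) in processed.items():
        for norm in config.normalizations:
            if norm == "h24":
                if subj not in h24_ref:
                    raise RuntimeError(
                        f"H24 normalization failed: subject {subj} has no hour-24 image"
                    )
                ref = h24_ref[subj]
            elif norm == "heart":
                ref = hearts[(subj, hour)]
            elif norm == "none":
                ref = 1.0
            else:
                raise ValueError(f"unknown normalization {norm!r}")
            if ref <= 0:
                raise RuntimeError(f"non-positive {norm} reference for {subj} hour {hour:g}")
            pts = diagram_points(
                trees[(subj, hour)],
                subject=subj,
                group=entry.image.group_id,
                hour=hour,
                normalization=norm,
                scale=1.0 / ref,
            )
            pts = pd.concat(
                [
                    split_high_low(pts[pts["kind"] == k], percentile=config.percentile)
                    for k in ("persistence", "childhood")
                ],
                ignore_index=True,
            )
            point_frames.append(pts)

    points = pd.concat(point_frames, ignore_index=True)

    # time-series tables per group × normalization × kind
    groups = sorted(points["group"].unique())
    tables = {}
    for g in groups:
        for norm in config.normalizations:
            for kind in ("persistence", "childhood"):
                sel = points[
                    (points["group"] == g)
                    & (points["normalization"] == norm)
                    & (points["kind"] == kind)
                ]
                per_image = [df for _, df in sel.groupby(["subject", "hour"], sort=False)]
                tables[(g, norm, kind)] = aggregate_time_series(
                    per_image, exclude_hours=set(config.exclude_hours)
                )

    stats_rows, properties = run_stats(tables, measures_df, config, groups)
    provenance = {
        "package_version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_images": len(cohort.entries),
        "subjects": cohort.subjects(),
    }
    return ReportBundle(
        config=config,
        trees=trees,
        points=points,
        tables=tables,
        measures=measures_df,
        stats=pd.DataFrame(stats_rows),
        properties=properties,
        provenance=provenance,
    )


def _pairs(df: pd.DataFrame, coord: str) -> np.ndarray:
    return df[["hour", coord]].to_numpy(dtype=float)


def _record(rows, method, comparison_name, comp: TrendComparison):
    rows.append(
        {
            "method": method,
            "comparison": comparison_name,
            "slope_a": comp.slope_a,
            "slope_b": comp.slope_b,
            "slope_diff": comp.slope_diff,
            "t_stat": comp.t_stat,
            "p_value": comp.p_value,
            "category": comp.category,
        }
    )


def run_stats(tables, measures_df, config: RunConfig, groups):
    """All trend comparisons, Kruskal–Wallis screens, and property reports.

    ``tables`` maps (group, normalization, kind) to a time-series points
    DataFrame; ``measures_df`` may be None to analyze diagram coordinates
    only.  Returns (rows, PropertyReports).
    """
    rows: list[dict] = []
    properties: list[PropertyReport] = []
    if len(groups) != 2:
        return rows, properties
    g1, g2 = groups[0], groups[1]

    # diagram coordinates
    for norm in config.normalizations:
        for kind in ("persistence", "childhood"):
            t1, t2 = tables[(g1, norm, kind)], tables[(g2, norm, kind)]
            if t1.empty or t2.empty:
                continue
            for coord in ("x", "y"):
                method = f"{kind}:{norm}:{coord}"
                # Kruskal-Wallis screen: coordinate grouped by hour, per group
                for g, tab in ((g1, t1), (g2, t2)):
                    samples = [grp[coord].to_numpy() for _, grp in tab.groupby("hour")]
                    if len(samples) >= 2:
                        h_stat, p = kruskal_wallis(samples)
                        rows.append(
                            {
                                "method": method,
                                "comparison": f"kruskal_wallis_group{g}",
                                "slope_a": np.nan,
                                "slope_b": np.nan,
                                "slope_diff": np.nan,
                                "t_stat": h_stat,
                                "p_value": p,
                                "category": "",
                            }
                        )
                if coord not in config.analysis_coords.get(norm, ()):
                    continue
                between = {}
                for region, sel in (
                    ("all", lambda df: df),
                    ("high", lambda df: df[df["segment"] == "high"]),
                    ("low", lambda df: df[df["segment"] == "low"]),
                ):
                    a, b = sel(t1), sel(t2)
                    if a.empty or b.empty:
                        continue
                    comp = compare_trends(_pairs(a, coord), _pairs(b, coord))
                    between[region] = comp
                    _record(rows, method, f"between_groups_{region}", comp)
                within = {}
                for g, tab in ((g1, t1), (g2, t2)):
                    hi = tab[tab["segment"] == "high"]
                    lo = tab[tab["segment"] == "low"]
                    if hi.empty or lo.empty:
                        continue
                    comp = compare_trends(_pairs(hi, coord), _pairs(lo, coord))
                    within[str(g)] = comp
                    _record(rows, method, f"within_group{g}_high_vs_low", comp)
                if "all" in between and len(within) == 2:
                    properties.append(evaluate_properties(method, between, within))

    # aggregate measures: H24-normalized %ID/g and T:H
    if measures_df is None or measures_df.empty:
        return rows, properties
    mdf = measures_df[~measures_df["hour"].isin(list(config.exclude_hours))]
    for method, col in (("pidg:h24", "pidg_h24norm"), ("th:heart", "th_ratio")):
        between, within = {}, {}
        for region in ("all", "high", "low"):
            a = mdf[(mdf["group"] == g1) & (mdf["region"] == region)]
            b = mdf[(mdf["group"] == g2) & (mdf["region"] == region)]
            if a.empty or b.empty:
                continue
            comp = compare_trends(_pairs(a, col), _pairs(b, col))
            between[region] = comp
            _record(rows, method, f"between_groups_{region}", comp)
        for g in (g1, g2):
            hi = mdf[(mdf["group"] == g) & (mdf["region"] == "high")]
            lo = mdf[(mdf["group"] == g) & (mdf["region"] == "low")]
            if hi.empty or lo.empty:
                continue
            comp = compare_trends(_pairs(hi, col), _pairs(lo, col))
            within[str(g)] = comp
            _record(rows, method, f"within_group{g}_high_vs_low", comp)
        if "all" in between and len(within) == 2:
            properties.append(evaluate_properties(method, between, within))

    return rows, properties


# ---------------------------------------------------------------------------
# file I/O: manifests, bundle output


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as NIfTI images + masks with a JSON manifest; returns manifest path."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for entry in cohort.entries:
        subj, hour = entry.image.subject_id, entry.image.hour
        stem = f"{subj}_h{hour:g}"
        affine = np.diag(list(entry.image.voxel_size) + [1.0])
        img_path = out / f"{stem}.nii.gz"
        roi_path = out / f"{stem}_roi.nii.gz"
        nib.save(nib.Nifti1Image(entry.image.values.astype(np.float32), affine), img_path)
        nib.save(nib.Nifti1Image(entry.roi.mask.astype(np.uint8), affine), roi_path)
        records.append(
            {
                "image": img_path.name,
                "roi": roi_path.name,
                "subject": subj,
                "group": entry.image.group_id,
                "hour": hour,
                "dose": entry.dose,
                "heart_mean": entry.heart_mean,
                "voxel_size": list(entry.image.voxel_size),
            }
        )
    manifest = {"images": records}
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_manifest(manifest_path: str | Path) -> Cohort:
    """Read a cohort manifest (as written by :func:`save_cohort`, or hand-made).

    Each record needs image/roi paths (NIfTI), subject, group, hour, dose,
    and either a ``heart_mean`` scalar or a ``heart_roi`` mask path from
    which the per-image heart mean is computed.
    """
    import nibabel as nib

    path = Path(manifest_path)
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed manifest JSON at {path}: {e}") from e
    base = path.parent
    entries = []
    for rec in manifest["images"]:
        values = np.asarray(nib.load(base / rec["image"]).dataobj, dtype=float)
        mask = np.asarray(nib.load(base / rec["roi"]).dataobj) > 0
        image = RawImage(
            values=values,
            voxel_size=tuple(rec.get("voxel_size", (1.0, 1.0, 1.0))),
            hour=float(rec["hour"]),
            subject_id=str(rec["subject"]),
            group_id=str(rec["group"]),
        )
        roi = RoiMask(mask=mask, kind="tumor")
        if "heart_mean" in rec:
            heart_mean = float(rec["heart_mean"])
        elif "heart_roi" in rec:
            hmask = np.asarray(nib.load(base / rec["heart_roi"]).dataobj) > 0
            heart_mean = heart_reference(image, RoiMask(mask=hmask, kind="heart"))
        else:
            raise ValueError(f"manifest record for {rec['subject']} lacks heart information")
        entries.append(
            CohortEntry(image=image, roi=roi, heart_mean=heart_mean, dose=float(rec["dose"]))
        )
    return Cohort(params=None, entries=entries, truth=None)


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write the report bundle (CSV tables, JSON reports, trees) to a directory."""
    out = Path(out_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    bundle.points.to_csv(out / "points.csv", index=False)
    bundle.measures.to_csv(out / "measures.csv", index=False)
    bundle.stats.to_csv(out / "stats.csv", index=False)
    props = [asdict(p) for p in bundle.properties]
    (out / "properties.json").write_text(json.dumps(props, indent=1))
    (out / "provenance.json").write_text(json.dumps(bundle.provenance, indent=1, default=str))
    for (subj, hour), tree in bundle.trees.items():
        stem = out / "trees" / f"{subj}_h{hour:g}"
        stem.with_suffix(".json").write_text(tree_to_json(tree))
        stem.with_suffix(".nwk").write_text(tree_to_newick(tree))
    return out
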