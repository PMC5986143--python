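"""End-to-end orchestration: phantom or user volumes through linker detection,
morphometrics and statistics into a reproducible JSON report.

All randomness flows from the single ``rng_seed``; two runs of the same config
produce byte-identical reports. Every stage logs its object counts so any
number in the report can be traced to the stage that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import detection, morphometrics, stats, synthetic
from .volumes import DensityVolume, LabelVolume, read_density, read_labels

__all__ = [
    "RunConfig",
    "run_analysis",
    "compare_to_truth",
    "phantom_spec_from_dict",
    "config_from_yaml",
]

log = logging.getLogger("tomolink")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run.

    Defaults mirror the standard analysis: 3-voxel / 320 nm^3 segment size
    filters, 45 nm proximal zone, 70-90 nm dense-core-vesicle diameter
    window, 0.5 um curvature point spacing.
    """

    phantom: Optional[synthetic.PhantomSpec] = None
    density_path: Optional[str] = None
    labels_path: Optional[str] = None
    catalog_path: Optional[str] = None
    smooth_sigma_nm: float = 0.0
    n_levels: int = 25
    schedule_levels: Optional[list] = None   # explicit override
    min_voxels: int = 3
    max_volume_nm3: float = 320.0
    proximal_nm: float = 45.0
    area_window_nm: float = 250.0
    dcv_diameter_nm: tuple = (70.0, 90.0)
    curvature_spacing_um: float = 0.5
    max_layer_distance_nm: float = 250.0
    radial_shells: int = 5
    rng_seed: int = 0
    outdir: Optional[str] = None

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        if self.phantom is not None:
            d["phantom"] = dataclasses.asdict(self.phantom)
        return d


def phantom_spec_from_dict(d: dict) -> synthetic.PhantomSpec:
    """Build a PhantomSpec from plain (YAML-friendly) nested dicts."""
    d = dict(d)
    if "volume_shape" in d:
        d["volume_shape"] = tuple(int(v) for v in d["volume_shape"])
    if d.get("vesicles"):
        d["vesicles"] = [synthetic.VesicleSpec(**v) for v in d["vesicles"]]
    if d.get("plasma_membrane") is not None:
        pm = d["plasma_membrane"]
        d["plasma_membrane"] = synthetic.MembraneSpec(**pm) if isinstance(pm, dict) \
            else synthetic.MembraneSpec()
    if d.get("microtubules"):
        d["microtubules"] = [synthetic.MicrotubuleSpec(**m) for m in d["microtubules"]]
    for key in ("connectors", "tethers"):
        if d.get(key) is not None:
            d[key] = synthetic.LinkerSpec(**d[key])
    if d.get("protrusions") is not None:
        d["protrusions"] = synthetic.ProtrusionSpec(**d["protrusions"])
    return synthetic.PhantomSpec(**d)


def config_from_yaml(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if raw.get("phantom") is not None:
        raw["phantom"] = phantom_spec_from_dict(raw["phantom"])
    if raw.get("dcv_diameter_nm") is not None:
        raw["dcv_diameter_nm"] = tuple(raw["dcv_diameter_nm"])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------

def _load_inputs(config: RunConfig):
    if config.phantom is not None:
        spec = dataclasses.replace(config.phantom, rng_seed=config.rng_seed
                                   if config.phantom.rng_seed == 0
                                   else config.phantom.rng_seed)
        density, labels, truth = synthetic.generate_phantom(spec)
        return density, labels, truth
    if not (config.density_path and config.labels_path and config.catalog_path):
        raise ValueError("config needs either a phantom spec or density+labels paths")
    density = read_density(config.density_path)
    labels = read_labels(config.labels_path, config.catalog_path)
    labels.check_paired(density)
    return density, labels, None


def _build_schedule(config: RunConfig, volume: DensityVolume,
                    labels: LabelVolume) -> tuple[detection.ThresholdSchedule, str]:
    if config.schedule_levels is not None:
        return detection.ThresholdSchedule(np.asarray(config.schedule_levels)), "explicit"
    try:
        return detection.make_schedule(volume, labels, config.n_levels), "auto"
    except detection.DegenerateScheduleError:
        # noise-free volume: span the density range below the cytoplasm mode
        free = labels.labels == 0
        lo = float(volume.data.min())
        hi = float(np.median(volume.data[free]))
        if hi <= lo:
            raise
        span = hi - lo
        levels = np.linspace(lo + 0.05 * span, hi - 0.02 * span, config.n_levels)
        log.info("degenerate cytoplasm sd; using range-based schedule %.3g..%.3g",
                 levels[0], levels[-1])
        return detection.ThresholdSchedule(levels), "range"


def compare_to_truth(segments, truth: synthetic.GroundTruth,
                     min_overlap_fraction: float = 0.5) -> dict:
    """Match detected 2-bound segments to ground-truth linkers.

    Greedy one-to-one matching by voxel overlap, requiring the overlap to
    cover at least ``min_overlap_fraction`` of the smaller voxel set. All
    2-bound segments take part regardless of size-filter class (the filter
    reclassifies, it does not delete), so recall reflects detection itself.
    """
    detected = [s for s in segments if s.base_class in ("tether", "connector")]
    gt_sets = {int(lid): set(map(tuple, vox))
               for lid, vox in truth.linker_voxels.items()}
    overlaps = []
    for s in detected:
        svox = set(map(tuple, s.voxels))
        for lid, gvox in gt_sets.items():
            inter = len(svox & gvox)
            if inter and inter >= min_overlap_fraction * min(len(svox), len(gvox)):
                overlaps.append((inter, s.segment_id, lid))
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))
    seg_by_id = {s.segment_id: s for s in detected}
    gap_by_id = dict(zip(truth.linkers["linker_id"].astype(int),
                         truth.linkers["gap_nm"]))
    class_by_id = dict(zip(truth.linkers["linker_id"].astype(int),
                           truth.linkers["class"]))
    used_seg, used_gt = set(), set()
    rows = []
    for inter, sid, lid in overlaps:
        if sid in used_seg or lid in used_gt:
            continue
        used_seg.add(sid)
        used_gt.add(lid)
        s = seg_by_id[sid]
        rows.append({
            "linker_id": lid, "segment_id": sid,
            "true_class": class_by_id[lid], "detected_class": s.class_,
            "overlap_voxels": inter,
            "true_gap_nm": float(gap_by_id[lid]),
            "detected_b2c_nm": s.length_b2c_nm,
            "length_error_nm": (s.length_b2c_nm - float(gap_by_id[lid]))
            if s.length_b2c_nm is not None else np.nan,
        })
    matches = pd.DataFrame(rows, columns=[
        "linker_id", "segment_id", "true_class", "detected_class",
        "overlap_voxels", "true_gap_nm", "detected_b2c_nm", "length_error_nm"])
    n_gt = len(gt_sets)
    n_det = len(detected)
    recall = len(used_gt) / n_gt if n_gt else 1.0
    precision = len(used_seg) / n_det if n_det else 1.0
    err = matches["length_error_nm"].abs()
    return {
        "matches": matches,
        "n_ground_truth": n_gt,
        "n_detected": n_det,
        "recall": recall,
        "precision": precision,
        "mean_abs_length_error_nm": float(err.mean()) if len(err) else np.nan,
    }


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.replace({np.nan: None}).to_dict(orient="records")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_analysis(config: RunConfig) -> dict:
    """Run all stages and return the report dict (also written to outdir)."""
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "config": config.resolved(), "stages": {}}

    density, labels, truth = _load_inputs(config)
    log.info("stage load: volume %s, %d boundaries", density.shape, len(labels.catalog))
    report["stages"]["load"] = {
        "shape": list(density.shape), "voxel_size_nm": density.voxel_size_nm,
        "n_boundaries": len(labels.catalog),
        "boundary_kinds": {k: len(labels.ids_of_kind(k)) for k in
                           ("vesicle", "plasma_membrane", "microtubule", "ser", "mvb")},
    }

    working = synthetic.smooth_stand_in(density, config.smooth_sigma_nm) \
        if config.smooth_sigma_nm > 0 else density
    report["stages"]["smoothing"] = {"sigma_nm": config.smooth_sigma_nm}

    schedule, sched_mode = _build_schedule(config, working, labels)
    report["stages"]["schedule"] = {"mode": sched_mode,
                                    "levels": schedule.levels.tolist()}

    segments = detection.hierarchical_segment(working, labels, schedule)
    log.info("stage hierarchical: %d segments", len(segments))
    vesicle_ids = labels.ids_of_kind("vesicle")
    protrusions = detection.detect_protrusions(working, labels, vesicle_ids) \
        if vesicle_ids else []
    segments = detection.filter_segments(segments, density.voxel_size_nm,
                                         config.min_voxels, config.max_volume_nm3)
    all_segments = detection.measure_segments(list(segments) + list(protrusions),
                                              labels, density.voxel_size_nm)
    seg_frame = detection.segments_to_frame(all_segments)
    class_counts = seg_frame["class"].value_counts().to_dict()
    log.info("stage segments: %s", class_counts)
    report["stages"]["segments"] = {"table": seg_frame,
                                    "class_counts": class_counts}

    per_vesicle, linker_summary = detection.summarize_linkers(all_segments, labels)
    report["stages"]["linker_summary"] = {"per_vesicle": per_vesicle,
                                          "aggregate": linker_summary}

    pm_ids = labels.ids_of_kind("plasma_membrane")
    if pm_ids and vesicle_ids:
        occupancy = morphometrics.layer_occupancy(
            labels, pm_ids[0], vesicle_ids, config.max_layer_distance_nm)
        proximal = morphometrics.proximal_stats(
            labels, pm_ids[0], vesicle_ids, config.proximal_nm,
            config.area_window_nm)
        report["stages"]["occupancy"] = {"layers": occupancy}
        report["stages"]["proximal"] = {
            "n_proximal": proximal["n_proximal"],
            "membrane_area_um2": proximal["membrane_area_um2"],
            "density_per_um2": proximal["density_per_um2"],
        }
        log.info("stage proximal: %d vesicles within %.0f nm",
                 proximal["n_proximal"], config.proximal_nm)

    # radial traces + lumen classes for medium-sized vesicles
    medium_rows = []
    free = labels.labels == 0
    cyto_mean = float(working.data[free].mean())
    cyto_sd = float(working.data[free].std())
    for vid in vesicle_ids:
        b = labels.catalog[vid]
        if b.center_nm is None or b.radius_nm is None or 2 * b.radius_nm < 50:
            continue  # medium-sized only (>= 50 nm diameter)
        try:
            trace = morphometrics.radial_trace(working, b.center_nm, b.radius_nm,
                                               config.radial_shells)
            lumen = morphometrics.classify_lumen(trace, cyto_mean, cyto_sd)
        except ValueError:
            continue  # too close to the volume edge for full shells
        mt_dist = morphometrics.distance_to_microtubule(labels, vid)
        medium_rows.append({"boundary_id": vid, "diameter_nm": 2 * b.radius_nm,
                            "lumen_class": lumen,
                            "mt_distance_nm": mt_dist if mt_dist is not None
                            else np.nan})
    if medium_rows:
        medium = pd.DataFrame(medium_rows)
        dcv = morphometrics.select_dcv(medium, *config.dcv_diameter_nm)
        report["stages"]["medium_vesicles"] = {
            "table": medium, "n_dcv": len(dcv),
            "dcv_ids": dcv["boundary_id"].tolist(),
        }
        log.info("stage medium vesicles: %d classified, %d DCVs",
                 len(medium), len(dcv))

    if truth is not None and truth.microtubules:
        curv_rows = []
        skipped = 0
        for i, pts in enumerate(truth.microtubules):
            try:
                cm = morphometrics.polyline_curvature(pts, config.curvature_spacing_um)
            except ValueError:
                skipped += 1  # polyline shorter than two point spacings
                continue
            curv_rows.append({"microtubule": i, "kappa_per_um": cm.kappa_per_um,
                              "angular_per_um": cm.angular_per_um})
        report["stages"]["curvature"] = {
            "table": pd.DataFrame(curv_rows,
                                  columns=["microtubule", "kappa_per_um",
                                           "angular_per_um"]),
            "spacing_um": config.curvature_spacing_um,
            "n_too_short": skipped,
        }

    # length summary statistics per class (inputs for two-sample tests)
    stats_block = {}
    for cls in ("connector", "tether"):
        vals = seg_frame.loc[seg_frame["class"] == cls, "length_b2c_nm"].dropna()
        if len(vals):
            stats_block[cls + "_length"] = {
                "mean_nm": float(vals.mean()),
                "sd_nm": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
            }
    report["stages"]["statistics"] = stats_block

    if truth is not None:
        match = compare_to_truth(all_segments, truth)
        report["stages"]["truth_comparison"] = {
            "matches": match["matches"],
            "n_ground_truth": match["n_ground_truth"],
            "n_detected": match["n_detected"],
            "recall": match["recall"],
            "precision": match["precision"],
            "mean_abs_length_error_nm": match["mean_abs_length_error_nm"],
        }
        log.info("stage truth comparison: recall %.3f precision %.3f",
                 match["recall"], match["precision"])

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        seg_frame.to_csv(out / "segments.csv", index=False)
        per_vesicle.to_csv(out / "per_vesicle.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report
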