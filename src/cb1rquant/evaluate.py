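"""End-to-end cohort processing in memory, and truth-vs-detection scoring.

This module drives one synthetic cohort through the full measurement chain
(exposure normalization → DoG enhancement → iterative segmentation →
filtering/typing → expressor split → site/layer aggregation) without touching
disk, and scores segmentation output against the generator's ground truth by
centroid matching.  Both the test suite and the analysis drivers use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import measure, segment, synthgen
from .core import CHANNEL_INDEX, StackGeometry
from .imgproc import EnhancementParams, correct_z_shrinkage, enhance_stack, normalize_exposure
from .measure import FilterParams
from .segment import SegmentationParams, objects_to_mask


@dataclass
class SiteResult:
    meta: dict
    records: pd.DataFrame
    sum_cb1r: float
    sum_plane: int
    truth: pd.DataFrame
    attrition: dict = field(default_factory=dict)
    match_stats: dict = field(default_factory=dict)


def process_site(
    stack: np.ndarray,
    geometry: StackGeometry,
    meta: dict,
    enhancement: EnhancementParams,
    seg_params: SegmentationParams,
    filters: FilterParams,
    reference_exposure_ms: float,
) -> tuple[pd.DataFrame, float, int, dict, dict]:
    """Run one stack through normalization, segmentation and measurement.

    Returns (bouton records without expressor labels, single-plane CB1R sum,
    plane index, per-channel segmented objects, attrition counts).
    """
    norm = normalize_exposure(
        stack, geometry.exposure_times_ms, reference_exposure_ms
    )
    enhanced = enhance_stack(norm, enhancement)
    objects = {}
    for channel in ("vglut1", "vgat", "cb1r"):
        c = CHANNEL_INDEX[channel]
        cb1r_idx = CHANNEL_INDEX["cb1r"]
        # masks are copied back onto the unenhanced channel for measurement
        objects[channel] = segment.segment_channel(
            enhanced[c], norm[c if channel != "cb1r" else cb1r_idx],
            seg_params, geometry, channel=channel,
        )
    # lipofuscin aggregates are far larger than the DoG pass-band; build the
    # exclusion mask on the unenhanced lipofuscin channel
    lipo_mask = segment.segment_lipofuscin(
        norm[CHANNEL_INDEX["lipofuscin"]], seg_params, geometry
    )
    marker_masks = {
        "vglut1": objects_to_mask(objects["vglut1"], geometry.shape),
        "vgat": objects_to_mask(objects["vgat"], geometry.shape),
    }
    attrition = {}
    accepted_markers = []
    for channel in ("vglut1", "vgat"):
        att = {}
        accepted_markers.extend(
            measure.apply_filters(
                objects[channel], lipo_mask, marker_masks, filters, geometry,
                attrition=att,
            )
        )
        attrition[channel] = att
    records = measure.classify_terminal_type(
        accepted_markers, norm[CHANNEL_INDEX["cb1r"]], meta
    )
    # CB1R objects feeding the single-plane sum: lipofuscin + frame filters
    cb1r_att = {}
    cb1r_accepted = measure.apply_filters(
        objects["cb1r"], lipo_mask, marker_masks, filters, geometry,
        which=("frame", "lipofuscin"), attrition=cb1r_att,
    )
    attrition["cb1r"] = cb1r_att
    plane = measure.default_sum_plane(geometry, filters)
    plane_sum = measure.plane_masked_sum(
        cb1r_accepted, norm[CHANNEL_INDEX["cb1r"]], plane
    )
    return records, plane_sum, plane, objects, attrition


def truth_in_window(
    truth: pd.DataFrame, geometry: StackGeometry, filters: FilterParams
) -> pd.DataFrame:
    """Ground-truth marker objects whose centers pass the depth/frame filters."""
    t = truth[truth["channel_role"].isin(["vglut1", "vgat"])].copy()
    if t.empty:
        return t
    depth = correct_z_shrinkage(
        t["z_um"].to_numpy(), geometry.measured_thickness, geometry.original_thickness
    )
    x_px = t["x_um"].to_numpy() / geometry.pixel_size_xy
    y_px = t["y_um"].to_numpy() / geometry.pixel_size_xy
    keep = (
        (depth >= filters.depth_min_um)
        & (depth <= filters.depth_max_um)
        & (x_px >= filters.frame_low_px)
        & (x_px <= filters.frame_high_px)
        & (y_px >= filters.frame_low_px)
        & (y_px <= filters.frame_high_px)
    )
    return t[keep]


def truth_interior(
    truth: pd.DataFrame, geometry: StackGeometry, margin_um: float = 0.5
) -> pd.DataFrame:
    """Ground-truth marker objects at least ``margin_um`` inside the stack.

    Border-truncated puncta are excluded from detection scoring: their
    rendered profile is clipped by the field of view, so neither the
    segmentation nor the counting-frame rules are meant to recover them.
    """
    t = truth[truth["channel_role"].isin(["vglut1", "vgat"])]
    ex = geometry.nx * geometry.pixel_size_xy
    ey = geometry.ny * geometry.pixel_size_xy
    ez = geometry.nz * geometry.z_step
    keep = (
        (t["x_um"] >= margin_um) & (t["x_um"] <= ex - margin_um)
        & (t["y_um"] >= margin_um) & (t["y_um"] <= ey - margin_um)
        & (t["z_um"] >= margin_um) & (t["z_um"] <= ez - margin_um)
    )
    return t[keep]


def match_objects(
    truth: pd.DataFrame, records: pd.DataFrame, max_dist_um: float = 0.3
) -> dict:
    """Match truth centers to detected centroids (optimal 1:1 assignment).

    Returns recall, false-discovery rate, and the matched index pairs; a
    detection matches at most one truth object within ``max_dist_um``.
    """
    if truth.empty or records.empty:
        return {
            "recall": 0.0 if len(truth) else float("nan"),
            "fdr": 1.0 if len(records) else float("nan"),
            "n_truth": len(truth),
            "n_detected": len(records),
            "pairs": [],
        }
    tc = truth[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    dc = records[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    dist = np.linalg.norm(tc[:, None, :] - dc[None, :, :], axis=2)
    cost = np.where(dist <= max_dist_um, dist, 1e6)
    ti, di = linear_sum_assignment(cost)
    ok = dist[ti, di] <= max_dist_um
    pairs = list(zip(truth.index[ti[ok]], records.index[di[ok]]))
    n_match = int(ok.sum())
    return {
        "recall": n_match / len(truth),
        "fdr": 1.0 - n_match / len(records),
        "n_truth": len(truth),
        "n_detected": len(records),
        "pairs": pairs,
    }


@dataclass
class CohortResult:
    records: pd.DataFrame
    site_summaries: pd.DataFrame
    layer_summaries: pd.DataFrame
    long_table: pd.DataFrame
    truth: pd.DataFrame
    median_split_adu: float
    manifest: pd.DataFrame
    match_stats: pd.DataFrame
    matched_values: pd.DataFrame | None = None

    def matched_class_comparison(self) -> pd.DataFrame:
        """Measured vs truth CB1R means per (group, pipeline class) cell.

        Uses the matched truth–detection pairs and the class labels the
        pipeline itself assigned, so both columns describe the same boutons;
        the relative error isolates segmentation/measurement accuracy from
        detection and classification differences.
        """
        if self.matched_values is None or self.matched_values.empty:
            raise ValueError("run_cohort(score_matches=True) required")
        rec = self.records.merge(
            self.matched_values,
            on=["site_id", "object_id", "terminal_type"],
            how="inner",
        )
        cls = measure.terminal_class(rec)
        rec = rec.assign(terminal_class=cls)
        out = rec.groupby(["group", "terminal_class"], as_index=False).agg(
            measured_mean=("cb1r_mean", "mean"),
            truth_mean=("truth_cb1r_mean", "mean"),
            n=("cb1r_mean", "size"),
        )
        out["rel_err"] = (out.measured_mean - out.truth_mean) / out.truth_mean
        return out

    def estimated_cell_means(self) -> pd.DataFrame:
        """Group × class mean of the subject-level dependent measure."""
        subj = (
            self.long_table.groupby(
                ["group", "terminal_class", "subject_id"], as_index=False
            )["response"]
            .mean()
        )
        return subj.groupby(["group", "terminal_class"], as_index=False)[
            "response"
        ].mean()

    def truth_cell_means(
        self,
        geometry: StackGeometry,
        filters: FilterParams,
        split: str = "median",
    ) -> pd.DataFrame:
        """Ground-truth class means over in-window objects (same windows).

        With ``split='median'`` (default) the high/low inhibitory classes are
        formed exactly as the pipeline forms them — at the control-group
        median of the truth values — so estimated and truth class means
        target the same estimand.  ``split='generating'`` uses the generating
        expressor labels instead.
        """
        frames = []
        for _, t in self.truth.groupby("site_id"):
            tw = truth_in_window(t, geometry, filters)
            frames.append(tw)
        tw = pd.concat(frames)
        meta = self.manifest.drop_duplicates("site_id").set_index("site_id")
        tw = tw.join(meta[["group", "subject_id"]], on="site_id")
        if split == "generating":
            expressor = tw["expressor_class_truth"].astype(str)
        elif split == "median":
            vgat = tw["channel_role"] == "vgat"
            median = float(
                tw.loc[vgat & (tw["group"] == "Ctrl"), "cb1r_mean_truth"].median()
            )
            expressor = pd.Series(
                np.where(tw["cb1r_mean_truth"] > median, "high", "low"),
                index=tw.index,
            )
        else:
            raise ValueError("split must be 'median' or 'generating'")
        cls = np.where(
            tw["channel_role"] == "vglut1", "vglut1", "vgat_" + expressor
        )
        tw = tw.assign(terminal_class=cls)
        subj = tw.groupby(["group", "terminal_class", "subject_id"], as_index=False)[
            "cb1r_mean_truth"
        ].mean()
        return subj.groupby(["group", "terminal_class"], as_index=False)[
            "cb1r_mean_truth"
        ].mean()


def run_cohort(
    params: synthgen.CohortSimParams,
    geometry: StackGeometry,
    layers=("III", "V"),
    sites_per_layer: int = 1,
    enhancement: EnhancementParams | None = None,
    seg_params: SegmentationParams | None = None,
    filters: FilterParams | None = None,
    score_matches: bool = False,
    match_dist_um: float = 0.3,
) -> CohortResult:
    """Generate and fully process one synthetic cohort in memory."""
    if enhancement is None:
        enhancement = EnhancementParams()
    if seg_params is None:
        seg_params = SegmentationParams()
    if filters is None:
        filters = FilterParams.scaled_frame(geometry)
    cohort = synthgen.generate_cohort(
        params, sites_per_layer=sites_per_layer, layers=layers, geometry=geometry
    )
    all_records = []
    site_rows = []
    truth_frames = []
    match_rows = []
    value_rows = []
    for i in range(len(cohort)):
        row = cohort.manifest.iloc[i]
        meta = {
            k: row[k] for k in ("subject_id", "pair_id", "group", "layer", "site_id")
        }
        site_geom = cohort.site_geometry(i)
        stack, objects = cohort.stack(i)
        records, plane_sum, plane, seg_objects, _ = process_site(
            stack, site_geom, meta, enhancement, seg_params, filters,
            params.reference_exposure_ms,
        )
        truth = synthgen.truth_table(objects)
        truth.insert(0, "site_id", row["site_id"])
        truth_frames.append(truth)
        all_records.append(records)
        site_rows.append((meta, plane_sum, plane))
        if score_matches:
            ti = truth_interior(truth, site_geom)
            n_truth = n_det = n_match = 0
            for channel in ("vglut1", "vgat"):
                det = pd.DataFrame(
                    [
                        {
                            "x_um": o.centroid_xyz_um[0],
                            "y_um": o.centroid_xyz_um[1],
                            "z_um": o.centroid_xyz_um[2],
                        }
                        for o in seg_objects[channel]
                    ]
                )
                if not det.empty:
                    det = truth_interior(
                        det.assign(channel_role=channel), site_geom
                    )
                stats = match_objects(
                    ti[ti["channel_role"] == channel], det, match_dist_um
                )
                n_truth += stats["n_truth"]
                n_det += stats["n_detected"]
                n_match += len(stats["pairs"])
            match_rows.append(
                {
                    "site_id": row["site_id"],
                    "recall": n_match / n_truth if n_truth else float("nan"),
                    "fdr": 1.0 - n_match / n_det if n_det else float("nan"),
                    "n_truth": n_truth,
                    "n_detected": n_det,
                    "n_matched": n_match,
                }
            )
            # value-level pairs: accepted records vs in-window truth
            tw = truth_in_window(truth, site_geom, filters)
            for channel in ("vglut1", "vgat"):
                pairs = match_objects(
                    tw[tw["channel_role"] == channel],
                    records[records["terminal_type"] == channel],
                    match_dist_um,
                )["pairs"]
                for t_idx, d_idx in pairs:
                    value_rows.append(
                        {
                            "site_id": row["site_id"],
                            "object_id": records.loc[d_idx, "object_id"],
                            "terminal_type": channel,
                            "truth_cb1r_mean": truth.loc[t_idx, "cb1r_mean_truth"],
                            "truth_expressor": truth.loc[
                                t_idx, "expressor_class_truth"
                            ],
                        }
                    )
    non_empty = [r for r in all_records if not r.empty]
    records = pd.concat(non_empty or all_records[:1], ignore_index=True)
    records, median = measure.split_expressor_class(records)
    summaries = []
    for meta, plane_sum, plane in site_rows:
        site_records = records[records["site_id"] == meta["site_id"]]
        summaries.append(
            measure.site_summary_from_records(site_records, plane_sum, plane, meta)
        )
    site_summaries = pd.DataFrame(summaries)
    layer_summaries = measure.summarize_layer(site_summaries)
    long_table = measure.layer_table_long(layer_summaries)
    return CohortResult(
        records=records,
        site_summaries=site_summaries,
        layer_summaries=layer_summaries,
        long_table=long_table,
        truth=pd.concat(truth_frames, ignore_index=True),
        median_split_adu=median,
        manifest=cohort.manifest,
        match_stats=pd.DataFrame(match_rows),
        matched_values=pd.DataFrame(value_rows),
    )


def small_test_geometry(nz: int = 32, n_xy: int = 64) -> StackGeometry:
    """Reduced-field geometry used for fast simulation studies.

    Same voxel calibration as the full 512-px field, smaller extent; the
    measured thickness of 20 μm puts the corrected 10–14 μm analysis window
    at raw depths 5–7 μm, inside a 32-plane stack.
    """
    return StackGeometry(
        nx=n_xy, ny=n_xy, nz=nz, measured_thickness=20.0,
    )


def small_test_params(seed: int = 0, **overrides) -> synthgen.CohortSimParams:
    """Cohort parameters matched to :func:`small_test_geometry`.

    Shrinkage factor 0.5 (sections measured at 20 μm) so the corrected
    10–14 μm depth window sits at raw 5–7 μm, inside the reduced stacks.
    """
    overrides.setdefault("shrinkage_factor", 0.5)
    return synthgen.CohortSimParams(seed=seed, **overrides)
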