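"""Acceptance filtering, terminal typing and aggregation of bouton measures.

Objects from the segmentation stage pass four independent acceptance filters
(depth window after shrinkage correction, XY counting frame, lipofuscin
overlap, dual-marker overlap).  Accepted vGlut1 / vGAT objects become typed
bouton records carrying the mean CB1R intensity under their mask; inhibitory
records are split into high/low CB1R expressor classes at the control-group
median; records aggregate to per-site and per-subject × layer summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StackGeometry
from .imgproc import correct_z_shrinkage
from .segment import ObjectMask

ALL_FILTERS = ("depth", "frame", "lipofuscin", "dual")

TERMINAL_CLASSES = ("vglut1", "vgat_high", "vgat_low")


@dataclass(frozen=True)
class FilterParams:
    """Object acceptance filters.

    ``depth_min/max`` bound the shrinkage-corrected centroid depth (μm below
    the tissue surface); ``frame_low/high`` bound centroid X and Y in pixels
    (the virtual counting frame excluding the outer 2% of a 512-px field).
    """

    depth_min_um: float = 10.0
    depth_max_um: float = 14.0
    frame_low_px: float = 10.0
    frame_high_px: float = 502.0

    def __post_init__(self) -> None:
        if not self.depth_min_um < self.depth_max_um:
            raise ValueError("FilterParams: depth_min must be < depth_max")
        if not self.frame_low_px < self.frame_high_px:
            raise ValueError("FilterParams: frame_low must be < frame_high")

    @classmethod
    def scaled_frame(cls, geometry: StackGeometry, margin_frac: float = 0.02, **kw):
        """Counting frame excluding ``margin_frac`` of each XY dimension."""
        n = min(geometry.nx, geometry.ny)
        lo = round(margin_frac * n)
        return cls(frame_low_px=lo, frame_high_px=n - lo, **kw)


@dataclass(frozen=True)
class LayerScheme:
    """Fractional pia→white-matter depth intervals of cortical layers I–VI."""

    boundaries: tuple = (
        ("I", 0.0, 0.10),
        ("II", 0.10, 0.20),
        ("III", 0.20, 0.50),
        ("IV", 0.50, 0.60),
        ("V", 0.60, 0.80),
        ("VI", 0.80, 1.0),
    )

    def __post_init__(self) -> None:
        lo = 0.0
        for _, a, b in self.boundaries:
            if not np.isclose(a, lo) or b <= a:
                raise ValueError("layer boundaries must partition [0, 1]")
            lo = b
        if not np.isclose(lo, 1.0):
            raise ValueError("layer boundaries must partition [0, 1]")

    def layer_of(self, depth_fraction: float) -> str:
        if not (0.0 <= depth_fraction <= 1.0):
            raise ValueError("depth fraction must lie in [0, 1]")
        for name, a, b in self.boundaries:
            if a <= depth_fraction < b:
                return name
        return self.boundaries[-1][0]


def _mask_lookup(mask: np.ndarray | None, voxels: np.ndarray) -> bool:
    if mask is None:
        return False
    return bool(mask[voxels[:, 0], voxels[:, 1], voxels[:, 2]].any())


def corrected_centroid_depth(obj: ObjectMask, geometry: StackGeometry) -> float:
    """Shrinkage-corrected depth (μm) of the object's centroid."""
    raw = obj.centroid_zyx_pix[0] * geometry.z_step
    return correct_z_shrinkage(
        raw, geometry.measured_thickness, geometry.original_thickness
    )


def filter_flags(
    obj: ObjectMask,
    lipofuscin_mask: np.ndarray | None,
    marker_masks: dict,
    filters: FilterParams,
    geometry: StackGeometry,
) -> dict:
    """Evaluate each acceptance filter for one object (True = passes)."""
    depth = corrected_centroid_depth(obj, geometry)
    cz, cy, cx = obj.centroid_zyx_pix
    on_vglut1 = obj.channel == "vglut1" or _mask_lookup(
        marker_masks.get("vglut1"), obj.voxels
    )
    on_vgat = obj.channel == "vgat" or _mask_lookup(
        marker_masks.get("vgat"), obj.voxels
    )
    return {
        "depth": filters.depth_min_um <= depth <= filters.depth_max_um,
        "frame": (
            filters.frame_low_px <= cx <= filters.frame_high_px
            and filters.frame_low_px <= cy <= filters.frame_high_px
        ),
        "lipofuscin": not _mask_lookup(lipofuscin_mask, obj.voxels),
        "dual": not (on_vglut1 and on_vgat),
    }


def apply_filters(
    objects: list[ObjectMask],
    lipofuscin_mask: np.ndarray | None,
    marker_masks: dict | None,
    filters: FilterParams,
    geometry: StackGeometry,
    which=ALL_FILTERS,
    attrition: dict | None = None,
) -> list[ObjectMask]:
    """Keep objects that pass every requested filter.

    Filters are evaluated independently per object, so their order (and any
    subset choice via ``which``) cannot change the result.  ``attrition``, if
    given, collects per-filter rejection counts for audit logs.
    """
    marker_masks = marker_masks or {}
    for m in list(marker_masks.values()) + [lipofuscin_mask]:
        if m is not None and m.shape != geometry.shape:
            raise ValueError("mask shape does not match stack geometry")
    accepted = []
    counts = {name: 0 for name in which}
    for obj in objects:
        flags = filter_flags(obj, lipofuscin_mask, marker_masks, filters, geometry)
        ok = True
        for name in which:
            if not flags[name]:
                counts[name] += 1
                ok = False
        if ok:
            accepted.append(obj)
    if attrition is not None:
        attrition.update(counts)
        attrition["n_in"] = len(objects)
        attrition["n_out"] = len(accepted)
    return accepted


def classify_terminal_type(
    marker_objects: list[ObjectMask],
    cb1r_channel: np.ndarray,
    meta: dict,
) -> pd.DataFrame:
    """Typed bouton records: mean CB1R under each accepted marker mask.

    ``marker_objects`` are filtered vGlut1/vGAT objects; ``meta`` supplies the
    manifest fields (subject_id, pair_id, group, layer, site_id) every record
    carries.
    """
    required = ("subject_id", "pair_id", "group", "layer", "site_id")
    missing = [k for k in required if k not in meta]
    if missing:
        raise KeyError(f"missing manifest fields: {missing}")
    cb1r_channel = np.asarray(cb1r_channel, dtype=float)
    rows = []
    for obj in marker_objects:
        if obj.channel not in ("vglut1", "vgat"):
            continue
        vox = obj.voxels
        cb1r_mean = float(cb1r_channel[vox[:, 0], vox[:, 1], vox[:, 2]].mean())
        rows.append(
            {
                **{k: meta[k] for k in required},
                "object_id": obj.object_id,
                "terminal_type": obj.channel,
                "cb1r_mean": cb1r_mean,
                "volume_um3": obj.volume_um3,
                "x_um": obj.centroid_xyz_um[0],
                "y_um": obj.centroid_xyz_um[1],
                "z_um": obj.centroid_xyz_um[2],
                "expressor_class": "n/a",
            }
        )
    columns = [
        "subject_id", "pair_id", "group", "layer", "site_id", "object_id",
        "terminal_type", "cb1r_mean", "volume_um3", "x_um", "y_um", "z_um",
        "expressor_class",
    ]
    return pd.DataFrame(rows, columns=columns)


def split_expressor_class(
    records: pd.DataFrame,
    control_group_label: str = "Ctrl",
    level: str = "bouton",
) -> tuple[pd.DataFrame, float]:
    """Label vGAT records high/low at the control-group median CB1R intensity.

    The median is taken over control-subject vGAT boutons (``level='bouton'``,
    default) or over control subject means (``level='subject'``); every vGAT
    record in both groups with cb1r_mean strictly above the median is 'high',
    ties and below are 'low'.  Returns (labelled records, median ADU).
    """
    if level not in ("bouton", "subject"):
        raise ValueError("level must be 'bouton' or 'subject'")
    vgat = records["terminal_type"] == "vgat"
    ctrl_vgat = records[vgat & (records["group"] == control_group_label)]
    if ctrl_vgat.empty:
        raise ValueError("no control vGAT records to compute the split median")
    if level == "bouton":
        median = float(ctrl_vgat["cb1r_mean"].median())
    else:
        median = float(ctrl_vgat.groupby("subject_id")["cb1r_mean"].mean().median())
    out = records.copy()
    out.loc[vgat, "expressor_class"] = np.where(
        out.loc[vgat, "cb1r_mean"] > median, "high", "low"
    )
    out.loc[~vgat, "expressor_class"] = "n/a"
    return out, median


def terminal_class(records: pd.DataFrame) -> pd.Series:
    """Combined class label: vglut1 / vgat_high / vgat_low."""
    cls = records["terminal_type"].copy()
    vgat = records["terminal_type"] == "vgat"
    cls[vgat] = "vgat_" + records.loc[vgat, "expressor_class"]
    return cls


def default_sum_plane(geometry: StackGeometry, filters: FilterParams) -> int:
    """Middle z-plane of the accepted depth window, in raw plane index."""
    mid_corrected = 0.5 * (filters.depth_min_um + filters.depth_max_um)
    raw = mid_corrected * geometry.measured_thickness / geometry.original_thickness
    plane = int(round(raw / geometry.z_step))
    return min(max(plane, 0), geometry.nz - 1)


def plane_masked_sum(
    cb1r_objects: list[ObjectMask], cb1r_channel: np.ndarray, plane: int
) -> float:
    """Sum of CB1R ADU under the object masks, restricted to one z-plane."""
    cb1r_channel = np.asarray(cb1r_channel, dtype=float)
    total = 0.0
    for obj in cb1r_objects:
        vox = obj.voxels
        sel = vox[:, 0] == plane
        if sel.any():
            total += float(cb1r_channel[plane, vox[sel, 1], vox[sel, 2]].sum())
    return total


def site_summary_from_records(
    records: pd.DataFrame, sum_cb1r: float, plane: int, meta: dict
) -> dict:
    """Assemble one SiteSummary row from labelled records + a plane sum."""
    if not records.empty and records["site_id"].nunique() > 1:
        raise ValueError("records from more than one site")
    out = {
        "subject_id": meta["subject_id"],
        "pair_id": meta["pair_id"],
        "group": meta["group"],
        "layer": meta["layer"],
        "site_id": meta["site_id"],
    }
    cls = terminal_class(records) if not records.empty else pd.Series(dtype=object)
    for name in TERMINAL_CLASSES:
        sel = records[cls == name] if not records.empty else records
        out[f"mean_cb1r_{name}"] = (
            float(sel["cb1r_mean"].mean()) if len(sel) else float("nan")
        )
        out[f"n_{name}"] = int(len(sel))
    out["sum_cb1r"] = float(sum_cb1r)
    out["sum_plane"] = int(plane)
    return out


def summarize_site(
    records: pd.DataFrame,
    cb1r_objects: list[ObjectMask],
    cb1r_channel: np.ndarray,
    plane: int,
    meta: dict,
) -> dict:
    """Per-site aggregate: unweighted per-class bouton means + single-plane sum.

    ``cb1r_objects`` are the CB1R-channel objects accepted for the sum measure
    (lipofuscin-excluded, frame-filtered); ``sum_cb1r`` adds their CB1R ADU on
    the selected z-plane only.  Sites with no boutons of a class report NaN
    for that class (never silently zero).
    """
    return site_summary_from_records(
        records, plane_masked_sum(cb1r_objects, cb1r_channel, plane), plane, meta
    )


def summarize_layer(site_summaries: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of site values per subject × layer cell.

    Missing cells (no sites, or all-NaN site values for a class) propagate as
    missing rows/NaNs rather than zeros.
    """
    if site_summaries.empty:
        return site_summaries.copy()
    value_cols = [
        c
        for c in site_summaries.columns
        if c.startswith("mean_cb1r_") or c == "sum_cb1r"
    ]
    grouped = (
        site_summaries.groupby(
            ["subject_id", "pair_id", "group", "layer"], as_index=False, sort=True
        )[value_cols]
        .mean()
    )
    n_sites = (
        site_summaries.groupby(
            ["subject_id", "pair_id", "group", "layer"], as_index=False, sort=True
        )["site_id"]
        .count()
        .rename(columns={"site_id": "n_sites"})
    )
    return grouped.merge(n_sites, on=["subject_id", "pair_id", "group", "layer"])


def layer_table_long(layer_summaries: pd.DataFrame) -> pd.DataFrame:
    """Long-format terminal-type dependent measure (subject × layer × class)."""
    frames = []
    for name in TERMINAL_CLASSES:
        col = f"mean_cb1r_{name}"
        if col not in layer_summaries.columns:
            continue
        sub = layer_summaries[
            ["subject_id", "pair_id", "group", "layer", col]
        ].rename(columns={col: "response"})
        sub["terminal_class"] = name
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    n_missing = int(out["response"].isna().sum())
    if n_missing:
        warnings.warn(
            f"dropping {n_missing} empty subject×layer×class cells", stacklevel=2
        )
    return out.dropna(subset=["response"]).reset_index(drop=True)
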