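"""Iterative combined intensity/morphologic threshold segmentation.

Puncta are segmented on the DoG-enhanced channel by sweeping a threshold
upward from the Otsu value in fixed gray-level increments.  At each threshold
the binarized stack is labeled in 3-D and components inside the physical size
gate (0.03–2.0 μm³ by default) are kept; kept voxels accumulate as a union
across iterations.  The union is then relabeled, the size gate re-applied, and
each final object is measured on the *unenhanced* intensity channel.

Gray levels are interpreted on the integer ADU scale of the 16-bit camera, so
enhanced channels are rounded to integers before histogramming/thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import DegenerateImageError, StackGeometry, voxel_volume

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the iterative multi-threshold segmentation."""

    threshold_increment: int = 50
    min_volume_um3: float = 0.03
    max_volume_um3: float = 2.0
    #: stop once the threshold exceeds this value; None → channel maximum
    max_threshold: int | None = None
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.threshold_increment <= 0:
            raise ValueError("threshold increment must be positive")
        if not (0 < self.min_volume_um3 < self.max_volume_um3):
            raise ValueError("require 0 < min_volume < max_volume")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class ObjectMask:
    """One segmented punctum.

    ``voxels`` is an (N, 3) integer array of (z, y, x) indices; centroids are
    reported both in voxel units and μm; intensity statistics are measured on
    the unenhanced channel the mask was copied back onto.
    """

    object_id: int
    channel: str
    voxels: np.ndarray
    centroid_zyx_pix: tuple[float, float, float]
    centroid_xyz_um: tuple[float, float, float]
    volume_um3: float
    mean_intensity: float
    summed_intensity: float

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


def volume_gate_voxels(params: SegmentationParams, geometry: StackGeometry):
    """Convert the μm³ size gate to inclusive voxel-count bounds.

    ceil for the minimum and floor for the maximum, so any object whose true
    volume lies inside the physical gate is kept.
    """
    v = voxel_volume(geometry)
    lo = math.ceil(params.min_volume_um3 / v)
    hi = math.floor(params.max_volume_um3 / v)
    return lo, hi


def _as_gray_levels(channel: np.ndarray) -> np.ndarray:
    """Round to the integer ADU scale thresholds are defined on."""
    channel = np.asarray(channel)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite voxels")
    if np.issubdtype(channel.dtype, np.integer):
        return channel.astype(np.int64)
    return np.rint(channel).astype(np.int64)


def initial_threshold(enhanced_channel: np.ndarray) -> int:
    """Otsu threshold on the full-stack integer histogram.

    Maximizes between-class variance over one-gray-level bins; the returned
    value t splits classes as (≤ t, > t).  Constant images are degenerate.
    """
    levels = _as_gray_levels(enhanced_channel)
    if levels.min() == levels.max():
        raise DegenerateImageError("constant image has no Otsu threshold")
    # integer input -> skimage bins each gray level exactly
    return int(threshold_otsu(levels))


def _threshold_union(
    enhanced: np.ndarray,
    params: SegmentationParams,
    geometry: StackGeometry,
    upper_gate: bool,
    min_threshold: int | None = None,
) -> np.ndarray:
    """Union of size-gated components over the ascending threshold sweep."""
    levels = _as_gray_levels(enhanced)
    structure = _STRUCTURES[params.connectivity]
    vmin, vmax = volume_gate_voxels(params, geometry)
    if not upper_gate:
        vmax = np.iinfo(np.int64).max
    union = np.zeros(levels.shape, dtype=bool)
    if levels.min() == levels.max():
        return union
    t = initial_threshold(levels)
    if min_threshold is not None:
        t = max(t, min_threshold)
    t_stop = int(levels.max()) if params.max_threshold is None else int(params.max_threshold)
    while t <= t_stop:
        mask = levels > t
        if not mask.any():
            break
        labels, n = ndimage.label(mask, structure=structure)
        sizes = np.bincount(labels.ravel())
        # masks are nested in t: component sizes only shrink, so once no
        # component reaches the minimum gate none ever will again
        if n == 0 or sizes[1:].max() < vmin:
            break
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = (sizes[1:] >= vmin) & (sizes[1:] <= vmax)
        union |= keep[labels]
        t += params.threshold_increment
    return union


def _measure_components(
    component_mask: np.ndarray,
    intensity: np.ndarray,
    params: SegmentationParams,
    geometry: StackGeometry,
    channel: str,
    upper_gate: bool = True,
) -> list[ObjectMask]:
    structure = _STRUCTURES[params.connectivity]
    vmin, vmax = volume_gate_voxels(params, geometry)
    if not upper_gate:
        vmax = np.iinfo(np.int64).max
    labels, n = ndimage.label(component_mask, structure=structure)
    if n == 0:
        return []
    sizes = np.bincount(labels.ravel())
    ids = [i for i in range(1, n + 1) if vmin <= sizes[i] <= vmax]
    if not ids:
        return []
    vol = voxel_volume(geometry)
    intensity = np.asarray(intensity, dtype=float)
    means = ndimage.mean(intensity, labels=labels, index=ids)
    sums = ndimage.sum_labels(intensity, labels=labels, index=ids)
    centroids = ndimage.center_of_mass(component_mask, labels=labels, index=ids)
    objects = []
    zz, yy, xx = np.nonzero(component_mask)
    lab_flat = labels[zz, yy, xx]
    order = np.argsort(lab_flat, kind="stable")
    zz, yy, xx, lab_flat = zz[order], yy[order], xx[order], lab_flat[order]
    bounds = np.searchsorted(lab_flat, np.arange(1, n + 2))
    for oid, (i, (cz, cy, cx), m, s) in enumerate(
        zip(ids, centroids, means, sums), start=1
    ):
        lo, hi = bounds[i - 1], bounds[i]
        vox = np.column_stack([zz[lo:hi], yy[lo:hi], xx[lo:hi]])
        objects.append(
            ObjectMask(
                object_id=oid,
                channel=channel,
                voxels=vox,
                centroid_zyx_pix=(float(cz), float(cy), float(cx)),
                centroid_xyz_um=(
                    float(cx) * geometry.pixel_size_xy,
                    float(cy) * geometry.pixel_size_xy,
                    float(cz) * geometry.z_step,
                ),
                volume_um3=float(sizes[i] * vol),
                mean_intensity=float(m),
                summed_intensity=float(s),
            )
        )
    return objects


def segment_channel(
    enhanced_channel: np.ndarray,
    intensity_channel: np.ndarray,
    params: SegmentationParams,
    geometry: StackGeometry,
    channel: str = "",
) -> list[ObjectMask]:
    """Segment puncta on the enhanced channel, measure on the intensity channel.

    Returns the final size-gated objects after union-merge across thresholds
    and relabeling; an empty list is a valid result.
    """
    enhanced_channel = np.asarray(enhanced_channel)
    intensity_channel = np.asarray(intensity_channel)
    if enhanced_channel.shape != intensity_channel.shape:
        raise ValueError("enhanced and intensity channels must share a shape")
    if enhanced_channel.shape != geometry.shape:
        raise ValueError("channel shape does not match geometry")
    union = _threshold_union(enhanced_channel, params, geometry, upper_gate=True)
    return _measure_components(
        union, intensity_channel, params, geometry, channel, upper_gate=True
    )


def segment_lipofuscin(
    lipofuscin_channel: np.ndarray,
    params: SegmentationParams,
    geometry: StackGeometry,
    noise_floor_sigmas: float = 5.0,
) -> np.ndarray:
    """Exclusion mask for lipofuscin: same sweep, no upper size gate.

    Lipofuscin aggregates can exceed the 2 μm³ bouton gate and must still be
    masked out, so only the lower gate applies.  Because the upper gate is
    absent, a section containing no lipofuscin would otherwise be masked
    wholesale when Otsu splits pure background noise; the starting threshold
    is therefore floored at median + ``noise_floor_sigmas`` robust SDs of the
    channel.  Returns a boolean voxel set.
    """
    lipofuscin_channel = np.asarray(lipofuscin_channel)
    if lipofuscin_channel.shape != geometry.shape:
        raise ValueError("channel shape does not match geometry")
    levels = _as_gray_levels(lipofuscin_channel)
    med = float(np.median(levels))
    mad = float(np.median(np.abs(levels - med)))
    floor = int(math.ceil(med + noise_floor_sigmas * 1.4826 * max(mad, 1.0)))
    return _threshold_union(
        levels, params, geometry, upper_gate=False, min_threshold=floor
    )


def objects_to_mask(objects: list[ObjectMask], shape) -> np.ndarray:
    """Boolean voxel set covered by a list of object masks."""
    out = np.zeros(shape, dtype=bool)
    for obj in objects:
        out[obj.voxels[:, 0], obj.voxels[:, 1], obj.voxels[:, 2]] = True
    return out
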