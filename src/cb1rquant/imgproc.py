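"""Stack normalization and spot enhancement.

Three pre-segmentation steps: linear exposure normalization across captures,
shrinkage correction of z positions back to the original 40 μm section
thickness, and a per-slice difference-of-Gaussians (DoG) band-pass that
sharpens sub-micron puncta before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CHANNELS, GeometryError


@dataclass(frozen=True)
class EnhancementParams:
    """DoG band-pass parameters, in XY pixel units, applied per z-slice.

    The narrow/wide sigma pair (0.7 / 2.0 px defaults) passes structures of
    roughly punctum scale while removing the diffuse background; the DoG of a
    spinning-disk punctum peaks at the punctum centre.
    """

    sigma_narrow: float = 0.7
    sigma_wide: float = 2.0
    reference_exposure_ms: float | None = None
    #: apply the filter slice-wise in XY (2-D, default) or fully in 3-D
    mode: str = "2d"

    def __post_init__(self) -> None:
        if not (0 < self.sigma_narrow < self.sigma_wide):
            raise ValueError("require 0 < sigma_narrow < sigma_wide")
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")


def normalize_exposure(
    stack: np.ndarray,
    exposure_times_ms,
    reference_exposure_ms: float,
) -> np.ndarray:
    """Rescale each channel to a common reference exposure.

    Camera response is linear in exposure time, so channel ``c`` recorded at
    ``t_c`` ms is multiplied by ``reference / t_c``.  Returns float64.
    """
    exposure_times_ms = np.asarray(exposure_times_ms, dtype=float)
    if np.any(exposure_times_ms <= 0) or reference_exposure_ms <= 0:
        raise ValueError("exposure times must be positive")
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4 or stack.shape[0] != len(exposure_times_ms):
        raise ValueError(
            f"expected (channel, z, y, x) stack with {len(exposure_times_ms)} channels"
        )
    scale = reference_exposure_ms / exposure_times_ms
    return stack * scale[:, None, None, None]


def correct_z_shrinkage(
    z_positions_um,
    measured_thickness_um: float,
    original_thickness_um: float = 40.0,
):
    """Map raw depths in the shrunken section back to original-thickness depths.

    Sections cut at 40 μm shrink during immunohistochemistry; measured depth
    positions are divided by the measured thickness and re-expressed on the
    original 40 μm scale: ``corrected = raw × original / measured``.
    Monotone order of positions is preserved (positive scale factor).
    """
    if measured_thickness_um <= 0:
        raise GeometryError("measured thickness must be positive")
    if original_thickness_um <= 0:
        raise GeometryError("original thickness must be positive")
    z = np.asarray(z_positions_um, dtype=float)
    out = z * (original_thickness_um / measured_thickness_um)
    if np.isscalar(z_positions_um) or np.ndim(z_positions_um) == 0:
        return float(out)
    return out


def difference_of_gaussians(
    channel: np.ndarray, params: EnhancementParams | None = None
) -> np.ndarray:
    """Band-pass a single channel: G(σ_narrow)∗I − G(σ_wide)∗I, clipped at 0.

    Applied per z-slice in XY by default (``params.mode == '2d'``); the result
    is non-negative so that downstream Otsu thresholds operate on one-sided
    data.  A constant (DC) channel maps to zeros.
    """
    if params is None:
        params = EnhancementParams()
    channel = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite voxels")
    if channel.ndim != 3:
        raise ValueError("expected a (z, y, x) channel")
    if params.mode == "2d":
        sig_n = (0.0, params.sigma_narrow, params.sigma_narrow)
        sig_w = (0.0, params.sigma_wide, params.sigma_wide)
    else:
        sig_n = (params.sigma_narrow,) * 3
        sig_w = (params.sigma_wide,) * 3
    out = ndimage.gaussian_filter(channel, sig_n) - ndimage.gaussian_filter(
        channel, sig_w
    )
    np.clip(out, 0.0, None, out=out)
    return out


def enhance_stack(
    stack: np.ndarray, params: EnhancementParams | None = None
) -> np.ndarray:
    """DoG-enhance every channel of a (channel, z, y, x) stack."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4 or stack.shape[0] != len(CHANNELS):
        raise ValueError("expected a (channel, z, y, x) stack")
    return np.stack(
        [difference_of_gaussians(stack[c], params) for c in range(stack.shape[0])]
    )
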