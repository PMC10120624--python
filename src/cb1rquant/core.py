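"""Shared geometry and error types for the CB1R bouton quantification pipeline.

Coordinate conventions used throughout the package:

* image arrays are ``(channel, z, y, x)`` with channels ordered
  ``(vglut1, cb1r, vgat, lipofuscin)``;
* voxel ``(k, j, i)`` sits at physical position
  ``(k * z_step, j * pixel_size_xy, i * pixel_size_xy)`` in μm;
* plane ``k = 0`` is the tissue surface and raw depth increases with ``k``;
  shrinkage-corrected depth is ``raw * original_thickness / measured_thickness``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CHANNELS = ("vglut1", "cb1r", "vgat", "lipofuscin")
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}

#: Channels carrying antibody-derived signal, subject to depth-dependent
#: penetrance loss.  The lipofuscin channel images intrinsic autofluorescence.
ANTIBODY_CHANNELS = ("vglut1", "cb1r", "vgat")

ORIGINAL_SECTION_THICKNESS_UM = 40.0


class GeometryError(ValueError):
    """Invalid stack geometry (non-positive dimensions or calibration)."""


class ConfigError(ValueError):
    """Invalid pipeline or generator configuration."""


class DegenerateImageError(ValueError):
    """Image histogram is degenerate (e.g. constant) for the requested step."""


@dataclass(frozen=True)
class StackGeometry:
    """Voxel calibration and acquisition parameters for one image stack.

    Defaults follow the acquisition used for the cohort this package targets:
    512×512 pixel fields covering 55×55 μm, z-planes every 0.25 μm, sections
    cut at 40 μm that shrink during immunohistochemistry to the measured
    thickness, and per-channel camera exposure times in ms.
    """

    nx: int = 512
    ny: int = 512
    nz: int = 44
    pixel_size_xy: float = 55.0 / 512
    z_step: float = 0.25
    measured_thickness: float = 28.0
    original_thickness: float = ORIGINAL_SECTION_THICKNESS_UM
    exposure_times_ms: tuple[float, float, float, float] = (25.0, 25.0, 25.0, 25.0)

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0 or self.nz <= 0:
            raise GeometryError("stack dimensions must be positive")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise GeometryError("voxel calibration must be positive")
        if not (0 < self.measured_thickness <= self.original_thickness):
            raise GeometryError(
                "measured thickness must be in (0, original_thickness]"
            )
        if len(self.exposure_times_ms) != len(CHANNELS):
            raise GeometryError("one exposure time per channel required")
        if any(t <= 0 for t in self.exposure_times_ms):
            raise GeometryError("exposure times must be positive")

    @property
    def shrinkage_factor(self) -> float:
        """Measured thickness / original 40 μm section thickness."""
        return self.measured_thickness / self.original_thickness

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nz, self.ny, self.nx)

    def z_position_um(self, k) -> float:
        """Raw (uncorrected) depth of plane ``k`` below the tissue surface."""
        return k * self.z_step


def voxel_volume(geometry: StackGeometry) -> float:
    """Physical volume of one voxel in μm³ (pixel_size_xy² × z_step)."""
    return geometry.pixel_size_xy**2 * geometry.z_step
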