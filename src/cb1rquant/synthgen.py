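"""Synthetic 4-channel confocal cohorts with ground truth.

Generates 3-D stacks that emulate deconvolved spinning-disk images of
immunolabeled human cortex: anisotropic Gaussian puncta for excitatory
(vGlut1) and inhibitory (vGAT) boutons each carrying a co-localized CB1R
signal, a non-synaptic CB1R-only population, and larger lipofuscin blobs that
bleed into every channel.  Antibody-derived signal decays with depth
(penetrance), sections shrink in z, and voxels carry Poisson-Gaussian camera
noise.  Every stack comes with an exact ground-truth object table, so each
downstream stage can be tested against known answers.

CB1R intensity structure mirrors the cohort the package targets: excitatory
boutons draw around one group mean per subject group, inhibitory boutons draw
from a two-component (high/low expressor) lognormal mixture, and schizophrenia
subjects use their own group means.  Two generator-design choices keep the
*measured* mean CB1R intensity of a bouton interpretable as its configured
target:

* the CB1R co-label of a bouton is a compact flat-top profile
  (``exp(-(u/u0)^order)`` in punctum-scaled radius u), nearly constant over
  any plausible object mask, so the measured mean is insensitive to the exact
  mask extent;
* bouton CB1R amplitudes are calibrated so that, at the depth of the analysis
  window, the expected measured mean (own signal plus the diffuse background
  contributed by all neighbours) equals the drawn target — the analytic
  background compensation of :func:`background_compensation`.

``cb1r_mean_truth`` records the mean of the full noise-free CB1R scene under
the object's truth mask: exactly what a perfect mask would measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    CHANNEL_INDEX,
    CHANNELS,
    ConfigError,
    GeometryError,
    StackGeometry,
)

GROUPS = ("Ctrl", "SZ")

#: mean CB1R intensity (ADU) by terminal class and subject group; these are
#: the default generating cell means for simulated cohorts (see
#: :mod:`cb1rquant.cohortdata` for the reference values they come from).
DEFAULT_CB1R_MEANS = {
    "vglut1": {"Ctrl": 770.537, "SZ": 1042.193},
    "vgat_high": {"Ctrl": 2510.098, "SZ": 2137.309},
    "vgat_low": {"Ctrl": 435.461, "SZ": 460.420},
}

TERMINAL_CLASS_ROLES = {"vglut1": "vglut1", "vgat_high": "vgat", "vgat_low": "vgat"}


@dataclass(frozen=True)
class CohortSimParams:
    """Generative settings for one synthetic cohort.

    Densities are objects per 1000 μm³ of imaged tissue.  ``intensity_cv`` is
    the bouton-to-bouton coefficient of variation of CB1R targets within a
    class; ``subject_cv`` the between-subject CV of class means (lognormal
    factors, one per subject × class).  ``depth_attenuation_rate`` is the
    fractional antibody signal loss per μm of raw depth.  ``shrinkage_factor``
    is measured thickness / 40 μm.
    """

    n_pairs: int = 10
    vglut1_cb1r_mean_by_group: dict = field(
        default_factory=lambda: dict(DEFAULT_CB1R_MEANS["vglut1"])
    )
    vgat_high_cb1r_mean_by_group: dict = field(
        default_factory=lambda: dict(DEFAULT_CB1R_MEANS["vgat_high"])
    )
    vgat_low_cb1r_mean_by_group: dict = field(
        default_factory=lambda: dict(DEFAULT_CB1R_MEANS["vgat_low"])
    )
    #: slightly below one half, so the control-group median — the split point
    #: of the expressor classification — falls in the upper tail of the low
    #: mode, as it does in the reference cohort, rather than in the empty
    #: inter-mode gap where it is an unstable order statistic
    high_fraction: float = 0.45
    intensity_cv: float = 0.12
    subject_cv: float = 0.10
    densities_per_type: dict = field(
        default_factory=lambda: {"vglut1": 30.0, "vgat": 30.0, "cb1r_only": 10.0}
    )
    lipofuscin_density: float = 5.0
    gaussian_sd: float = 15.0
    poisson_scale: float = 0.5
    depth_attenuation_rate: float = 0.01
    shrinkage_factor: float = 0.7
    #: marker-channel peak amplitude (lognormal mean, ADU) and its CV
    marker_peak_adu: float = 1500.0
    marker_peak_cv: float = 0.25
    #: peak amplitude scale of non-synaptic CB1R puncta
    cb1r_only_peak_adu: float = 600.0
    #: lipofuscin-channel peak amplitude and relative bleed into other channels
    lipofuscin_peak_adu: float = 2000.0
    lipofuscin_bleed_range: tuple[float, float] = (0.2, 0.5)
    #: flat-top CB1R co-label: exp(-(u/u0)^order) in punctum-scaled radius u
    colabel_radius: float = 2.4
    colabel_order: int = 8
    #: truth mask radius in punctum-scaled units (see truth_mask)
    truth_mask_radius: float = 1.8
    #: bouton σ_xy range (μm); σ_z = z_sigma_ratio × σ_xy (post-deconvolution)
    sigma_xy_range: tuple[float, float] = (0.12, 0.26)
    lipofuscin_sigma_range: tuple[float, float] = (0.4, 1.0)
    #: axial elongation of boutons after deconvolution
    z_sigma_ratio: float = 1.5
    #: exposure times drawn uniformly in this range (ms); lipofuscin constant
    exposure_range_ms: tuple[float, float] = (20.0, 30.0)
    reference_exposure_ms: float = 30.0
    #: corrected-depth window the amplitude calibration targets (μm)
    analysis_window_um: tuple[float, float] = (10.0, 14.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if not (0.0 <= self.high_fraction <= 1.0):
            raise ConfigError("high_fraction must lie in [0, 1]")
        if any(v < 0 for v in self.densities_per_type.values()):
            raise ConfigError("densities must be non-negative")
        if self.lipofuscin_density < 0:
            raise ConfigError("densities must be non-negative")
        if not (0.0 < self.shrinkage_factor <= 1.0):
            raise ConfigError("shrinkage_factor must lie in (0, 1]")
        if self.depth_attenuation_rate < 0:
            raise ConfigError("depth_attenuation_rate must be non-negative")
        if self.truth_mask_radius <= 0 or self.colabel_radius <= 0:
            raise ConfigError("profile radii must be positive")


@dataclass
class GroundTruthObject:
    """One generated object with its exact, as-rendered CB1R statistics."""

    object_id: int
    channel_role: str  # vglut1 | vgat | cb1r_only | lipofuscin
    center_xyz_um: tuple[float, float, float]
    sigma_xyz_um: tuple[float, float, float]
    peak_amplitudes_per_channel: tuple[float, float, float, float]
    cb1r_mean_truth: float
    cb1r_target_adu: float
    expressor_class_truth: str  # high | low | n/a
    colocal_partner: int | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma_xyz_um):
            raise ValueError("sigma components must be positive")
        if any(a < 0 for a in self.peak_amplitudes_per_channel):
            raise ValueError("amplitudes must be non-negative")


def truth_table(objects: list[GroundTruthObject]) -> pd.DataFrame:
    rows = []
    for o in objects:
        rows.append(
            {
                "object_id": o.object_id,
                "channel_role": o.channel_role,
                "x_um": o.center_xyz_um[0],
                "y_um": o.center_xyz_um[1],
                "z_um": o.center_xyz_um[2],
                "sigma_x_um": o.sigma_xyz_um[0],
                "sigma_y_um": o.sigma_xyz_um[1],
                "sigma_z_um": o.sigma_xyz_um[2],
                **{
                    f"peak_{name}": o.peak_amplitudes_per_channel[i]
                    for name, i in CHANNEL_INDEX.items()
                },
                "cb1r_mean_truth": o.cb1r_mean_truth,
                "cb1r_target_adu": o.cb1r_target_adu,
                "expressor_class_truth": o.expressor_class_truth,
            }
        )
    columns = [
        "object_id", "channel_role", "x_um", "y_um", "z_um",
        "sigma_x_um", "sigma_y_um", "sigma_z_um",
        "peak_vglut1", "peak_cb1r", "peak_vgat", "peak_lipofuscin",
        "cb1r_mean_truth", "cb1r_target_adu", "expressor_class_truth",
    ]
    return pd.DataFrame(rows, columns=columns)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal draw(s) with the requested arithmetic mean and CV."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if cv <= 0:
        return mean if size is None else np.full(size, mean)
    s2 = np.log1p(cv**2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=size)


# ---------------------------------------------------------------------------
# intensity profiles and rendering


def _u2_patch(geometry: StackGeometry, center_um, sigma_um, extent_sigma: float):
    """Squared punctum-scaled radius u² = Σ dᵢ²/σᵢ² on a clipped local grid.

    Returns the (z0, y0, x0) patch origin and the u² array; empty if the
    extent misses the stack.
    """
    cx, cy, cz = center_um
    sx, sy, sz = sigma_um
    px, pz = geometry.pixel_size_xy, geometry.z_step
    x0 = max(int(np.floor((cx - extent_sigma * sx) / px)), 0)
    x1 = min(int(np.ceil((cx + extent_sigma * sx) / px)) + 1, geometry.nx)
    y0 = max(int(np.floor((cy - extent_sigma * sy) / px)), 0)
    y1 = min(int(np.ceil((cy + extent_sigma * sy) / px)) + 1, geometry.ny)
    z0 = max(int(np.floor((cz - extent_sigma * sz) / pz)), 0)
    z1 = min(int(np.ceil((cz + extent_sigma * sz) / pz)) + 1, geometry.nz)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return (0, 0, 0), np.zeros((0, 0, 0))
    ux = ((np.arange(x0, x1) * px - cx) / sx) ** 2
    uy = ((np.arange(y0, y1) * px - cy) / sy) ** 2
    uz = ((np.arange(z0, z1) * pz - cz) / sz) ** 2
    u2 = uz[:, None, None] + uy[None, :, None] + ux[None, None, :]
    return (z0, y0, x0), u2


def _gaussian_patch(geometry, center_um, sigma_um, n_sigma: float = 4.0):
    origin, u2 = _u2_patch(geometry, center_um, sigma_um, n_sigma)
    return origin, np.exp(-u2 / 2.0)


def _flattop_patch(geometry, center_um, sigma_um, u0: float, order: int):
    # p < 2e-3 beyond 1.25·u0 for order 8; clip the support there
    origin, u2 = _u2_patch(geometry, center_um, sigma_um, 1.25 * u0)
    return origin, np.exp(-((u2 / u0**2) ** (order / 2.0)))


def flattop_mass_coefficient(u0: float, order: int) -> float:
    """∫ exp(-(u/u0)^order) d³u over unit-σ space: 4π u0³ Γ(3/order)/order."""
    return 4.0 * math.pi * u0**3 * math.gamma(3.0 / order) / order


def gaussian_mass_coefficient() -> float:
    """∫ exp(-u²/2) d³u = (2π)^{3/2}."""
    return (2.0 * math.pi) ** 1.5


def truth_mask(
    geometry: StackGeometry, center_um, sigma_um, radius: float = 2.0
) -> np.ndarray:
    """Boolean truth voxel set: u ≤ radius in punctum-scaled coordinates.

    This is the 'perfect mask' the generator calibrates against; radius 2.0
    covers the voxels an accurate segmentation of the marker punctum selects.
    """
    origin, u2 = _u2_patch(geometry, center_um, sigma_um, radius)
    out = np.zeros(geometry.shape, dtype=bool)
    if u2.size == 0:
        return out
    z0, y0, x0 = origin
    nz, ny, nx = u2.shape
    out[z0 : z0 + nz, y0 : y0 + ny, x0 : x0 + nx] = u2 <= radius**2
    return out


def _depth_factors(geometry: StackGeometry, rate: float, z0: int, nz: int):
    """Per-plane antibody penetrance factors exp(−rate × raw depth)."""
    depths = np.arange(z0, z0 + nz) * geometry.z_step
    return np.exp(-rate * depths)


def window_attenuation(params: CohortSimParams) -> float:
    """Penetrance factor at the raw depth of the analysis-window centre."""
    lo, hi = params.analysis_window_um
    raw_mid = 0.5 * (lo + hi) * params.shrinkage_factor
    return math.exp(-params.depth_attenuation_rate * raw_mid)


def background_compensation(params: CohortSimParams, group_weights=None) -> float:
    """Expected diffuse CB1R background (ADU) at the analysis window.

    Every punctum's CB1R profile adds mass to the channel; under spatially
    uniform random placement the expected background at a voxel is the total
    expected profile mass per unit volume.  Solving the self-consistency
    'targets are as-measured means = own signal + background' for the
    background gives the compensation subtracted from each drawn target.
    """
    a_mid = window_attenuation(params)
    lo, hi = params.sigma_xy_range
    # E[σx σy σz] with σz = 2 σxy, σxy ~ U(lo, hi)
    e_sig3 = 2.0 * (hi**4 - lo**4) / (4.0 * (hi - lo)) if hi > lo else 2.0 * lo**3
    c_flat = flattop_mass_coefficient(params.colabel_radius, params.colabel_order)
    c_gauss = gaussian_mass_coefficient()
    # flat-top profile ≈ 1 over the truth mask, so amplitude ≈ target
    class_means = {
        "vglut1": params.vglut1_cb1r_mean_by_group,
        "vgat_high": params.vgat_high_cb1r_mean_by_group,
        "vgat_low": params.vgat_low_cb1r_mean_by_group,
    }
    dens = params.densities_per_type
    rho = {  # per μm³
        "vglut1": dens.get("vglut1", 0.0) / 1000.0,
        "vgat_high": dens.get("vgat", 0.0) * params.high_fraction / 1000.0,
        "vgat_low": dens.get("vgat", 0.0) * (1.0 - params.high_fraction) / 1000.0,
    }
    mean_of = lambda d: float(np.mean(list(d.values())))
    sum_rho_c = sum(rho.values()) * c_flat * e_sig3
    sum_rho_c_m = sum(
        rho[k] * c_flat * e_sig3 * mean_of(class_means[k]) for k in rho
    )
    m_only = (
        dens.get("cb1r_only", 0.0)
        / 1000.0
        * c_gauss
        * e_sig3
        * params.cb1r_only_peak_adu
        / 0.70  # FWHM-mask flatness of a Gaussian punctum
    )
    # delta = sum_rho_c * (M - delta) + a_mid * m_only  (targets divided by
    # a_mid before rendering cancel the attenuation factor on bouton terms)
    return (sum_rho_c_m + a_mid * m_only) / (1.0 + sum_rho_c)


@dataclass
class _ObjectSpec:
    role: str
    center: tuple
    sigma: tuple
    marker_peak: float
    cb1r_target: float  # as-measured target (boutons) or peak scale
    expressor: str


def object_spec(
    role: str,
    center_um,
    sigma_xy_um: float,
    marker_peak: float = 1500.0,
    cb1r_target: float = 800.0,
    sigma_z_um: float | None = None,
    expressor: str = "n/a",
) -> _ObjectSpec:
    """Explicit object description for :func:`render_scene` (tests, demos)."""
    if sigma_z_um is None:
        sigma_z_um = 1.5 * sigma_xy_um
    return _ObjectSpec(
        role=role,
        center=tuple(center_um),
        sigma=(sigma_xy_um, sigma_xy_um, sigma_z_um),
        marker_peak=marker_peak,
        cb1r_target=cb1r_target,
        expressor=expressor,
    )


def _draw_object_specs(rng, geometry, params, group, subject_scales):
    extent_um = (
        geometry.nx * geometry.pixel_size_xy,
        geometry.ny * geometry.pixel_size_xy,
        geometry.nz * geometry.z_step,
    )
    volume_um3 = extent_um[0] * extent_um[1] * extent_um[2]
    class_means = {
        "vglut1": params.vglut1_cb1r_mean_by_group,
        "vgat_high": params.vgat_high_cb1r_mean_by_group,
        "vgat_low": params.vgat_low_cb1r_mean_by_group,
    }
    specs = []
    for role in ("vglut1", "vgat", "cb1r_only"):
        density = params.densities_per_type.get(role, 0.0)
        n = rng.poisson(density * volume_um3 / 1000.0)
        for _ in range(n):
            center = tuple(rng.uniform(0.0, e) for e in extent_um)
            sxy = rng.uniform(*params.sigma_xy_range)
            sigma = (sxy, sxy, params.z_sigma_ratio * sxy)
            expressor = "n/a"
            if role == "cb1r_only":
                target = float(
                    _lognormal(rng, params.cb1r_only_peak_adu, params.intensity_cv)
                )
                marker_peak = 0.0
            else:
                if role == "vgat":
                    expressor = (
                        "high" if rng.random() < params.high_fraction else "low"
                    )
                    cls = f"vgat_{expressor}"
                else:
                    cls = "vglut1"
                base = class_means[cls].get(group)
                if base is None:
                    raise ConfigError(f"no CB1R mean for group {group!r} in {cls}")
                target = float(
                    _lognormal(
                        rng, base * subject_scales.get(cls, 1.0), params.intensity_cv
                    )
                )
                marker_peak = float(
                    _lognormal(rng, params.marker_peak_adu, params.marker_peak_cv)
                )
            specs.append(
                _ObjectSpec(role, center, sigma, marker_peak, target, expressor)
            )
    n_lipo = rng.poisson(params.lipofuscin_density * volume_um3 / 1000.0)
    for _ in range(n_lipo):
        center = tuple(rng.uniform(0.0, e) for e in extent_um)
        s = rng.uniform(*params.lipofuscin_sigma_range)
        peak = float(rng.uniform(0.5, 1.0) * params.lipofuscin_peak_adu)
        specs.append(
            _ObjectSpec("lipofuscin", center, (s, s, s), peak, 0.0, "n/a")
        )
    return specs


def render_scene(
    geometry: StackGeometry,
    params: CohortSimParams,
    specs: list[_ObjectSpec],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[GroundTruthObject]]:
    """Render a noise-free scene (reference-exposure ADU) and its truth table.

    Bouton CB1R amplitudes are calibrated so the as-measured mean at the
    analysis window equals the object's configured target: the compensation is
    subtracted and the window attenuation divided out before rendering;
    ``cb1r_mean_truth`` is then measured from the finished scene under each
    object's truth mask.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    scene = np.zeros((len(CHANNELS),) + geometry.shape, dtype=float)
    delta = background_compensation(params)
    a_mid = window_attenuation(params)
    rate = params.depth_attenuation_rate
    cb1r = CHANNEL_INDEX["cb1r"]
    masks = []
    objects = []
    for spec in specs:
        amps = [0.0, 0.0, 0.0, 0.0]
        if spec.role == "lipofuscin":
            origin, patch = _gaussian_patch(geometry, spec.center, spec.sigma)
            z0, y0, x0 = origin
            nz, ny, nx = patch.shape
            lo, hi = params.lipofuscin_bleed_range
            for c, name in enumerate(CHANNELS):
                amp = spec.marker_peak * (
                    1.0 if name == "lipofuscin" else float(rng.uniform(lo, hi))
                )
                amps[c] = amp
                if patch.size:
                    # autofluorescence: no antibody penetrance decay
                    scene[c, z0 : z0 + nz, y0 : y0 + ny, x0 : x0 + nx] += amp * patch
            masks.append(None)
        else:
            own_target = max(spec.cb1r_target - delta, 0.0) / a_mid
            if spec.role == "cb1r_only":
                origin, patch = _gaussian_patch(geometry, spec.center, spec.sigma)
                mask_radius = math.sqrt(2.0 * math.log(2.0))  # FWHM
            else:
                origin, patch = _flattop_patch(
                    geometry, spec.center, spec.sigma,
                    params.colabel_radius, params.colabel_order,
                )
                mask_radius = params.truth_mask_radius
            z0, y0, x0 = origin
            if patch.size == 0 or patch.max() <= 0:
                masks.append(None)
                amp_cb1r = 0.0
            else:
                mask = truth_mask(geometry, spec.center, spec.sigma, mask_radius)
                mz, my, mx = np.nonzero(mask)
                if mz.size == 0:
                    masks.append(None)
                    amp_cb1r = 0.0
                else:
                    # amplitude from the profile's own mean over the mask
                    prof = np.zeros(mz.size)
                    inz, iny, inx = patch.shape
                    inside = (
                        (mz >= z0) & (mz < z0 + inz)
                        & (my >= y0) & (my < y0 + iny)
                        & (mx >= x0) & (mx < x0 + inx)
                    )
                    prof[inside] = patch[
                        mz[inside] - z0, my[inside] - y0, mx[inside] - x0
                    ]
                    flat = float(prof.mean())
                    amp_cb1r = own_target / flat if flat > 0 else 0.0
                    masks.append((mz, my, mx))
            if patch.size and amp_cb1r >= 0:
                nz, ny, nx = patch.shape
                atten = _depth_factors(geometry, rate, z0, nz)
                scene[cb1r, z0 : z0 + nz, y0 : y0 + ny, x0 : x0 + nx] += (
                    amp_cb1r * patch * atten[:, None, None]
                )
            amps[cb1r] = amp_cb1r
            if spec.role in ("vglut1", "vgat"):
                c_m = CHANNEL_INDEX[spec.role]
                amps[c_m] = spec.marker_peak
                origin_m, patch_m = _gaussian_patch(geometry, spec.center, spec.sigma)
                if patch_m.size:
                    z0m, y0m, x0m = origin_m
                    nzm, nym, nxm = patch_m.shape
                    atten_m = _depth_factors(geometry, rate, z0m, nzm)
                    scene[c_m, z0m : z0m + nzm, y0m : y0m + nym, x0m : x0m + nxm] += (
                        spec.marker_peak * patch_m * atten_m[:, None, None]
                    )
        objects.append(
            GroundTruthObject(
                object_id=len(objects) + 1,
                channel_role=spec.role,
                center_xyz_um=spec.center,
                sigma_xyz_um=spec.sigma,
                peak_amplitudes_per_channel=tuple(amps),
                cb1r_mean_truth=0.0,
                cb1r_target_adu=spec.cb1r_target,
                expressor_class_truth=spec.expressor,
            )
        )
    # truth pass: what a perfect mask measures on the finished noise-free scene
    cb1r_scene = scene[cb1r]
    for obj, mask in zip(objects, masks):
        if mask is not None and obj.channel_role != "lipofuscin":
            mz, my, mx = mask
            obj.cb1r_mean_truth = float(cb1r_scene[mz, my, mx].mean())
    return scene, objects


def generate_stack(
    geometry: StackGeometry,
    params: CohortSimParams,
    layer_label: str = "III",
    site_id: str = "site1",
    group: str = "Ctrl",
    subject_scales: dict | None = None,
    rng: np.random.Generator | None = None,
):
    """Render one 4-channel stack and its ground-truth object table.

    ``subject_scales`` maps terminal class (vglut1 / vgat_high / vgat_low) to
    a multiplicative between-subject factor on the CB1R class mean; the cohort
    generator draws one set per subject.  Returns ``(stack, objects)`` with
    ``stack`` a uint16 (channel, z, y, x) array in ADU.
    """
    if geometry.nx <= 0 or geometry.ny <= 0 or geometry.nz <= 0:
        raise GeometryError("stack dimensions must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if subject_scales is None:
        subject_scales = {}
    specs = _draw_object_specs(rng, geometry, params, group, subject_scales)
    scene, objects = render_scene(geometry, params, specs, rng)
    stack = _record(scene, geometry, params, rng)
    return stack, objects


def _record(scene, geometry, params, rng):
    """Exposure scaling + Poisson-Gaussian camera noise + 16-bit quantization."""
    exposures = np.asarray(geometry.exposure_times_ms, dtype=float)
    scale = exposures / params.reference_exposure_ms
    recorded = scene * scale[:, None, None, None]
    if params.gaussian_sd > 0 or params.poisson_scale > 0:
        var = params.gaussian_sd**2 + params.poisson_scale * recorded
        recorded = recorded + rng.standard_normal(recorded.shape) * np.sqrt(var)
    return np.clip(np.rint(recorded), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# cohort-level generation


DEFAULT_LAYERS = ("I", "II", "III", "IV", "V", "VI")

#: reference demographics for covariate draws (see cohortdata)
_COVARIATE_DIST = {
    "age_mean": 47.6, "age_sd": 14.0, "age_within_pair_sd": 3.0,
    "pmi_mean": 19.0, "pmi_sd": 8.0,
    "storage_mean": 188.0, "storage_sd": 20.0,
    "ph_mean": 6.94, "ph_sd": 0.22,
    "black_prob": 0.15,
    "cannabis_prob_sz": 0.3,
    "antipsychotic_prob_sz": 0.8,
    "antidepressant_prob_sz": 0.4,
    "benzodiazepine_prob_sz": 0.3,
    "valproate_prob_sz": 0.2,
}


@dataclass
class SyntheticCohort:
    """A lazily-rendered cohort: manifest up front, stacks on demand."""

    params: CohortSimParams
    geometry_template: StackGeometry
    manifest: pd.DataFrame
    subject_scales: dict

    def stack(self, site_index: int):
        """Render the stack (and truth objects) for one manifest row."""
        row = self.manifest.iloc[site_index]
        geometry = self.site_geometry(site_index)
        rng = np.random.default_rng([int(self.params.seed) % (2**31), 7, site_index])
        return generate_stack(
            geometry,
            self.params,
            layer_label=row["layer"],
            site_id=row["site_id"],
            group=row["group"],
            subject_scales=self.subject_scales[row["subject_id"]],
            rng=rng,
        )

    def site_geometry(self, site_index: int) -> StackGeometry:
        row = self.manifest.iloc[site_index]
        exposures = tuple(float(row[f"exposure_{c}_ms"]) for c in CHANNELS)
        return replace(
            self.geometry_template,
            measured_thickness=float(row["measured_thickness_um"]),
            exposure_times_ms=exposures,
        )

    def __len__(self) -> int:
        return len(self.manifest)


def generate_cohort(
    params: CohortSimParams,
    sites_per_layer: int = 6,
    layers=DEFAULT_LAYERS,
    geometry: StackGeometry | None = None,
) -> SyntheticCohort:
    """Build a matched-pair cohort manifest with per-subject effects.

    Each pair contributes one Ctrl and one SZ subject; every subject has
    ``sites_per_layer`` sites in each cortical layer.  Covariates are drawn
    from the documented reference-cohort distributions.  Stacks themselves are
    rendered lazily per manifest row (deterministic in ``params.seed``).
    """
    if params.n_pairs < 1:
        raise ConfigError("n_pairs must be >= 1")
    layers = list(layers)
    if not layers:
        raise ConfigError("at least one layer required")
    if sites_per_layer < 1:
        raise ConfigError("sites_per_layer must be >= 1")
    if geometry is None:
        geometry = StackGeometry()
    rng = np.random.default_rng([int(params.seed) % (2**31), 1])
    dist = _COVARIATE_DIST
    measured = params.shrinkage_factor * geometry.original_thickness

    subject_rows = []
    subject_scales = {}
    for pair in range(1, params.n_pairs + 1):
        pair_age = rng.normal(dist["age_mean"], dist["age_sd"])
        sex = "F" if pair == 1 else "M"
        for group in GROUPS:
            sid = f"{group}{pair:02d}"
            scales = {
                cls: float(_lognormal(rng, 1.0, params.subject_cv))
                for cls in ("vglut1", "vgat_high", "vgat_low")
            }
            subject_scales[sid] = scales
            is_sz = group == "SZ"
            subject_rows.append(
                {
                    "subject_id": sid,
                    "pair_id": pair,
                    "group": group,
                    "sex": sex,
                    "race": "Black" if rng.random() < dist["black_prob"] else "White",
                    "age_years": float(
                        np.clip(pair_age + rng.normal(0, dist["age_within_pair_sd"]), 20, 85)
                    ),
                    "pmi_hours": float(
                        np.clip(rng.normal(dist["pmi_mean"], dist["pmi_sd"]), 4, 45)
                    ),
                    "storage_months": float(
                        rng.normal(dist["storage_mean"], dist["storage_sd"])
                    ),
                    "ph": float(rng.normal(dist["ph_mean"], dist["ph_sd"])),
                    "cannabis_history": bool(
                        is_sz and rng.random() < dist["cannabis_prob_sz"]
                    ),
                    "antipsychotic_history": bool(
                        is_sz and rng.random() < dist["antipsychotic_prob_sz"]
                    ),
                    "antidepressant_history": bool(
                        is_sz and rng.random() < dist["antidepressant_prob_sz"]
                    ),
                    "benzodiazepine_history": bool(
                        is_sz and rng.random() < dist["benzodiazepine_prob_sz"]
                    ),
                    "valproate_history": bool(
                        is_sz and rng.random() < dist["valproate_prob_sz"]
                    ),
                    "measured_thickness_um": measured,
                }
            )

    rows = []
    idx = 0
    lo, hi = params.exposure_range_ms
    for srow in subject_rows:
        for layer in layers:
            for s in range(1, sites_per_layer + 1):
                exposures = {
                    f"exposure_{c}_ms": (
                        25.0 if c == "lipofuscin" else float(np.round(rng.uniform(lo, hi), 1))
                    )
                    for c in CHANNELS
                }
                rows.append(
                    {
                        "site_index": idx,
                        "site_id": f"{srow['subject_id']}_L{layer}_s{s:02d}",
                        "layer": layer,
                        **srow,
                        **exposures,
                    }
                )
                idx += 1
    manifest = pd.DataFrame(rows)
    return SyntheticCohort(
        params=params,
        geometry_template=geometry,
        manifest=manifest,
        subject_scales=subject_scales,
    )


# ---------------------------------------------------------------------------
# table-level cohort simulator (no image rendering)


def simulate_measure_table(
    n_pairs: int,
    layers=DEFAULT_LAYERS,
    cell_means: dict | None = None,
    subject_sd: float = 80.0,
    pair_sd: float = 40.0,
    residual_sd: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the subject × layer (× terminal class) dependent-measure table.

    Used for statistical calibration and power checks where image rendering
    adds nothing: response = class/group mean + pair effect + subject effect
    + residual, all Gaussian.  ``cell_means`` maps either group → mean (single
    measure) or terminal class → {group → mean}.
    """
    rng = np.random.default_rng(seed)
    if cell_means is None:
        cell_means = DEFAULT_CB1R_MEANS
    nested = isinstance(next(iter(cell_means.values())), dict)
    classes = list(cell_means) if nested else [None]
    rows = []
    for pair in range(1, n_pairs + 1):
        pair_eff = rng.normal(0.0, pair_sd)
        for group in GROUPS:
            sid = f"{group}{pair:02d}"
            subj_eff = {cls: rng.normal(0.0, subject_sd) for cls in classes}
            for layer in layers:
                for cls in classes:
                    mean = cell_means[cls][group] if nested else cell_means[group]
                    value = mean + pair_eff + subj_eff[cls] + rng.normal(0.0, residual_sd)
                    row = {
                        "subject_id": sid,
                        "pair_id": pair,
                        "group": group,
                        "layer": layer,
                        "response": value,
                    }
                    if nested:
                        row["terminal_class"] = cls
                    rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk interface


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Write OME-TIFF stacks (ZCYX), the manifest CSV and the truth CSV.

    One TIFF per site under ``out_dir/stacks``; returns the paths written.
    """
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    stack_dir = out / "stacks"
    stack_dir.mkdir(parents=True, exist_ok=True)
    truth_frames = []
    manifest = cohort.manifest.copy()
    paths = []
    for i in range(len(cohort)):
        row = manifest.iloc[i]
        stack, objects = cohort.stack(i)
        path = stack_dir / f"{row['site_id']}.ome.tif"
        # internal (C, Z, Y, X) -> ZCYX on disk
        tifffile.imwrite(
            path,
            np.moveaxis(stack, 0, 1),
            metadata={"axes": "ZCYX"},
            ome=True,
        )
        paths.append(str(path))
        tt = truth_table(objects)
        tt.insert(0, "site_id", row["site_id"])
        truth_frames.append(tt)
    manifest["stack_path"] = paths
    manifest_path = out / "manifest.csv"
    truth_path = out / "truth.csv"
    manifest.to_csv(manifest_path, index=False)
    pd.concat(truth_frames, ignore_index=True).to_csv(truth_path, index=False)
    return {
        "manifest": str(manifest_path),
        "truth": str(truth_path),
        "stacks": [str(p) for p in paths],
    }


def params_from_dict(cfg: dict) -> tuple[CohortSimParams, StackGeometry, dict]:
    """Build (CohortSimParams, StackGeometry, cohort shape) from a config dict."""
    gcfg = dict(cfg.get("geometry", {}))
    if "exposure_times_ms" in gcfg:
        gcfg["exposure_times_ms"] = tuple(gcfg["exposure_times_ms"])
    geometry = StackGeometry(**gcfg)
    pcfg = dict(cfg.get("cohort", {}))
    for key in (
        "sigma_xy_range", "lipofuscin_sigma_range", "exposure_range_ms",
        "lipofuscin_bleed_range", "analysis_window_um",
    ):
        if key in pcfg:
            pcfg[key] = tuple(pcfg[key])
    params = CohortSimParams(**pcfg)
    shape = {
        "sites_per_layer": int(cfg.get("sites_per_layer", 6)),
        "layers": list(cfg.get("layers", DEFAULT_LAYERS)),
    }
    return params, geometry, shape


def params_from_yaml(path) -> tuple[CohortSimParams, StackGeometry, dict]:
    """Read generator parameters from a YAML config file."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return params_from_dict(cfg)
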