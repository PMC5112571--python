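"""Synthetic brain phantoms with known ground truth for the MRI pipeline.

The phantom is a nested-ellipsoid "brain" on a regular grid: a white-matter
core, a gray-matter shell, two CSF ventricles, a blood vessel tube standing
in for the anterior cerebral artery (ACA), and a skull shell outside the
brain.  Each compartment carries a pre-contrast T1 drawn from its tissue
class (defaults sit inside the T1 segmentation intervals: white 950 ms,
gray 1400 ms, blood 400 ms, CSF 3000 ms).  An ellipsoidal focal Gd-uptake
region ("the opening") raises the post-contrast relaxation rate via
``1/T1 = 1/T1_0 + r1 * [Gd]``; brain tissue additionally retains a small
background concentration and vessels carry an intravascular concentration,
so the contralateral-subtraction and vessel-filter steps of the analysis
have something real to remove.

From the T1 maps the phantom renders the acquisitions the pipeline
consumes: a 5-angle SPGR variable-flip-angle series (TR 10 ms) and pre/post
T1-weighted SPGR volumes (flip angle 8 deg, TR 8.5 ms), plus a sham pair
with no focal uptake.  Additive Gaussian noise (a magnitude-Gaussian
approximation, adequate at SNR >= 10) is scaled so that SNR = mean
brain-parenchyma signal / sigma.  The world origin sits at the grid centre
and the geometry is symmetric about the x = 0 mid-sagittal plane, so the
contralateral mirror of any VOI lands on equivalent anatomy.

A second builder produces spherical-shell skull phantoms with analytically
known surface normals and displaced openings for the targeting-accuracy
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .grids import VolumeGrid
from .relaxometry import GD_DTPA_BMA_R1, spgr_signal
from .targeting import TargetPlan

__all__ = [
    "PhantomSpec",
    "PhantomData",
    "TargetingPhantom",
    "build_phantom",
    "build_targeting_phantom",
]

TISSUE_CODE = {"unassigned": 0, "blood": 1, "white": 2, "gray": 3, "csf": 4, "skull": 5}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue T1s, focal uptake and noise level of a phantom."""

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_semi_axes_mm: tuple[float, float, float] = (40.0, 40.0, 28.0)
    cortex_fraction: float = 0.78  # normalized radius of the white/cortical-gray border
    skull_fractions: tuple[float, float] = (1.04, 1.14)  # inner/outer shell radii
    # deep gray nuclei (putamen-like sonication targets), one per hemisphere
    nucleus_centers_mm: tuple = ((20.0, 0.0, 0.0), (-20.0, 0.0, 0.0))
    nucleus_semi_axes_mm: tuple[float, float, float] = (8.0, 8.0, 11.0)
    ventricle_centers_mm: tuple = ((6.0, 0.0, 8.0), (-6.0, 0.0, 8.0))
    ventricle_radius_mm: float = 3.0
    vessel_xy_mm: tuple[float, float] = (0.0, 20.0)  # tube along z at this (x, y)
    vessel_radius_mm: float = 1.5
    vessel_half_length_mm: float = 18.0
    t1_ms: dict = field(
        default_factory=lambda: {"white": 950.0, "gray": 1400.0, "blood": 400.0, "csf": 3000.0}
    )
    skull_t1_ms: float = 300.0
    skull_m0: float = 0.3
    opening_center_mm: tuple[float, float, float] = (20.0, 0.0, 0.0)
    opening_semi_axes_mm: tuple[float, float, float] = (4.0, 4.0, 6.0)
    opening_peak_gd_mM: float = 0.07
    opening_profile: str = "uniform"  # or "gaussian"
    sonicated_scale: float = 1.6  # focal (sonicated) zone = opening scaled by this
    background_gd_mM: float = 0.02  # intrinsic parenchymal retention post-contrast
    vessel_gd_mM: float = 0.5  # intravascular concentration post-contrast
    r1: float = GD_DTPA_BMA_R1
    flip_angles_deg: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 35.0)
    vfa_tr_ms: float = 10.0
    t1w_flip_deg: float = 8.0
    t1w_tr_ms: float = 8.5
    snr: float | None = 50.0  # None -> noiseless
    seed: int = 0

    def __post_init__(self) -> None:
        if self.opening_profile not in ("uniform", "gaussian"):
            raise ConfigurationError("opening_profile must be 'uniform' or 'gaussian'")
        if self.opening_peak_gd_mM < 0 or self.background_gd_mM < 0:
            raise ConfigurationError("concentrations must be >= 0")
        if self.snr is not None and self.snr <= 0:
            raise ConfigurationError("snr must be positive or None")


@dataclass
class PhantomData:
    """All phantom outputs plus the ground-truth record."""

    t1_pre: VolumeGrid
    t1_post: VolumeGrid
    vfa_pre: list[VolumeGrid]
    vfa_post: list[VolumeGrid]
    pre_t1w: VolumeGrid
    post_t1w: VolumeGrid
    sham_pre_t1w: VolumeGrid
    sham_post_t1w: VolumeGrid
    brain_mask: VolumeGrid
    skull_mask: VolumeGrid
    tissue_labels: VolumeGrid
    gd_truth: VolumeGrid
    thalamus_mask: VolumeGrid
    aca_mask: VolumeGrid
    sonicated_mask: VolumeGrid
    truth: dict
    spec: PhantomSpec


def _world_coords(shape, spacing):
    """Voxel-centre world coordinates with the origin at the grid centre."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * d for n, d in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_r2(coords, center, semi_axes):
    return sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, center, semi_axes))


def build_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomData:
    """Render the phantom volumes and the ground-truth record.

    The truth record holds the voxelized opening volume (mm^3), the delivered
    Gd amount (nmol; focal uptake in excess of background, summed over
    opening voxels), the opening's center of mass (world mm) and the per-voxel
    truth maps.  Output is bit-identical for a fixed ``spec.seed``.
    """
    shape = spec.shape
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * spacing
    ref = VolumeGrid(np.zeros(shape), affine)
    xx, yy, zz = _world_coords(shape, spacing)

    r2_brain = _ellipsoid_r2((xx, yy, zz), (0, 0, 0), spec.brain_semi_axes_mm)
    brain = r2_brain <= 1.0
    skull = (r2_brain > spec.skull_fractions[0] ** 2) & (
        r2_brain <= spec.skull_fractions[1] ** 2
    )

    labels = np.zeros(shape, dtype=np.int16)
    labels[brain & (r2_brain <= spec.cortex_fraction**2)] = TISSUE_CODE["white"]
    labels[brain & (r2_brain > spec.cortex_fraction**2)] = TISSUE_CODE["gray"]
    for c in spec.nucleus_centers_mm:
        nuc = _ellipsoid_r2((xx, yy, zz), c, spec.nucleus_semi_axes_mm) <= 1.0
        labels[brain & nuc] = TISSUE_CODE["gray"]
    for c in spec.ventricle_centers_mm:
        vent = _ellipsoid_r2((xx, yy, zz), c, (spec.ventricle_radius_mm,) * 3) <= 1.0
        labels[brain & vent] = TISSUE_CODE["csf"]
    vx, vy = spec.vessel_xy_mm
    vessel = (
        ((xx - vx) ** 2 + (yy - vy) ** 2 <= spec.vessel_radius_mm**2)
        & (np.abs(zz) <= spec.vessel_half_length_mm)
        & brain
    )
    labels[vessel] = TISSUE_CODE["blood"]
    labels[skull] = TISSUE_CODE["skull"]

    t1_pre = np.full(shape, np.nan)
    m0 = np.zeros(shape)
    for name, t1v in spec.t1_ms.items():
        sel = labels == TISSUE_CODE[name]
        t1_pre[sel] = t1v
        m0[sel] = 1.0
    t1_pre[skull] = spec.skull_t1_ms
    m0[skull] = spec.skull_m0

    # focal Gd uptake (the opening), background retention, vessel concentration
    r2_open = _ellipsoid_r2(
        (xx, yy, zz), spec.opening_center_mm, spec.opening_semi_axes_mm
    )
    inside = r2_open <= 1.0
    if np.any(inside & ~brain):
        raise ConfigurationError("opening extends outside the brain")
    opening = inside & brain
    uptake = np.zeros(shape)
    if spec.opening_profile == "uniform":
        uptake[opening] = spec.opening_peak_gd_mM
    else:
        uptake[opening] = spec.opening_peak_gd_mM * np.exp(-0.5 * r2_open[opening] * 4.0)

    gd = uptake.copy()
    parenchyma = (labels == TISSUE_CODE["white"]) | (labels == TISSUE_CODE["gray"])
    tissue = brain & (labels != TISSUE_CODE["blood"])
    gd[tissue] += spec.background_gd_mM
    gd[vessel] = spec.vessel_gd_mM
    gd_sham = gd - uptake  # same retention pattern, no focal uptake

    r1 = spec.r1
    with np.errstate(divide="ignore", invalid="ignore"):
        t1_post = 1.0 / (1.0 / t1_pre + r1 * gd / 1000.0)  # rates in 1/ms via mM*ms
        t1_post_sham = 1.0 / (1.0 / t1_pre + r1 * gd_sham / 1000.0)
    # note: r1 [s^-1 mM^-1] * [Gd] [mM] = s^-1 = 1e-3 ms^-1, hence the /1000

    rng = np.random.default_rng(spec.seed)

    def render(t1_map, flip, tr):
        sig = np.where(
            np.isfinite(t1_map), spgr_signal(np.nan_to_num(t1_map, nan=1.0), flip, tr, m0), 0.0
        )
        return sig

    def add_noise(sig):
        if spec.snr is None:
            return sig
        sigma = float(np.mean(sig[parenchyma])) / spec.snr
        return sig + rng.normal(0.0, sigma, sig.shape)

    vfa_pre, vfa_post = [], []
    for fa in spec.flip_angles_deg:
        vfa_pre.append(ref.with_voxels(add_noise(render(t1_pre, fa, spec.vfa_tr_ms))))
        vfa_post.append(ref.with_voxels(add_noise(render(t1_post, fa, spec.vfa_tr_ms))))

    pre_t1w = add_noise(render(t1_pre, spec.t1w_flip_deg, spec.t1w_tr_ms))
    post_t1w = add_noise(render(t1_post, spec.t1w_flip_deg, spec.t1w_tr_ms))
    sham_pre = add_noise(render(t1_pre, spec.t1w_flip_deg, spec.t1w_tr_ms))
    sham_post = add_noise(render(t1_post_sham, spec.t1w_flip_deg, spec.t1w_tr_ms))

    # reference regions: "thalamus" = unsonicated deep tissue sphere; ACA = vessel tube
    thal = _ellipsoid_r2((xx, yy, zz), (0.0, -15.0, 0.0), (4.0, 4.0, 4.0)) <= 1.0
    thal &= parenchyma

    voxel_vol = float(np.prod(spacing))
    n_open = int(opening.sum())
    com = (
        np.array(
            [float(xx[opening].mean()), float(yy[opening].mean()), float(zz[opening].mean())]
        )
        if n_open
        else np.full(3, np.nan)
    )
    delivered_nmol = float(uptake[opening].sum()) * 1e-3 * voxel_vol * 1e-6 * 1e9
    sonicated = (
        _ellipsoid_r2(
            (xx, yy, zz),
            spec.opening_center_mm,
            tuple(a * spec.sonicated_scale for a in spec.opening_semi_axes_mm),
        )
        <= 1.0
    ) & brain

    truth = {
        "opening_volume_mm3": n_open * voxel_vol,
        "delivered_nmol": delivered_nmol,
        "opening_center_mm": com,
        "opening_mask": ref.with_voxels(opening, units="bool"),
        "t1_pre_ms": ref.with_voxels(t1_pre, units="ms"),
        "t1_post_ms": ref.with_voxels(t1_post, units="ms"),
        "gd_uptake_mM": ref.with_voxels(uptake, units="mM"),
    }
    return PhantomData(
        t1_pre=ref.with_voxels(t1_pre, units="ms"),
        t1_post=ref.with_voxels(t1_post, units="ms"),
        vfa_pre=vfa_pre,
        vfa_post=vfa_post,
        pre_t1w=ref.with_voxels(pre_t1w),
        post_t1w=ref.with_voxels(post_t1w),
        sham_pre_t1w=ref.with_voxels(sham_pre),
        sham_post_t1w=ref.with_voxels(sham_post),
        brain_mask=ref.with_voxels(brain, units="bool"),
        skull_mask=ref.with_voxels(skull, units="bool"),
        tissue_labels=ref.with_voxels(labels, units="label"),
        gd_truth=ref.with_voxels(gd, units="mM"),
        thalamus_mask=ref.with_voxels(thal, units="bool"),
        aca_mask=ref.with_voxels(vessel, units="bool"),
        sonicated_mask=ref.with_voxels(sonicated, units="bool"),
        truth=truth,
        spec=spec,
    )


@dataclass
class TargetingPhantom:
    skull_mask: VolumeGrid
    opening_mask: VolumeGrid
    plan: TargetPlan
    truth: dict


def build_targeting_phantom(
    shape: tuple[int, int, int] = (80, 80, 80),
    spacing_mm: float = 1.0,
    skull_radii_mm: tuple[float, float] = (30.0, 34.0),
    trajectory_tilt_deg: float = 0.0,
    opening_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    opening_axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
    opening_radius_mm: float = 3.0,
    opening_half_length_mm: float = 8.0,
    focus_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TargetingPhantom:
    """Spherical-shell skull phantom with a displaced cylindrical opening.

    The planned trajectory approaches along -z (entering through the top of
    the sphere), tilted by ``trajectory_tilt_deg`` in the x-z plane, so the
    analytic incidence angle at the outer sphere equals the tilt whenever the
    trajectory passes through the sphere centre.  The opening is a cylinder
    of known axis placed at ``focus + opening_offset``, so the true target
    shift decomposition is available in closed form.
    """
    ri, ro = skull_radii_mm
    if not (0 < ri < ro):
        raise ConfigurationError("skull radii must satisfy 0 < inner < outer")
    spacing = (spacing_mm,) * 3
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * spacing_mm
    ref = VolumeGrid(np.zeros(shape), affine)
    xx, yy, zz = _world_coords(shape, spacing)

    r = np.sqrt(xx**2 + yy**2 + zz**2)
    skull = (r > ri) & (r <= ro)

    tilt = np.deg2rad(trajectory_tilt_deg)
    trajectory = np.array([np.sin(tilt), 0.0, -np.cos(tilt)])  # approach direction
    focus = np.asarray(focus_mm, dtype=float)
    if np.linalg.norm(focus) >= ri:
        raise ConfigurationError("focus must lie inside the skull cavity")

    center = focus + np.asarray(opening_offset_mm, dtype=float)
    axis = np.asarray(opening_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    d = np.stack([xx - center[0], yy - center[1], zz - center[2]], axis=-1)
    along = d @ axis
    radial = np.linalg.norm(d - along[..., None] * axis, axis=-1)
    opening = (np.abs(along) <= opening_half_length_mm) & (radial <= opening_radius_mm)
    if np.any(opening & (r > ri)):
        raise ConfigurationError("opening must stay inside the skull cavity")

    # analytic entry point: march from the transducer side (focus - t*trajectory)
    # onto the outer sphere of radius ro
    fd = float(focus @ trajectory)
    t_entry = fd + np.sqrt(fd**2 - float(focus @ focus) + ro**2)  # transducer-side root
    entry = focus - t_entry * trajectory
    normal_out = entry / np.linalg.norm(entry)
    incidence = float(np.degrees(np.arccos(abs(trajectory @ normal_out))))

    shift = center - focus
    axial = abs(float(shift @ trajectory))
    lateral = float(np.linalg.norm(shift - (shift @ trajectory) * trajectory))

    truth = {
        "incidence_deg": incidence,
        "entry_point_mm": entry,
        "outer_normal": normal_out,
        "opening_axis": axis,
        "opening_center_mm": center,
        "total_shift_mm": float(np.linalg.norm(shift)),
        "lateral_shift_mm": lateral,
        "axial_shift_mm": axial,
    }
    return TargetingPhantom(
        skull_mask=ref.with_voxels(skull, units="bool"),
        opening_mask=ref.with_voxels(opening, units="bool"),
        plan=TargetPlan(focus=tuple(focus), trajectory=tuple(trajectory)),
        truth=truth,
    )
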