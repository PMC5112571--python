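"""BBB-opening volumetry and gadolinium delivery from co-registered volumes.

The quantification chain mirrors the standard contrast-enhancement pipeline
for focused-ultrasound blood-brain-barrier (BBB) opening:

1. contrast enhancement = ratio of post- to pre-contrast T1-weighted
   volumes, linearly rescaled so the unsonicated thalamus maps to 0 and the
   anterior cerebral artery (ACA, the intravascular reference) maps to 1;
2. sham-cohort enhancement is subtracted and the brain mask applied;
3. the opening volume is the above-cutoff volume inside a box-shaped volume
   of interest (VOI, default 10 x 10 x 32.5 mm^3) on the target, minus the
   same quantity in the mirror-image contralateral VOI; an opening is called
   significant when the volume exceeds a threshold (default 80 mm^3, the
   sham mean + 3 SD);
4. the delivered gadolinium amount integrates the concentration map over
   the ipsilateral VOI minus the contralateral VOI, after zeroing voxels
   exceeding the ACA concentration (intravascular signal) and masking to
   brain; delivery efficiency is the delivered fraction of the injected
   amount (default 1 mmol), in percent;
5. the opened voxels are broken down by tissue class, giving per-tissue
   opening fractions and the gray:white opening-probability ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, DegenerateInputError
from .grids import VolumeGrid
from .relaxometry import GdMap, TissueSegmentation, TISSUE_LABELS

__all__ = [
    "VoiSpec",
    "OpeningVolumeResult",
    "DeliveryResult",
    "TissueBreakdown",
    "OpeningReport",
    "enhancement_map",
    "opening_volume",
    "delivered_gd",
    "per_tissue_breakdown",
]

log = logging.getLogger(__name__)

DEFAULT_VOI_EXTENTS_MM = (10.0, 10.0, 32.5)
OPENING_SIGNIFICANCE_MM3 = 80.0  # sham-cohort mean + 3 SD
DEFAULT_INJECTED_MOL = 1e-3  # 1 mmol of Gd injected systemically


@dataclass(frozen=True)
class VoiSpec:
    """Axis-aligned box volume of interest in world millimetres.

    The contralateral VOI is the mirror image across the mid-sagittal plane
    ``x = mirror_plane_x`` (world mm, first axis).
    """

    center: tuple[float, float, float]
    extents: tuple[float, float, float] = DEFAULT_VOI_EXTENTS_MM
    mirror_plane_x: float = 0.0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extents):
            raise ConfigurationError("VOI extents must be positive")

    def mirrored(self) -> "VoiSpec":
        cx, cy, cz = self.center
        return VoiSpec(
            (2 * self.mirror_plane_x - cx, cy, cz), self.extents, self.mirror_plane_x
        )

    def mask(self, grid: VolumeGrid) -> np.ndarray:
        """Boolean voxel mask of the box, aligned to the grid axes."""
        c_vox = grid.world_to_voxel(np.asarray(self.center, dtype=float))
        half_vox = np.asarray(self.extents) / (2.0 * grid.spacing)
        lo = c_vox - half_vox
        hi = c_vox + half_vox
        if np.any(lo < -0.5) or np.any(hi > np.asarray(grid.shape) - 0.5):
            warnings.warn("VOI extends outside the grid; clipping", stacklevel=2)
        idx = [np.arange(n) for n in grid.shape]
        ii, jj, kk = np.meshgrid(*idx, indexing="ij")
        m = np.ones(grid.shape, dtype=bool)
        for axis, coord in enumerate((ii, jj, kk)):
            m &= (coord >= lo[axis]) & (coord <= hi[axis])
        return m


@dataclass
class OpeningVolumeResult:
    opening_volume_mm3: float
    opened_voxel_mask: VolumeGrid
    significant: bool
    significance_threshold_mm3: float
    ipsi_volume_mm3: float
    contra_volume_mm3: float


@dataclass
class DeliveryResult:
    delivered_nmol: float
    efficiency_pct: float
    injected_mol: float
    ipsi_nmol: float
    contra_nmol: float


@dataclass
class TissueBreakdown:
    """Per-tissue opening composition and the gray:white probability ratio."""

    table: pd.DataFrame  # index: tissue, columns: volumes/fractions/probabilities
    gray_white_probability_ratio: float
    ratio_defined: bool


@dataclass
class OpeningReport:
    """Combined outcome of one sonication's MRI quantification."""

    opening_volume_mm3: float
    significant: bool
    gd_delivered_nmol: float | None = None
    delivery_efficiency_pct: float | None = None
    injected_mol: float = DEFAULT_INJECTED_MOL
    tissue_breakdown: TissueBreakdown | None = None
    opened_voxel_mask: VolumeGrid | None = None

    @classmethod
    def from_parts(
        cls,
        vol: OpeningVolumeResult,
        delivery: DeliveryResult | None = None,
        breakdown: TissueBreakdown | None = None,
    ) -> "OpeningReport":
        return cls(
            opening_volume_mm3=vol.opening_volume_mm3,
            significant=vol.significant,
            gd_delivered_nmol=None if delivery is None else delivery.delivered_nmol,
            delivery_efficiency_pct=None if delivery is None else delivery.efficiency_pct,
            injected_mol=DEFAULT_INJECTED_MOL if delivery is None else delivery.injected_mol,
            tissue_breakdown=breakdown,
            opened_voxel_mask=vol.opened_voxel_mask,
        )

    def to_dict(self) -> dict:
        d = {
            "opening_volume_mm3": self.opening_volume_mm3,
            "significant": self.significant,
            "gd_delivered_nmol": self.gd_delivered_nmol,
            "delivery_efficiency_pct": self.delivery_efficiency_pct,
            "injected_mol": self.injected_mol,
        }
        if self.tissue_breakdown is not None:
            d["tissue"] = self.tissue_breakdown.table.to_dict(orient="index")
            d["gray_white_probability_ratio"] = (
                self.tissue_breakdown.gray_white_probability_ratio
            )
        return d


def enhancement_map(
    post_t1w: VolumeGrid,
    pre_t1w: VolumeGrid,
    thalamus_mask: np.ndarray | VolumeGrid,
    aca_mask: np.ndarray | VolumeGrid,
) -> VolumeGrid:
    """Normalized contrast enhancement: post/pre ratio scaled thalamus->0, ACA->1.

    Voxels where the pre-contrast signal is (numerically) zero are flagged
    invalid as NaN.  Raises :class:`ConfigurationError` for empty or
    overlapping reference regions and :class:`DegenerateInputError` when
    the two references have equal mean ratio (no contrast scale).
    """
    post_t1w.require_same_grid(pre_t1w, "enhancement_map")
    thal = _as_bool_mask(thalamus_mask, post_t1w)
    aca = _as_bool_mask(aca_mask, post_t1w)
    if not thal.any() or not aca.any():
        raise ConfigurationError("reference regions must be non-empty")
    if np.any(thal & aca):
        raise ConfigurationError("thalamus and ACA reference regions must be disjoint")

    pre = pre_t1w.voxels
    post = post_t1w.voxels
    ok = np.abs(pre) > 1e-9 * np.nanmax(np.abs(pre))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ok, post / pre, np.nan)

    thal_mean = float(np.nanmean(ratio[thal]))
    aca_mean = float(np.nanmean(ratio[aca]))
    denom = aca_mean - thal_mean
    if not np.isfinite(denom) or abs(denom) < 1e-9:
        raise DegenerateInputError(
            "reference regions have equal mean enhancement; cannot normalize"
        )
    return post_t1w.with_voxels((ratio - thal_mean) / denom, units="norm-enh")


def opening_volume(
    enh: VolumeGrid,
    brain_mask: np.ndarray | VolumeGrid,
    sham_enh: VolumeGrid | None,
    voi: VoiSpec,
    voxel_cutoff: float = 0.0,
    significance_threshold_mm3: float = OPENING_SIGNIFICANCE_MM3,
    min_cluster_voxels: int = 0,
) -> OpeningVolumeResult:
    """BBB-opening volume by above-cutoff counting with contralateral subtraction.

    The sham enhancement (if any) is subtracted voxelwise, the brain mask
    applied, and voxels with (residual) normalized enhancement strictly above
    ``voxel_cutoff`` are counted inside the ipsilateral VOI; the mirrored
    contralateral VOI's above-cutoff volume is subtracted and the result
    floored at zero.  Significance compares the final volume against
    ``significance_threshold_mm3``.

    ``min_cluster_voxels`` optionally removes above-cutoff connected
    components (face connectivity) smaller than the given voxel count before
    counting -- isolated noise voxels are spatially incoherent while a real
    opening is one contiguous region, so a modest value (~10) suppresses
    noise-driven counts without touching the opening itself.  Default 0
    (no cleanup).
    """
    brain = _as_bool_mask(brain_mask, enh)
    if sham_enh is None:
        log.info("opening_volume: no sham enhancement supplied; assuming zero")
        resid = enh.voxels
    else:
        enh.require_same_grid(sham_enh, "sham enhancement")
        resid = enh.voxels - sham_enh.voxels

    above = np.zeros(enh.shape, dtype=bool)
    finite = np.isfinite(resid)
    above[finite & brain & (resid > voxel_cutoff)] = True
    if min_cluster_voxels > 1 and above.any():
        lab, n = ndimage.label(above)  # face (6-) connectivity
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes < min_cluster_voxels)
        above &= ~np.isin(lab, small[small > 0])

    ipsi = voi.mask(enh)
    contra = voi.mirrored().mask(enh)
    vv = enh.voxel_volume_mm3
    ipsi_vol = float(np.sum(above & ipsi)) * vv
    contra_vol = float(np.sum(above & contra)) * vv
    volume = max(ipsi_vol - contra_vol, 0.0)
    return OpeningVolumeResult(
        opening_volume_mm3=volume,
        opened_voxel_mask=enh.with_voxels(above & ipsi, units="bool"),
        significant=volume > significance_threshold_mm3,
        significance_threshold_mm3=significance_threshold_mm3,
        ipsi_volume_mm3=ipsi_vol,
        contra_volume_mm3=contra_vol,
    )


def delivered_gd(
    gd: GdMap,
    brain_mask: np.ndarray | VolumeGrid,
    aca_concentration_mM: float,
    voi: VoiSpec,
    injected_mol: float = DEFAULT_INJECTED_MOL,
) -> DeliveryResult:
    """Delivered Gd amount (nmol) and delivery efficiency (% of injected).

    Voxels with concentration above the ACA (intravascular) level are zeroed
    as vessel signal, the brain mask is applied, and the concentration map is
    integrated over the ipsilateral VOI minus its contralateral mirror
    (removing intrinsic parenchymal Gd retention), floored at zero:
    ``delivered [mol] = sum [Gd][mol/L] * voxel volume [L]``.
    """
    if aca_concentration_mM <= 0:
        raise ConfigurationError("aca_concentration_mM must be positive")
    if injected_mol <= 0:
        raise ConfigurationError("injected_mol must be positive")
    grid = gd.concentration
    brain = _as_bool_mask(brain_mask, grid)
    conc = grid.voxels.copy()
    invalid = ~np.isfinite(conc)
    if invalid.any():
        log.info("delivered_gd: %d invalid voxels excluded", int(invalid.sum()))
    conc[invalid] = 0.0
    conc[conc > aca_concentration_mM] = 0.0
    conc[~brain] = 0.0

    ipsi = voi.mask(grid)
    contra = voi.mirrored().mask(grid)
    voxel_litres = grid.voxel_volume_mm3 * 1e-6
    # mM = mmol/L = 1e-3 mol/L
    ipsi_mol = float(np.sum(conc[ipsi])) * 1e-3 * voxel_litres
    contra_mol = float(np.sum(conc[contra])) * 1e-3 * voxel_litres
    delivered_mol = max(ipsi_mol - contra_mol, 0.0)
    return DeliveryResult(
        delivered_nmol=delivered_mol * 1e9,
        efficiency_pct=100.0 * delivered_mol / injected_mol,
        injected_mol=injected_mol,
        ipsi_nmol=ipsi_mol * 1e9,
        contra_nmol=contra_mol * 1e9,
    )


def per_tissue_breakdown(
    opened_voxel_mask: VolumeGrid,
    seg: TissueSegmentation,
    sonicated_region_mask: np.ndarray | VolumeGrid,
) -> TissueBreakdown:
    """Tissue composition of the opening and per-tissue opening probability.

    For each tissue class: the opened volume, its fraction of the total
    opening, its fraction of the sonicated region, and the opening
    probability ``|opened & tissue| / |sonicated & tissue|``.  The
    gray:white probability ratio quantifies how much more readily gray
    matter opens; it is NaN (flagged) when undefined.
    """
    opened_voxel_mask.require_same_grid(seg.labels, "tissue breakdown")
    opened = opened_voxel_mask.voxels.astype(bool)
    sonicated = _as_bool_mask(sonicated_region_mask, seg.labels)
    if not sonicated.any():
        raise ConfigurationError("sonicated region is empty")

    vv = seg.labels.voxel_volume_mm3
    n_open = int(opened.sum())
    n_son = int(sonicated.sum())
    rows = {}
    probs = {}
    for code, name in TISSUE_LABELS.items():
        tissue = seg.labels.voxels == code
        n_ot = int(np.sum(opened & tissue))
        n_st = int(np.sum(sonicated & tissue))
        prob = n_ot / n_st if n_st > 0 else np.nan
        probs[name] = prob
        rows[name] = {
            "opened_volume_mm3": n_ot * vv,
            "fraction_of_opening_pct": 100.0 * n_ot / n_open if n_open else 0.0,
            "fraction_of_sonicated_pct": 100.0 * n_st / n_son,
            "opening_probability": prob,
        }
    gw_defined = (
        np.isfinite(probs.get("gray", np.nan))
        and np.isfinite(probs.get("white", np.nan))
        and probs["white"] > 0
        and n_open > 0
    )
    ratio = probs["gray"] / probs["white"] if gw_defined else float("nan")
    return TissueBreakdown(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        gray_white_probability_ratio=ratio,
        ratio_defined=bool(gw_defined),
    )


def _as_bool_mask(mask, grid: VolumeGrid) -> np.ndarray:
    if isinstance(mask, VolumeGrid):
        grid.require_same_grid(mask, "mask")
        return mask.voxels.astype(bool)
    mask = np.asarray(mask)
    if mask.shape != grid.shape:
        raise ConfigurationError(f"mask shape {mask.shape} != grid {grid.shape}")
    return mask.astype(bool)
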