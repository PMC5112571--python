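"""Variable-flip-angle T1 relaxometry, Gd concentration maps, T1 tissue segmentation.

The spoiled-gradient-echo (SPGR) signal at flip angle alpha and repetition
time TR is

    S(alpha) = M0 * sin(alpha) * (1 - E1) / (1 - E1 * cos(alpha)),
    E1 = exp(-TR / T1).

Rearranged, ``S/sin(alpha) = E1 * S/tan(alpha) + M0*(1 - E1)`` -- a line
whose slope across flip angles gives E1 and hence T1 (the classic
DESPOT1 / VFA line fit).  With a pre-contrast map T1_0 and a post-contrast
map T1, the voxelwise gadolinium concentration follows from the fast-exchange
relaxivity relation

    [Gd] = (1/T1 - 1/T1_0) / r1,

with r1 = 4 s^-1 mM^-1 for gadodiamide (Gd-DTPA-BMA).  Tissue classes are
segmented from the pre-contrast T1 map by interval membership: blood
(1, 700] ms, white matter (700, 1170] ms, gray matter (1170, 1800] ms and
CSF (1800, 5000] ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, IncompatibleGridsError
from .grids import VolumeGrid

__all__ = [
    "VfaSeries",
    "T1FitResult",
    "GdMap",
    "TissueSegmentation",
    "DEFAULT_FLIP_ANGLES_DEG",
    "DEFAULT_TISSUE_THRESHOLDS_MS",
    "TISSUE_LABELS",
    "spgr_signal",
    "fit_t1",
    "gd_concentration",
    "segment_tissue",
]

log = logging.getLogger(__name__)

DEFAULT_FLIP_ANGLES_DEG = (5.0, 10.0, 15.0, 20.0, 35.0)
DEFAULT_TR_MS = 10.0
GD_DTPA_BMA_R1 = 4.0  # s^-1 mM^-1, gadodiamide

# label code -> name; thresholds are the half-open (lo, hi] interval bounds in ms
TISSUE_LABELS = {0: "unassigned", 1: "blood", 2: "white", 3: "gray", 4: "csf"}
DEFAULT_TISSUE_THRESHOLDS_MS = (1.0, 700.0, 1170.0, 1800.0, 5000.0)

T1_VALID_RANGE_MS = (1.0, 10000.0)  # outside: ln(E1) numerically meaningless


def spgr_signal(
    t1_ms: np.ndarray | float,
    flip_angle_deg: np.ndarray | float,
    tr_ms: float,
    m0: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Closed-form SPGR steady-state signal (forward model)."""
    t1_ms = np.asarray(t1_ms, dtype=float)
    alpha = np.deg2rad(flip_angle_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.exp(-tr_ms / t1_ms)
    return m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


@dataclass
class VfaSeries:
    """Multi-flip-angle SPGR volumes on a common grid."""

    volumes: list[VolumeGrid]
    flip_angles_deg: tuple[float, ...] = DEFAULT_FLIP_ANGLES_DEG
    tr_ms: float = DEFAULT_TR_MS

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.flip_angles_deg):
            raise ConfigurationError("one volume per flip angle required")
        if len(set(self.flip_angles_deg)) < 2:
            raise ConfigurationError("at least two distinct flip angles required")
        if self.tr_ms <= 0:
            raise ConfigurationError("TR must be positive")
        for v in self.volumes[1:]:
            self.volumes[0].require_same_grid(v, "VFA series")

    @property
    def grid(self) -> VolumeGrid:
        return self.volumes[0]

    def signal_stack(self) -> np.ndarray:
        """Signals as an array of shape (n_angles, nx, ny, nz)."""
        return np.stack([v.voxels for v in self.volumes], axis=0)


@dataclass
class T1FitResult:
    """Voxelwise DESPOT1 fit: T1 (ms), M0, linear-fit R^2 and a validity mask."""

    t1: VolumeGrid
    m0: VolumeGrid
    r_squared: VolumeGrid
    valid: VolumeGrid  # boolean-valued


@dataclass
class GdMap:
    """Voxelwise gadolinium concentration (mM) with provenance and validity."""

    concentration: VolumeGrid
    r1: float
    valid: VolumeGrid
    n_clamped_negative: int = 0
    t1_post: VolumeGrid | None = None
    t1_pre: VolumeGrid | None = None


@dataclass
class TissueSegmentation:
    """Integer-coded tissue labels (see :data:`TISSUE_LABELS`) from a pre-Gd T1 map."""

    labels: VolumeGrid
    thresholds_ms: tuple[float, ...] = DEFAULT_TISSUE_THRESHOLDS_MS

    def mask(self, tissue: str) -> np.ndarray:
        code = {v: k for k, v in TISSUE_LABELS.items()}[tissue]
        return self.labels.voxels == code


def fit_t1(series: VfaSeries) -> T1FitResult:
    """Voxelwise T1 and M0 by the VFA/DESPOT1 linear fit.

    Per voxel the points ``(x, y) = (S/tan(alpha), S/sin(alpha))`` are fit by
    unweighted least squares; the slope is E1 and ``T1 = -TR / ln(E1)``.
    Voxels with E1 outside (0, 1), T1 outside (1, 10000) ms, or degenerate
    regression (zero variance in x) are flagged invalid.  Raises
    :class:`DegenerateInputError` when no voxel yields a usable fit.
    """
    s = series.signal_stack()  # (k, ...)
    alphas = np.deg2rad(np.asarray(series.flip_angles_deg))
    k = alphas.size
    sin_a = np.sin(alphas).reshape((k,) + (1,) * (s.ndim - 1))
    tan_a = np.tan(alphas).reshape((k,) + (1,) * (s.ndim - 1))

    y = s / sin_a
    x = s / tan_a
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    syy = ((y - ym) ** 2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym - slope * xm
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 0.0)
        t1 = -series.tr_ms / np.log(slope)
        m0 = intercept / (1.0 - slope)

    lo, hi = T1_VALID_RANGE_MS
    valid = (
        np.isfinite(slope)
        & (slope > 0.0)
        & (slope < 1.0)
        & (sxx > 0)
        & np.isfinite(t1)
        & (t1 > lo)
        & (t1 < hi)
    )
    if not valid.any():
        raise DegenerateInputError("no voxel produced a usable VFA fit")

    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid, m0, np.nan)
    r2 = np.where(valid, r2, 0.0)
    g = series.grid
    return T1FitResult(
        t1=g.with_voxels(t1, units="ms"),
        m0=g.with_voxels(m0, units="a.u."),
        r_squared=g.with_voxels(r2, units=""),
        valid=g.with_voxels(valid, units="bool"),
    )


def gd_concentration(
    t1_post: VolumeGrid,
    t1_pre: VolumeGrid,
    r1: float = GD_DTPA_BMA_R1,
    valid_post: VolumeGrid | None = None,
    valid_pre: VolumeGrid | None = None,
) -> GdMap:
    """Gadolinium concentration map ``[Gd] = (1/T1 - 1/T1_0)/r1`` in mM.

    T1 maps are in ms; rates are formed in s^-1 so that with r1 in
    s^-1 mM^-1 the result is mM.  Negative concentrations (noise can push
    T1 above T1_0) are clamped to zero and counted; invalid-T1 voxels
    (NaN or flagged) propagate as invalid, never as silent zeros.
    """
    t1_post.require_same_grid(t1_pre, "gd_concentration")
    if r1 <= 0:
        raise ConfigurationError("relaxivity r1 must be positive")
    post_s = t1_post.voxels / 1000.0
    pre_s = t1_pre.voxels / 1000.0
    valid = np.isfinite(post_s) & np.isfinite(pre_s) & (post_s > 0) & (pre_s > 0)
    for extra in (valid_post, valid_pre):
        if extra is not None:
            t1_post.require_same_grid(extra, "validity mask")
            valid &= extra.voxels.astype(bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = (1.0 / post_s - 1.0 / pre_s) / r1
    n_neg = int(np.sum(valid & (conc < 0)))
    if n_neg:
        log.info("gd_concentration: clamped %d negative-concentration voxels", n_neg)
    conc = np.where(valid, np.clip(conc, 0.0, None), np.nan)
    return GdMap(
        concentration=t1_post.with_voxels(conc, units="mM"),
        r1=r1,
        valid=t1_post.with_voxels(valid, units="bool"),
        n_clamped_negative=n_neg,
        t1_post=t1_post,
        t1_pre=t1_pre,
    )


def segment_tissue(
    t1_pre: VolumeGrid,
    thresholds_ms: tuple[float, ...] = DEFAULT_TISSUE_THRESHOLDS_MS,
) -> TissueSegmentation:
    """Classify voxels by pre-contrast T1 into blood / white / gray / CSF.

    Intervals are half-open ``(lo, hi]`` over the ascending ``thresholds_ms``
    boundaries; voxels outside the overall range (or non-finite) are left
    unassigned (label 0).
    """
    th = np.asarray(thresholds_ms, dtype=float)
    if th.size != 5 or np.any(np.diff(th) <= 0):
        raise ConfigurationError("thresholds must be 5 strictly increasing values (ms)")
    t1 = t1_pre.voxels
    labels = np.zeros(t1.shape, dtype=np.int16)
    finite = np.isfinite(t1)
    for code in (1, 2, 3, 4):
        lo, hi = th[code - 1], th[code]
        labels[finite & (t1 > lo) & (t1 <= hi)] = code
    return TissueSegmentation(
        labels=t1_pre.with_voxels(labels, units="label"),
        thresholds_ms=tuple(th),
    )
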