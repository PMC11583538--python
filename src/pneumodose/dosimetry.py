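"""EQD2 conversion and dose-volume analytics for pneumonitis regions.

The planned physical dose D (Gy, accumulated over N equal fractions) is
converted per voxel to the equivalent dose in 2-Gy fractions under the
linear-quadratic model,

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta),   d = D / N,

with alpha/beta = 3 Gy for normal lung by default. Dose is then categorized
into three levels: low dose (LD) below 20 Gy, intermediate dose (ID) from
20 Gy up to (but excluding) 40 Gy, and high dose (HD) at 40 Gy and above;
"at least x Gy" metrics (V20, V40) use dose >= x, so exactly 20 Gy counts as
ID and toward V20, and exactly 40 Gy counts as HD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import BinaryMask, ImageGrid, mask_volume_cm3, same_geometry

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FractionationScheme:
    """Number of (equal) fractions and the tissue alpha/beta ratio in Gy."""

    n_fractions: int
    alpha_beta_gy: float = 3.0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.alpha_beta_gy <= 0:
            raise ValueError("alpha_beta_gy must be > 0")


@dataclass(frozen=True)
class DoseLevelConfig:
    """LD / ID / HD boundaries: LD < ld_upper_gy <= ID < hd_lower_gy <= HD."""

    ld_upper_gy: float = 20.0
    hd_lower_gy: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.ld_upper_gy < self.hd_lower_gy:
            raise ValueError("need 0 < ld_upper_gy < hd_lower_gy")


@dataclass
class DVH:
    """Cumulative dose-volume histogram: % of structure volume at >= each edge."""

    bin_edges_gy: np.ndarray
    cumulative_volume_pct: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges_gy = np.asarray(self.bin_edges_gy, dtype=float)
        self.cumulative_volume_pct = np.asarray(self.cumulative_volume_pct, dtype=float)
        if self.bin_edges_gy.shape != self.cumulative_volume_pct.shape:
            raise ValueError("edges and volumes must align")
        if self.bin_edges_gy[0] != 0 or np.any(np.diff(self.bin_edges_gy) <= 0):
            raise ValueError("bin edges must increase from 0")
        if abs(self.cumulative_volume_pct[0] - 100.0) > 1e-9:
            raise ValueError("cumulative DVH must start at 100%")
        if np.any(np.diff(self.cumulative_volume_pct) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")

    def volume_at(self, dose_gy: float) -> float:
        """Linear interpolation of the curve at an arbitrary dose."""
        return float(np.interp(dose_gy, self.bin_edges_gy, self.cumulative_volume_pct))


@dataclass
class PtpDoseMetrics:
    """Dosimetric summary of one pneumonitis volume (post GTV subtraction)."""

    volume_cm3: float
    v20_pct: float
    v20_cm3: float
    v40_pct: float
    mean_eqd2_gy: float
    ld_fraction_pct: float
    id_fraction_pct: float
    hd_fraction_pct: float
    auc_gy_pct: float


@dataclass
class LungMetrics:
    """Total-lung mean dose (Gy) and V20 (%)."""

    mld_gy: float
    v20_pct: float


def eqd2_convert(dose: ImageGrid, scheme: FractionationScheme) -> ImageGrid:
    """Voxel-wise EQD2 conversion of a physical dose grid.

    At 2 Gy per fraction the conversion is the identity for any alpha/beta;
    zero dose maps to zero and the map is monotone in D for fixed N.
    """
    d_total = np.asarray(dose.values, dtype=np.float64)
    if d_total.min() < 0:
        raise ValueError("dose grid contains negative values")
    per_fx = d_total / scheme.n_fractions
    eqd2 = d_total * (per_fx + scheme.alpha_beta_gy) / (2.0 + scheme.alpha_beta_gy)
    return dose.with_values(eqd2)


def subtract_gtv(ptp: BinaryMask, gtv: BinaryMask) -> BinaryMask:
    """Set difference ptp \\ gtv, so solid tumor never counts as pneumonitis."""
    if not same_geometry(ptp, gtv):
        raise ValueError("PTP and GTV masks live on different geometries")
    voxels = ptp.voxels & ~gtv.voxels
    if ptp.count() and not voxels.any():
        warnings.warn("GTV subtraction left an empty pneumonitis mask", stacklevel=2)
    return BinaryMask(voxels, ptp.spacing_mm, ptp.origin_mm, ptp.frame_id, ptp.roi_name)


def _in_mask_dose(dose: ImageGrid, mask: BinaryMask) -> np.ndarray:
    if not same_geometry(dose, mask):
        raise ValueError("dose grid and mask live on different geometries")
    if not mask.voxels.any():
        raise ValueError(f"mask {mask.roi_name!r} is empty")
    return np.asarray(dose.values, dtype=np.float64)[mask.voxels]


def compute_dvh(dose: ImageGrid, mask: BinaryMask, bin_width_gy: float = 0.1) -> DVH:
    """Cumulative DVH over edges 0, w, 2w, ... covering the max in-mask dose.

    The value at edge D is 100 x (in-mask voxels with dose >= D) / (in-mask voxels).
    """
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be > 0")
    doses = _in_mask_dose(dose, mask)
    n_edges = int(np.ceil(doses.max() / bin_width_gy)) + 2
    edges = np.arange(n_edges) * bin_width_gy
    sorted_doses = np.sort(doses)
    # voxels with dose >= edge == n - first index where dose >= edge
    at_least = doses.size - np.searchsorted(sorted_doses, edges, side="left")
    return DVH(edges, 100.0 * at_least / doses.size)


def dvh_auc(dvh: DVH) -> float:
    """Trapezoidal area under the cumulative DVH, in Gy*%.

    By the layer-cake identity AUC/100 approximates the mean in-mask dose to
    within one bin width.
    """
    return float(np.trapezoid(dvh.cumulative_volume_pct, dvh.bin_edges_gy))


def compute_ptp_metrics(
    eqd2: ImageGrid,
    ptp: BinaryMask,
    levels: DoseLevelConfig = DoseLevelConfig(),
    bin_width_gy: float = 0.1,
) -> PtpDoseMetrics:
    """All per-patient pneumonitis dose metrics on the EQD2 grid."""
    doses = _in_mask_dose(eqd2, ptp)
    n = doses.size
    vol_cm3 = mask_volume_cm3(ptp)
    ld, hd = levels.ld_upper_gy, levels.hd_lower_gy
    v20_frac = float((doses >= ld).sum()) / n
    v40_frac = float((doses >= hd).sum()) / n
    ld_pct = 100.0 * float((doses < ld).sum()) / n
    id_pct = 100.0 * float(((doses >= ld) & (doses < hd)).sum()) / n
    hd_pct = 100.0 * v40_frac
    dvh = compute_dvh(eqd2, ptp, bin_width_gy)
    return PtpDoseMetrics(
        volume_cm3=vol_cm3,
        v20_pct=100.0 * v20_frac,
        v20_cm3=vol_cm3 * v20_frac,
        v40_pct=100.0 * v40_frac,
        mean_eqd2_gy=float(doses.mean()),
        ld_fraction_pct=ld_pct,
        id_fraction_pct=id_pct,
        hd_fraction_pct=hd_pct,
        auc_gy_pct=dvh_auc(dvh),
    )


def compute_lung_metrics(eqd2: ImageGrid, lung: BinaryMask,
                         v_threshold_gy: float = 20.0) -> LungMetrics:
    """Mean lung dose and V20 of the total lung on the given dose grid."""
    doses = _in_mask_dose(eqd2, lung)
    return LungMetrics(
        mld_gy=float(doses.mean()),
        v20_pct=100.0 * float((doses >= v_threshold_gy).sum()) / doses.size,
    )
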