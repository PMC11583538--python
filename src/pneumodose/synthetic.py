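"""Self-contained phantom patients with known ground truth.

Every stage of the pipeline can be validated without clinical data: the module
generates paired planning / follow-up CTs related by a known smooth (Gaussian
bump) deformation, a conformal logistic dose distribution around the PTV, the
standard structures (GTV, PTV, total lung), and a two-lobe pneumonitis region
whose overlap with the high-dose (EQD2 >= 40 Gy) region is calibrated to a
target fraction. The anatomy is analytic, so all truth quantities (forward
displacement field, pneumonitis mask on the planning frame, per-level dose
fractions) are computable independently of the pipeline.

HU palette (plausible contrast, not clinical claims): air -1000, lung -700,
soft tissue 40, tumor 60, pneumonitis opacity -300 (ground-glass-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import dosimetry
from .dosimetry import DoseLevelConfig, FractionationScheme, LungMetrics, PtpDoseMetrics
from .cohort import PatientRecord
from .io_formats import BinaryMask, ImageGrid
from .registration import DisplacementField

HU_AIR = -1000.0
HU_LUNG = -700.0
HU_SOFT = 40.0
HU_TUMOR = 60.0
HU_PTP = -300.0


@dataclass
class PhantomSpec:
    """Geometry, anatomy, deformation, dose and noise of one phantom patient."""

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # anatomy (mm, phantom coordinates)
    body_center: tuple[float, float, float] = (80.0, 80.0, 60.0)
    body_axes: tuple[float, float, float] = (72.0, 58.0, 70.0)
    lung_centers: tuple = ((45.0, 78.0, 60.0), (115.0, 78.0, 60.0))
    lung_axes: tuple[float, float, float] = (28.0, 32.0, 40.0)
    # off-lattice centre: avoids degenerate voxel shells exactly at dose thresholds
    tumor_center: tuple[float, float, float] = (50.7, 80.4, 60.9)
    tumor_radius_mm: float = 10.0
    ptv_margin_mm: float = 10.0
    # deformation: Gaussian bump displacement applied to the follow-up frame
    deformation_center: tuple[float, float, float] = (52.3, 94.1, 60.6)
    deformation_peak_mm: float = 6.0
    deformation_sigma_mm: float = 22.0
    deformation_direction: tuple[float, float, float] = (0.6, 0.8, 0.0)
    # dose model
    prescription_gy: float = 60.0
    n_fractions: int = 30
    penumbra_mm: float = 10.0
    # pneumonitis model: in-field lobe + out-of-field lobe, clipped to lung
    ptp_in_lobe_offset_mm: tuple[float, float, float] = (-3.0, 3.0, 0.0)
    ptp_in_lobe_radius_mm: float = 17.0
    ptp_out_lobe_radius_mm: float = 20.0
    ptp_out_direction: tuple[float, float, float] = (0.0, 0.4, 0.9)
    ptp_lung_margin_mm: float = 3.0  # keep the opacity off the pleural wall
    overlap_fraction: float = 0.45  # target HD fraction of the PTP volume
    noise_sd_hu: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        extent = min(n * s for n, s in zip(self.shape, self.spacing_mm))
        if self.deformation_peak_mm >= extent / 4:
            raise ValueError("deformation peak must stay below a quarter of the extent")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")

    @property
    def ptv_radius_mm(self) -> float:
        return self.tumor_radius_mm + self.ptv_margin_mm

    def grid(self, frame_id: str) -> ImageGrid:
        return ImageGrid(np.zeros(self.shape), self.spacing_mm, self.origin_mm, frame_id)


@dataclass
class PhantomTruth:
    """Ground truth of one phantom pair, recomputable independently of the pipeline."""

    true_field: DisplacementField          # forward field on the planning grid
    true_ptp_planning: BinaryMask          # pneumonitis region in planning frame
    dose_fn: object                        # callable (N,3) mm -> physical Gy
    eqd2_fn: object                        # callable (N,3) mm -> EQD2 Gy
    achieved_overlap_fraction: float       # HD fraction actually realized
    spec: PhantomSpec

    def ptp_metrics(self, levels: DoseLevelConfig = DoseLevelConfig()) -> PtpDoseMetrics:
        """Analytic per-level truth metrics on the true planning-frame mask.

        The truth AUC uses the exact layer-cake identity AUC = 100 x mean EQD2.
        """
        mask = self.true_ptp_planning
        pts = _mask_centers(mask)
        doses = self.eqd2_fn(pts)
        n = doses.size
        vol = mask.count() * mask.voxel_volume_mm3 / 1000.0
        v20 = float((doses >= levels.ld_upper_gy).sum()) / n
        v40 = float((doses >= levels.hd_lower_gy).sum()) / n
        return PtpDoseMetrics(
            volume_cm3=vol,
            v20_pct=100 * v20,
            v20_cm3=vol * v20,
            v40_pct=100 * v40,
            mean_eqd2_gy=float(doses.mean()),
            ld_fraction_pct=100 * float((doses < levels.ld_upper_gy).sum()) / n,
            id_fraction_pct=100 * float(((doses >= levels.ld_upper_gy)
                                         & (doses < levels.hd_lower_gy)).sum()) / n,
            hd_fraction_pct=100 * v40,
            auc_gy_pct=100.0 * float(doses.mean()),
        )

    def lung_metrics(self, exclude_gtv: bool = True) -> LungMetrics:
        spec = self.spec
        grid = spec.grid("planning")
        lung = _lung_mask(spec, grid)
        vox = lung.voxels
        if exclude_gtv:
            vox = vox & ~_sphere_mask(grid, spec.tumor_center, spec.tumor_radius_mm)
        pts = _grid_points(grid)[vox.ravel()]
        doses = self.eqd2_fn(pts)
        return LungMetrics(mld_gy=float(doses.mean()),
                           v20_pct=100.0 * float((doses >= 20.0).sum()) / doses.size)


# ---------------------------------------------------------------------------
# analytic geometry helpers
# ---------------------------------------------------------------------------

def _grid_points(grid: ImageGrid) -> np.ndarray:
    axes = grid.voxel_centers_mm()
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def _mask_centers(mask: BinaryMask) -> np.ndarray:
    idx = np.argwhere(mask.voxels)
    return np.asarray(mask.origin_mm) + idx * np.asarray(mask.spacing_mm)


def _in_ellipsoid(points, center, axes) -> np.ndarray:
    d = (points - np.asarray(center)) / np.asarray(axes)
    return (d ** 2).sum(axis=1) <= 1.0


def _in_sphere(points, center, radius) -> np.ndarray:
    d = points - np.asarray(center)
    return (d ** 2).sum(axis=1) <= radius ** 2


def _sphere_mask(grid: ImageGrid, center, radius) -> np.ndarray:
    return _in_sphere(_grid_points(grid), center, radius).reshape(grid.shape)


def _lung_region(spec: PhantomSpec, points: np.ndarray,
                 margin_mm: float = 0.0) -> np.ndarray:
    axes = tuple(a - margin_mm for a in spec.lung_axes)
    inside = np.zeros(len(points), dtype=bool)
    for c in spec.lung_centers:
        inside |= _in_ellipsoid(points, c, axes)
    return inside


def _lung_mask(spec: PhantomSpec, grid: ImageGrid) -> BinaryMask:
    vox = _lung_region(spec, _grid_points(grid)).reshape(grid.shape)
    return BinaryMask.from_grid(grid, vox, "Lung_total")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# dose and pneumonitis models
# ---------------------------------------------------------------------------

def make_dose_fn(spec: PhantomSpec):
    """Analytic conformal dose: prescription inside the PTV with logistic
    falloff whose 20-80% penumbra width is ``penumbra_mm``."""
    s = spec.penumbra_mm / (2.0 * math.log(4.0))
    center = np.asarray(spec.tumor_center)
    r_ptv = spec.ptv_radius_mm

    def dose(points: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(np.atleast_2d(points) - center, axis=1)
        return spec.prescription_gy / (1.0 + np.exp((r - r_ptv) / s))

    return dose


def make_eqd2_fn(spec: PhantomSpec):
    dose = make_dose_fn(spec)
    scheme = FractionationScheme(spec.n_fractions)

    def eqd2(points: np.ndarray) -> np.ndarray:
        d_total = dose(points)
        return d_total * (d_total / scheme.n_fractions + scheme.alpha_beta_gy) \
            / (2.0 + scheme.alpha_beta_gy)

    return eqd2


def _ptp_region_fn(spec: PhantomSpec, out_offset_mm: float,
                   out_radius_mm: float | None = None, net: bool = False):
    """Membership function of the two-lobe pneumonitis region (anatomy frame).

    ``net=False`` is the region as delineated on the follow-up CT (it may
    overlap the tumor); ``net=True`` excludes the GTV sphere, matching the
    analysis convention that solid tumor never counts as pneumonitis.
    """
    c_in = np.asarray(spec.tumor_center) + np.asarray(spec.ptp_in_lobe_offset_mm)
    c_out = np.asarray(spec.tumor_center) + _unit(spec.ptp_out_direction) * out_offset_mm
    r_out = spec.ptp_out_lobe_radius_mm if out_radius_mm is None else out_radius_mm

    def region(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        lobes = _in_sphere(pts, c_in, spec.ptp_in_lobe_radius_mm)
        if r_out > 0:
            lobes |= _in_sphere(pts, c_out, r_out)
        inside = lobes & _lung_region(spec, pts, spec.ptp_lung_margin_mm)
        if net:
            inside &= ~_in_sphere(pts, spec.tumor_center, spec.tumor_radius_mm)
        return inside

    return region


def calibrate_ptp_region(spec: PhantomSpec, max_offset_mm: float = 40.0,
                         tol: float = 0.0125):
    """Choose out-lobe placement and size so the HD fraction of the net
    (GTV-excluded) pneumonitis region meets ``spec.overlap_fraction`` as
    closely as the geometry allows.

    A 2-D grid of (offset along ``ptp_out_direction``, out-lobe radius up to
    the configured one) is scanned on the planning grid; lung clipping makes
    the response non-monotone, so no bisection. Among candidates within
    ``tol`` of the target the largest region wins (better statistics);
    otherwise the closest. Extreme targets clamp to what the geometry supports
    (penumbra leakage below 1.0, a lobe-size floor above 0). Returns
    ``(offset_mm, out_radius_mm, achieved_fraction)``.
    """
    grid = spec.grid("planning")
    pts = _grid_points(grid)
    hd = make_eqd2_fn(spec)(pts) >= 40.0
    lung_er = _lung_region(spec, pts, spec.ptp_lung_margin_mm)
    not_gtv = ~_in_sphere(pts, spec.tumor_center, spec.tumor_radius_mm)
    base = lung_er & not_gtv
    c_in = np.asarray(spec.tumor_center) + np.asarray(spec.ptp_in_lobe_offset_mm)
    in_mask = _in_sphere(pts, c_in, spec.ptp_in_lobe_radius_mm) & base
    direction = _unit(spec.ptp_out_direction)
    tumor = np.asarray(spec.tumor_center)

    offsets = np.arange(0.0, max_offset_mm + 1e-9, 2.0)
    radii = np.linspace(0.0, spec.ptp_out_lobe_radius_mm, 9)
    candidates = []  # (deviation, -n_voxels, offset, radius, fraction)
    for t in offsets:
        d2 = ((pts - (tumor + direction * t)) ** 2).sum(axis=1)
        for r in radii:
            region = in_mask | ((d2 <= r * r) & base)
            n = int(region.sum())
            if n == 0:
                continue
            f = float(hd[region].sum()) / n
            candidates.append((abs(f - spec.overlap_fraction), -n, float(t),
                               float(r), f))
    candidates.sort()
    best_dev = candidates[0][0]
    near = [c for c in candidates if c[0] <= max(best_dev, tol)]
    near.sort(key=lambda c: c[1])  # largest region first
    _, _, offset, radius, achieved = near[0]
    return offset, radius, achieved


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def make_bump_fn(spec: PhantomSpec):
    """Gaussian-bump displacement w(y) (mm) applied in the follow-up frame."""
    center = np.asarray(spec.deformation_center)
    direction = _unit(spec.deformation_direction) if spec.deformation_peak_mm > 0 \
        else np.zeros(3)
    peak = spec.deformation_peak_mm
    sig2 = 2.0 * spec.deformation_sigma_mm ** 2

    def bump(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        d2 = ((pts - center) ** 2).sum(axis=1)
        return np.outer(peak * np.exp(-d2 / sig2), direction)

    return bump


def _check_no_folding(spec: PhantomSpec, bump_fn, grid: ImageGrid) -> None:
    """Reject deformations whose Jacobian det(I + grad w) is not positive."""
    if spec.deformation_peak_mm == 0:
        return
    pts = _grid_points(grid)
    w = bump_fn(pts).reshape(grid.shape + (3,))
    grads = np.empty((3, 3) + grid.shape)
    for c in range(3):
        for a in range(3):
            grads[c, a] = np.gradient(w[..., c], grid.spacing_mm[a], axis=a)
    ident = np.eye(3)[:, :, None, None, None]
    jac = np.linalg.det(np.moveaxis(grads + ident, (0, 1), (-2, -1)))
    if jac.min() <= 0:
        raise ValueError(
            f"deformation folds space (min Jacobian {jac.min():.3f} <= 0); "
            "reduce peak or widen sigma")


def true_forward_field(spec: PhantomSpec, bump_fn, grid: ImageGrid,
                       n_iter: int = 25) -> DisplacementField:
    """Exact forward field u on the planning grid: u(x) = -w(x + u(x)).

    Solved by fixed-point iteration, which contracts because the analytic bump
    has |grad w| < 1 (enforced by the folding check).
    """
    pts = _grid_points(grid)
    u = np.zeros_like(pts)
    for _ in range(n_iter):
        u = -bump_fn(pts + u)
    return DisplacementField(u.reshape(grid.shape + (3,)), grid.spacing_mm,
                             grid.origin_mm, grid.frame_id)


# ---------------------------------------------------------------------------
# phantom pair generation
# ---------------------------------------------------------------------------

def _scene_hu(spec: PhantomSpec, points: np.ndarray, region_fn=None) -> np.ndarray:
    hu = np.full(len(points), HU_AIR)
    hu[_in_ellipsoid(points, spec.body_center, spec.body_axes)] = HU_SOFT
    hu[_lung_region(spec, points)] = HU_LUNG
    if region_fn is not None:
        hu[region_fn(points)] = HU_PTP
    hu[_in_sphere(points, spec.tumor_center, spec.tumor_radius_mm)] = HU_TUMOR
    return hu


def generate_phantom_pair(spec: PhantomSpec):
    """Generate (planning CT, follow-up CT, structures, dose grid, truth).

    The follow-up CT shows the anatomy plus the pneumonitis opacity, observed
    through the Gaussian-bump deformation; the planning CT is the undeformed
    anatomy. Both carry independent Gaussian HU noise. All outputs are
    bit-reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    plan_grid = spec.grid("planning")
    fu_grid = spec.grid("followup")
    pts = _grid_points(plan_grid)

    offset, out_radius, achieved = calibrate_ptp_region(spec)
    # as delineated on the follow-up CT (may hit the GTV) vs the analysis truth
    region_fn = _ptp_region_fn(spec, offset, out_radius)
    net_region_fn = _ptp_region_fn(spec, offset, out_radius, net=True)
    bump_fn = make_bump_fn(spec)
    _check_no_folding(spec, bump_fn, plan_grid)

    planning_hu = _scene_hu(spec, pts).reshape(spec.shape)
    fu_pts = pts + bump_fn(pts)  # follow-up voxel centre mapped to anatomy frame
    followup_hu = _scene_hu(spec, fu_pts, region_fn).reshape(spec.shape)
    if spec.noise_sd_hu > 0:
        planning_hu = planning_hu + rng.normal(0, spec.noise_sd_hu, spec.shape)
        followup_hu = followup_hu + rng.normal(0, spec.noise_sd_hu, spec.shape)

    planning_ct = ImageGrid(planning_hu, spec.spacing_mm, spec.origin_mm, "planning")
    followup_ct = ImageGrid(followup_hu, spec.spacing_mm, spec.origin_mm, "followup")

    structures = {
        "GTV": BinaryMask.from_grid(planning_ct,
                                    _sphere_mask(planning_ct, spec.tumor_center,
                                                 spec.tumor_radius_mm), "GTV"),
        "PTV": BinaryMask.from_grid(planning_ct,
                                    _sphere_mask(planning_ct, spec.tumor_center,
                                                 spec.ptv_radius_mm), "PTV"),
        "Lung_total": _lung_mask(spec, planning_ct),
    }
    # pneumonitis as delineated on the follow-up CT (deformed frame)
    ptp_followup = BinaryMask.from_grid(
        fu_grid, region_fn(fu_pts).reshape(spec.shape), "PTP")
    ptp_followup.frame_id = "followup"
    structures["PTP_followup"] = ptp_followup

    # dose on its own (offset, different-resolution) grid, as exported by a
    # planning system
    dose_spacing = (2.0, 2.0, 2.0)
    dose_shape = tuple(int(n * s / 2.0) - 1 for n, s in zip(spec.shape, spec.spacing_mm))
    dose_origin = tuple(o + off for o, off in zip(spec.origin_mm, (1.1, 0.7, 0.9)))
    dose_grid = ImageGrid(np.zeros(dose_shape), dose_spacing, dose_origin, "planning")
    dose_fn = make_dose_fn(spec)
    dose_grid = dose_grid.with_values(
        dose_fn(_grid_points(dose_grid)).reshape(dose_shape))

    truth = PhantomTruth(
        true_field=true_forward_field(spec, bump_fn, plan_grid),
        true_ptp_planning=BinaryMask.from_grid(
            planning_ct, net_region_fn(pts).reshape(spec.shape), "PTP"),
        dose_fn=dose_fn,
        eqd2_fn=make_eqd2_fn(spec),
        achieved_overlap_fraction=achieved,
        spec=spec,
    )
    return planning_ct, followup_ct, structures, dose_grid, truth


# ---------------------------------------------------------------------------
# simulated cohorts
# ---------------------------------------------------------------------------

_COHORT_SHAPE = (24, 24, 24)
_COHORT_SPACING = (5.0, 5.0, 5.0)


def _cohort_patient_metrics(rng, rx_gy, n_fx, theta) -> tuple[PtpDoseMetrics, LungMetrics]:
    """Metrics for one simulated patient, computed by the real dosimetry chain
    on a small analytic dose grid. ``theta`` in [0, 1] steers how much of the
    pneumonitis sphere sits inside the treated volume."""
    center = np.array([60.0, 60.0, 60.0])
    grid = ImageGrid(np.zeros(_COHORT_SHAPE), _COHORT_SPACING, (0, 0, 0), "sim")
    pts = _grid_points(grid)
    r_ptv = float(rng.uniform(18.0, 32.0))
    s = 10.0 / (2.0 * math.log(4.0))
    r = np.linalg.norm(pts - center, axis=1)
    dose = ImageGrid((rx_gy / (1.0 + np.exp((r - r_ptv) / s))).reshape(_COHORT_SHAPE),
                     _COHORT_SPACING, (0, 0, 0), "sim")
    r_ptp = float(rng.uniform(12.0, 30.0))
    offset_dir = _unit(rng.normal(size=3))
    offset = (1.0 - theta) * (r_ptv + r_ptp)
    c_ptp = center + offset_dir * offset
    ptp = BinaryMask.from_grid(grid, _in_sphere(pts, c_ptp, r_ptp).reshape(_COHORT_SHAPE),
                               "PTP")
    if not ptp.voxels.any():  # sphere fell outside the grid; fall back to in-field
        ptp = BinaryMask.from_grid(grid, _in_sphere(pts, center, r_ptp)
                                   .reshape(_COHORT_SHAPE), "PTP")
    lung = BinaryMask.from_grid(grid, _in_ellipsoid(pts, center, (52.0, 48.0, 48.0))
                                .reshape(_COHORT_SHAPE), "Lung_total")
    eqd2 = dosimetry.eqd2_convert(dose, FractionationScheme(n_fx))
    metrics = dosimetry.compute_ptp_metrics(eqd2, ptp, bin_width_gy=0.25)
    lung_metrics = dosimetry.compute_lung_metrics(eqd2, lung)
    return metrics, lung_metrics


def generate_cohort(n_per_group: int, effect_auc_gy_pct: float = 0.0,
                    seed: int = 0) -> list[PatientRecord]:
    """Simulate a two-group pneumonitis cohort with the real dosimetry chain.

    Each patient receives a sampled fractionation scheme (definitive 54-66 Gy at
    1.8-2 Gy per fraction, palliative 30-50.4 Gy at 1.8-3 Gy), a sampled PTV,
    and a pneumonitis sphere whose in-field share is the random parameter theta.
    ``effect_auc_gy_pct`` shifts theta in the RCT_ICI group by an amount chosen
    to raise the expected DVH AUC by roughly that many Gy*%; at 0 the two groups
    are exchangeable (a true null for every summarized variable).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    # AUC ~ 100 x mean EQD2; a theta shift moves mean EQD2 by ~55 Gy per unit
    delta_theta = effect_auc_gy_pct / (100.0 * 55.0)
    records = []
    for group, tag in (("RCT_ICI", "ICI"), ("RCT", "CTL")):
        for i in range(n_per_group):
            definitive = rng.uniform() < 0.65
            if definitive:
                fx_dose = rng.uniform(1.8, 2.0)
                n_fx = int(round(rng.uniform(54.0, 66.0) / fx_dose))
            else:
                fx_dose = rng.uniform(1.8, 3.0)
                n_fx = max(1, int(round(rng.uniform(30.0, 50.4) / fx_dose)))
            rx = n_fx * fx_dose
            theta = rng.normal(0.45, 0.18)
            if group == "RCT_ICI":
                theta += delta_theta
            theta = float(np.clip(theta, 0.05, 0.95))
            metrics, lung_metrics = _cohort_patient_metrics(rng, rx, n_fx, theta)
            ptv_cm3 = float(np.clip(rng.lognormal(6.0, 0.55), 90.0, 1200.0))
            grade = int(rng.choice([1, 2, 3], p=[0.65, 0.25, 0.10]))
            onset = int(np.clip(rng.normal(87.0, 55.0), 5, 400))
            records.append(PatientRecord(
                patient_id=f"{tag}-{i:03d}",
                group=group,
                intent="definitive" if definitive else "palliative",
                ptv_cm3=ptv_cm3,
                pneumonitis=True,
                grade=grade,
                onset_days=onset,
                metrics=metrics,
                lung=lung_metrics,
            ))
    return records
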