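"""Deformable registration of the follow-up CT onto the planning CT.

Classic (additive) Thirion demons with Gaussian field regularization, run over a
multi-resolution pyramid. The displacement field lives on the fixed (planning)
grid: ``fixed-frame point + vector = corresponding moving-frame point``, so a
pneumonitis mask delineated on the follow-up CT can be pulled straight into the
frame of the dose grid.

Per iteration the update at each voxel is

    delta = -(m(x+u) - f(x)) * grad f / (|grad f|^2 + (m(x+u) - f(x))^2 / K)

with K the squared mean voxel spacing (the standard intensity/geometry
normalization, giving the update mm units and a bounded step of sqrt(K)/2),
step-limited to ``max_step_mm``, added to the field and Gaussian-smoothed with
``field_smoothing_sigma_mm``. The negative sign moves the sampled moving-image
point toward the fixed intensity under the field convention above. Everything
is deterministic given inputs and parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .io_formats import BinaryMask, ImageGrid, same_geometry

log = logging.getLogger(__name__)

_HU_CLAMP = (-1000.0, 1000.0)  # bone/metal extremes destabilize demons forces


@dataclass
class DemonsParams:
    """Parameters of the multi-resolution demons solver (all lengths in mm)."""

    pyramid_levels: int = 3
    iterations_per_level: int = 50
    field_smoothing_sigma_mm: float = 3.0
    max_step_mm: float = 2.0
    convergence_tol_mm: float = 0.005

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if min(self.iterations_per_level, self.field_smoothing_sigma_mm,
               self.max_step_mm, self.convergence_tol_mm) <= 0:
            raise ValueError("all demons parameters must be positive")


@dataclass
class DisplacementField:
    """Per-voxel 3-D displacement (mm) on the fixed grid."""

    vectors: np.ndarray  # (nx, ny, nz, 3)
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_id: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[3] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("displacement field contains non-finite components")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.vectors ** 2).sum(axis=3))


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Anti-aliased strided downsampling; geometry keeps the same origin."""
    if factor == 1:
        return img
    smoothed = gaussian_filter(img, sigma=factor / 2.0)
    return smoothed[::factor, ::factor, ::factor]


def _warp_coords(shape, spacing, origin, u, m_spacing, m_origin):
    """Moving-image index coordinates of fixed voxel centres displaced by u."""
    idx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    coords = np.empty((3,) + tuple(shape))
    for a in range(3):
        pos = origin[a] + idx[a] * spacing[a] + u[..., a]
        coords[a] = (pos - m_origin[a]) / m_spacing[a]
    return coords


def _upsample_field(u: np.ndarray, new_shape, ratio: float) -> np.ndarray:
    """Resample a displacement field (mm values) onto a finer grid of the same origin."""
    idx = np.meshgrid(*(np.arange(n) for n in new_shape), indexing="ij")
    coords = np.stack([idx[a] / ratio for a in range(3)])
    out = np.empty(tuple(new_shape) + (3,))
    for c in range(3):
        out[..., c] = map_coordinates(u[..., c], coords, order=1, mode="nearest")
    return out


def demons_register(fixed: ImageGrid, moving: ImageGrid,
                    params: DemonsParams | None = None) -> DisplacementField:
    """Register ``moving`` (follow-up CT) onto ``fixed`` (planning CT).

    Returns the displacement field on the fixed grid. ``field.diagnostics``
    carries per-level mean-squared intensity residuals (before/after) and
    iteration counts.
    """
    params = params or DemonsParams()
    for name, img in (("fixed", fixed), ("moving", moving)):
        if not np.isfinite(img.values).all():
            raise ValueError(f"{name} image contains non-finite voxels")
    lo = [max(f[0], m[0]) for f, m in zip(fixed.extent_mm(), moving.extent_mm())]
    hi = [min(f[1], m[1]) for f, m in zip(fixed.extent_mm(), moving.extent_mm())]
    if any(l >= h for l, h in zip(lo, hi)):
        raise ValueError("fixed and moving extents do not overlap")

    f_full = np.clip(np.asarray(fixed.values, dtype=np.float64), *_HU_CLAMP)
    m_full = np.clip(np.asarray(moving.values, dtype=np.float64), *_HU_CLAMP)

    diagnostics: dict = {"levels": []}
    u = None
    prev_factor = None
    for level in reversed(range(params.pyramid_levels)):
        factor = 2 ** level
        if any(n // factor < 4 for n in fixed.shape):
            factor = max(1, min(n // 4 for n in fixed.shape))
        f_l = _downsample(f_full, factor)
        m_l = _downsample(m_full, factor)
        spacing = tuple(s * factor for s in fixed.spacing_mm)
        m_spacing = tuple(s * factor for s in moving.spacing_mm)
        K = float(np.mean(spacing)) ** 2
        if u is None:
            u = np.zeros(f_l.shape + (3,))
        elif u.shape[:3] != f_l.shape:
            u = _upsample_field(u, f_l.shape, ratio=prev_factor / factor)
        prev_factor = factor
        grads = np.gradient(f_l, *spacing)
        g2 = sum(g * g for g in grads)
        # never smooth below one voxel, or coarse levels lose regularization
        sigma_vox = [max(params.field_smoothing_sigma_mm / s, 1.0) for s in spacing]

        def residual(u_now):
            coords = _warp_coords(f_l.shape, spacing, fixed.origin_mm, u_now,
                                  m_spacing, moving.origin_mm)
            warped = map_coordinates(m_l, coords, order=1, mode="nearest")
            return warped - f_l

        diff0 = residual(u)
        mse_before = float((diff0 ** 2).mean())
        iters_used = 0
        for it in range(params.iterations_per_level):
            diff = diff0 if it == 0 else residual(u)
            denom = g2 + diff * diff / K
            scale = np.where(denom > 1e-9, -diff / np.maximum(denom, 1e-9), 0.0)
            delta = np.stack([scale * g for g in grads], axis=3)
            mag = np.sqrt((delta ** 2).sum(axis=3))
            over = mag > params.max_step_mm
            if over.any():
                delta[over] *= (params.max_step_mm / mag[over])[:, None]
            u = u + delta
            for c in range(3):
                u[..., c] = gaussian_filter(u[..., c], sigma=sigma_vox)
            iters_used = it + 1
            if float(mag.mean()) < params.convergence_tol_mm:
                break
        mse_after = float((residual(u) ** 2).mean())
        diagnostics["levels"].append({
            "factor": factor, "iterations": iters_used,
            "mse_before": mse_before, "mse_after": mse_after,
        })
        log.info("demons level 1/%d: %d iters, MSE %.1f -> %.1f",
                 factor, iters_used, mse_before, mse_after)

    if u.shape[:3] != fixed.shape:
        u = _upsample_field(u, fixed.shape, ratio=float(prev_factor))
    return DisplacementField(u, fixed.spacing_mm, fixed.origin_mm, fixed.frame_id,
                             diagnostics)


def warp_image(moving: ImageGrid, field: DisplacementField) -> ImageGrid:
    """Pull ``moving`` onto the fixed grid through the displacement field."""
    coords = _warp_coords(field.shape, field.spacing_mm, field.origin_mm,
                          field.vectors, moving.spacing_mm, moving.origin_mm)
    values = map_coordinates(np.asarray(moving.values, dtype=np.float64), coords,
                             order=1, mode="nearest")
    return ImageGrid(values, field.spacing_mm, field.origin_mm, field.frame_id)


def warp_mask(mask_on_moving: BinaryMask, field: DisplacementField) -> BinaryMask:
    """Warp a mask from the moving (follow-up) frame onto the fixed grid.

    The mask is sampled as a trilinear 0/1 indicator at each displaced fixed
    voxel centre and thresholded at 0.5; samples outside the moving extent are
    background. With the zero field on matching geometry this is the identity.
    """
    zero_field = not field.vectors.any()
    if zero_field and same_geometry(mask_on_moving, field):
        return BinaryMask(mask_on_moving.voxels.copy(), field.spacing_mm,
                          field.origin_mm, field.frame_id, mask_on_moving.roi_name)
    coords = _warp_coords(field.shape, field.spacing_mm, field.origin_mm,
                          field.vectors, mask_on_moving.spacing_mm,
                          mask_on_moving.origin_mm)
    sampled = map_coordinates(mask_on_moving.voxels.astype(np.float32), coords,
                              order=1, mode="constant", cval=0.0)
    voxels = sampled >= 0.5
    if mask_on_moving.count() and not voxels.any():
        warnings.warn(
            f"warped mask {mask_on_moving.roi_name!r} is empty "
            "(mapped outside the moving extent?)", stacklevel=2)
    return BinaryMask(voxels, field.spacing_mm, field.origin_mm, field.frame_id,
                      mask_on_moving.roi_name)
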