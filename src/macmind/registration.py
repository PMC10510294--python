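"""Warping, a classical multi-resolution deformable optimizer, and
deformation-field quality analysis.

The optimizer is a desk-scale, deterministic stand-in for a trained
registration network: Gaussian-smoothed dense gradient descent (demons
style) on the descriptor similarity, with a coarse-to-fine pyramid and a
step-halving line search that only ever accepts non-increasing total-loss
steps.  Descriptors are recomputed from the warped moving *image* at every
loss evaluation rather than warping a pre-computed feature map: the
self-similarity normalisation then absorbs interpolation-induced blur, which
otherwise biases the objective (a warped feature map has its noise smoothed,
so any off-grid field spuriously lowers a feature-map SSD).  The descent
direction uses the warped image's feature gradients with a
mean-regularised demons normalisation, so texture-free regions stay quiet.

The optimizer's internal objective weights the diffusion regulariser per
voxel (E_smo / number of voxels) and defaults to a heavier smoothness weight
than the loss-module default: a classical greedy optimizer needs the
stronger prior to avoid chasing the structured cross-modality residual that
a trained network averages away over a cohort.

Field quality is summarized by the fraction of voxels whose deformation
Jacobian determinant is negative ("folding", a non-physical local
inversion), conventionally quoted per ten thousand voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core_io import DisplacementField, LabelMask, Volume
from .descriptors import DescriptorConfig, macmind, mind_descriptor
from .losses import LossReport, RegLossConfig, dice_label_loss, smoothness_loss

logger = logging.getLogger(__name__)

__all__ = [
    "RegistrationConfig",
    "JacobianReport",
    "warp",
    "warp_mask_soft",
    "register",
    "jacobian_report",
]


# ---------------------------------------------------------------------------
# trilinear sampling of channel stacks

def _sample_stack(stack: np.ndarray, coords: np.ndarray, nearest: bool = False) -> np.ndarray:
    """Sample a (X, Y, Z, C) stack at fractional voxel coordinates.

    ``coords`` is (..., 3); out-of-bounds positions use edge replication.
    Trilinear by default; ``nearest=True`` rounds to the closest voxel.
    Exact at integer coordinates (zero displacement is the identity).
    """
    shape = np.asarray(stack.shape[:3])
    c = np.moveaxis(np.asarray(coords, dtype=np.float64), -1, 0)  # (3, ...)
    c = np.clip(c, 0.0, (shape - 1).reshape(3, *([1] * (c.ndim - 1))))
    if nearest:
        idx = np.rint(c).astype(int)
        return stack[idx[0], idx[1], idx[2]]
    c0 = np.floor(c).astype(int)
    c0 = np.minimum(c0, (shape - 2).reshape(3, *([1] * (c.ndim - 1))))
    c0 = np.maximum(c0, 0)
    w = c - c0
    x0, y0, z0 = c0
    x1, y1, z1 = x0 + 1, y0 + 1, z0 + 1
    wx, wy, wz = (w[i][..., None] for i in range(3))
    out = (
        stack[x0, y0, z0] * (1 - wx) * (1 - wy) * (1 - wz)
        + stack[x1, y0, z0] * wx * (1 - wy) * (1 - wz)
        + stack[x0, y1, z0] * (1 - wx) * wy * (1 - wz)
        + stack[x0, y0, z1] * (1 - wx) * (1 - wy) * wz
        + stack[x1, y1, z0] * wx * wy * (1 - wz)
        + stack[x1, y0, z1] * wx * (1 - wy) * wz
        + stack[x0, y1, z1] * (1 - wx) * wy * wz
        + stack[x1, y1, z1] * wx * wy * wz
    )
    return out


def _identity_coords(shape) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    return np.stack(grids, axis=-1)


def warp(vol: Volume, phi: DisplacementField, interpolation: str = "trilinear") -> Volume:
    """Resample ``vol`` at ``p + phi(p)`` (edge replication out of bounds)."""
    if vol.shape != phi.grid_shape:
        raise ValueError(f"grid mismatch: volume {vol.shape} vs field {phi.grid_shape}")
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    coords = _identity_coords(vol.shape) + phi.data
    out = _sample_stack(
        np.asarray(vol.data)[..., None], coords, nearest=interpolation == "nearest"
    )[..., 0]
    return Volume(
        data=out.astype(vol.data.dtype, copy=False),
        spacing=vol.spacing,
        origin=vol.origin,
    )


def warp_mask_soft(mask, phi: DisplacementField) -> np.ndarray:
    """Trilinearly warped binary mask as a soft [0, 1] map (for losses)."""
    data = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    soft = (np.asarray(data) > 0).astype(np.float64)
    coords = _identity_coords(soft.shape) + phi.data
    return _sample_stack(soft[..., None], coords)[..., 0]


def warp_mask(mask: LabelMask, phi: DisplacementField) -> LabelMask:
    """Nearest-neighbour warped label mask (for reported/evaluated masks)."""
    coords = _identity_coords(mask.shape) + phi.data
    out = _sample_stack(
        np.asarray(mask.data, dtype=np.float64)[..., None], coords, nearest=True
    )[..., 0]
    return LabelMask(data=out.astype(np.int16), spacing=mask.spacing, origin=mask.origin)


# ---------------------------------------------------------------------------
# Jacobian folding analysis

@dataclass
class JacobianReport:
    folding_count: int
    total_voxels: int

    @property
    def folding_fraction(self) -> float:
        return self.folding_count / self.total_voxels if self.total_voxels else 0.0

    @property
    def folding_per_ten_thousand(self) -> float:
        return self.folding_fraction * 1e4

    def to_dict(self) -> dict:
        return {
            "folding_count": self.folding_count,
            "total_voxels": self.total_voxels,
            "folding_fraction": self.folding_fraction,
            "folding_per_ten_thousand": self.folding_per_ten_thousand,
        }


def jacobian_report(phi: DisplacementField) -> JacobianReport:
    """Count interior voxels where det J of the mapping p + phi(p) < 0.

    The Jacobian uses central differences; the one-voxel boundary shell is
    excluded from the counts.
    """
    data = phi.data if isinstance(phi, DisplacementField) else np.asarray(phi)
    if min(data.shape[:3]) < 3:
        raise ValueError("field must have at least 3 voxels per axis")
    J = np.empty(data.shape[:3] + (3, 3))
    for comp in range(3):
        for axis in range(3):
            J[..., comp, axis] = np.gradient(data[..., comp], axis=axis)
        J[..., comp, comp] += 1.0
    det = np.linalg.det(J[1:-1, 1:-1, 1:-1])
    return JacobianReport(
        folding_count=int((det < 0).sum()), total_voxels=int(det.size)
    )


# ---------------------------------------------------------------------------
# multi-resolution optimizer

#: relative weight of the mean gradient norm in the demons step normaliser
FORCE_NORM_ALPHA = 1.0
#: per-voxel cap (in level-grid voxels) on the raw demons update
UPDATE_CAP = 1.0
#: default internal loss weights of the demo optimizer (heavier smoothness
#: than the loss-module default; see module docstring)
DEFAULT_REG_LOSS = RegLossConfig(lambda_sim=1.0, lambda_label=2.0, lambda_smo=20.0)


@dataclass
class RegistrationConfig:
    """Settings of the classical demo optimizer.

    ``levels`` are coarse-to-fine downsampling factors; the field returned is
    always upsampled to the input grid.  ``step`` is the initial line-search
    scale applied to the (capped, smoothed) demons update; ``field_sigma``
    is the Gaussian width smoothing each update, in full-resolution voxels
    (divided by the level factor at each pyramid level).
    """

    metric: str = "macmind"
    levels: tuple[int, ...] = (4, 2)
    iterations: tuple[int, ...] = (40, 30)
    step: float = 1.0
    field_sigma: float = 4.0
    tol: float = 1e-6
    seed: int | None = None
    descriptor: DescriptorConfig = dc_field(default_factory=DescriptorConfig)

    def __post_init__(self):
        if self.metric not in ("macmind", "mind", "ssd"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if len(self.levels) != len(self.iterations):
            raise ValueError("one iteration count per pyramid level required")
        if sorted(self.levels, reverse=True) != list(self.levels):
            raise ValueError("levels must be ordered coarse to fine")
        if min(self.iterations) < 1:
            raise ValueError("iterations must be >= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "levels": list(self.levels),
            "iterations": list(self.iterations),
            "step": self.step,
            "field_sigma": self.field_sigma,
            "tol": self.tol,
            "seed": self.seed,
            "descriptor": self.descriptor.to_dict(),
        }


def _resize(data: np.ndarray, new_shape, smooth_factors=None) -> np.ndarray:
    """Align-corners trilinear resize of a 3D array, with optional Gaussian
    pre-smoothing for downsampling (anti-aliasing)."""
    src = np.asarray(data, dtype=np.float64)
    if smooth_factors is not None:
        sig = [0.5 * f if f > 1 else 0.0 for f in smooth_factors]
        if any(s > 0 for s in sig):
            src = gaussian_filter(src, sigma=sig)
    old = np.asarray(src.shape)
    new = np.asarray(new_shape)
    axes = [
        np.linspace(0, o - 1, n) if n > 1 else np.array([0.5 * (o - 1)])
        for o, n in zip(old, new)
    ]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return _sample_stack(src[..., None], coords)[..., 0]


def _resize_field(phi_data: np.ndarray, new_shape) -> np.ndarray:
    """Resize a displacement field and rescale components to the new grid's
    voxel units."""
    old = np.asarray(phi_data.shape[:3], dtype=float)
    new = np.asarray(new_shape, dtype=float)
    scale = (new - 1) / np.maximum(old - 1, 1)
    comps = [
        _resize(phi_data[..., c], new_shape) * scale[c] for c in range(3)
    ]
    return np.stack(comps, axis=-1)


def _extract_features(vol: Volume, cfg: RegistrationConfig) -> np.ndarray:
    if cfg.metric == "macmind":
        return np.asarray(macmind(vol, cfg.descriptor).data, dtype=np.float32)
    if cfg.metric == "mind":
        d = cfg.descriptor
        return np.asarray(
            mind_descriptor(vol, d.L, d.R1, d.eps_rel).data, dtype=np.float32
        )
    # raw-intensity SSD on min-max normalized images
    x = np.asarray(vol.data, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    norm = (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
    return norm.astype(np.float32)[..., None]


def _level_losses(
    phi: np.ndarray,
    feat_fixed: np.ndarray,
    moving_img: np.ndarray,
    spacing,
    reg_cfg: RegistrationConfig,
    idcoords: np.ndarray,
    soft_fixed: np.ndarray | None,
    soft_moving: np.ndarray | None,
    loss_cfg: RegLossConfig,
) -> tuple[LossReport, np.ndarray]:
    """Loss report at ``phi`` plus the feature stack of the warped moving
    image (descriptors recomputed from the warped image; E_smo per voxel)."""
    coords = idcoords + phi
    warped_img = _sample_stack(moving_img[..., None], coords)[..., 0]
    warped = _extract_features(Volume(warped_img, spacing=spacing), reg_cfg)
    diff = warped.astype(np.float64) - feat_fixed
    e_sim = float(np.square(diff).sum(axis=-1).mean())
    nvox = float(np.prod(phi.shape[:3]))
    e_smo = smoothness_loss(phi) / nvox
    e_label = 0.0
    if soft_fixed is not None and soft_moving is not None:
        warped_lab = _sample_stack(soft_moving[..., None], coords)[..., 0]
        e_label = dice_label_loss(soft_fixed, warped_lab)
    report = LossReport(e_sim=e_sim, e_label=e_label, e_smo=e_smo, weights=loss_cfg)
    if not np.isfinite(report.e_total):
        bad = [k for k, v in report.weighted.items() if not np.isfinite(v)]
        raise FloatingPointError(
            f"non-finite registration loss; offending terms: {bad}"
        )
    return report, warped


def _demons_update(warped: np.ndarray, feat_fixed: np.ndarray, sigma: float) -> np.ndarray:
    """Capped, mean-regularised, Gaussian-smoothed descent direction."""
    diff = (warped - feat_fixed).astype(np.float32)
    grads = np.gradient(warped, axis=(0, 1, 2))
    force = np.stack(
        [np.einsum("...c,...c->...", diff, g) for g in grads], axis=-1
    ).astype(np.float64)
    gnorm = sum(np.square(g.astype(np.float64)).sum(axis=-1) for g in grads)
    u = -force / (gnorm + FORCE_NORM_ALPHA * gnorm.mean() + 1e-30)[..., None]
    mag = np.sqrt(np.square(u).sum(axis=-1))
    u *= np.minimum(1.0, UPDATE_CAP / np.maximum(mag, 1e-12))[..., None]
    return np.stack(
        [gaussian_filter(u[..., c], sigma) for c in range(3)], axis=-1
    )


def register(
    fixed: Volume,
    moving: Volume,
    cfg: RegistrationConfig | None = None,
    fixed_label: LabelMask | None = None,
    moving_label: LabelMask | None = None,
    loss_cfg: RegLossConfig | None = None,
) -> tuple[DisplacementField, pd.DataFrame]:
    """Deformable registration of ``moving`` onto ``fixed``.

    Returns the displacement field on the fixed grid (voxel units; a warp of
    the moving image samples at ``p + phi(p)``) and the per-iteration loss
    trace (columns: level, iteration, e_sim, e_label, e_smo, e_total, step,
    accepted).  ``e_smo`` in the trace is the diffusion term per voxel.  The
    accepted-step loss trace is non-increasing within each pyramid level by
    construction of the line search.  Deterministic given inputs and config.
    """
    cfg = cfg or RegistrationConfig()
    loss_cfg = loss_cfg or DEFAULT_REG_LOSS
    if fixed.shape != moving.shape:
        raise ValueError(f"grid mismatch: fixed {fixed.shape} vs moving {moving.shape}")
    full_shape = fixed.shape
    phi = None
    rows = []

    def record(level, iteration, step, report):
        rows.append(
            dict(level=level, iteration=iteration, step=step, accepted=True,
                 **{k: report.to_dict()[k] for k in
                    ("e_sim", "e_label", "e_smo", "e_total")})
        )

    for level_idx, (factor, n_iter) in enumerate(zip(cfg.levels, cfg.iterations)):
        shape_l = tuple(max(4, int(round(s / factor))) for s in full_shape)
        factors = [s / n for s, n in zip(full_shape, shape_l)]
        spacing_l = tuple(sp * f for sp, f in zip(fixed.spacing, factors))
        fix_l = Volume(
            data=_resize(fixed.data, shape_l, smooth_factors=factors),
            spacing=spacing_l, origin=fixed.origin,
        )
        mov_img = _resize(moving.data, shape_l, smooth_factors=factors)
        feat_f = _extract_features(fix_l, cfg).astype(np.float64)
        soft_f = soft_m = None
        if fixed_label is not None and moving_label is not None:
            soft_f = _resize((fixed_label.data > 0).astype(np.float64), shape_l)
            soft_m = _resize((moving_label.data > 0).astype(np.float64), shape_l)
        idcoords = _identity_coords(shape_l)
        sigma = max(1.0, cfg.field_sigma / factor)
        phi = (
            np.zeros(shape_l + (3,))
            if phi is None
            else _resize_field(phi, shape_l)
        )
        report, warped = _level_losses(
            phi, feat_f, mov_img, spacing_l, cfg, idcoords, soft_f, soft_m, loss_cfg
        )
        record(level_idx, -1, 0.0, report)
        step = cfg.step
        for it in range(n_iter):
            direction = _demons_update(warped, feat_f, sigma)
            if not np.abs(direction).any():
                break
            accepted = False
            while step >= 1e-3:
                cand = phi + step * direction
                cand_report, cand_warped = _level_losses(
                    cand, feat_f, mov_img, spacing_l, cfg, idcoords,
                    soft_f, soft_m, loss_cfg,
                )
                if cand_report.e_total <= report.e_total:
                    improvement = report.e_total - cand_report.e_total
                    phi, warped = cand, cand_warped
                    report = cand_report
                    accepted = True
                    record(level_idx, it, step, report)
                    step = min(step * 1.2, cfg.step * 2)
                    break
                step *= 0.5
            if not accepted:
                break
            if improvement <= cfg.tol * max(abs(report.e_total), 1e-12):
                break
    final = _resize_field(phi, full_shape)
    trace = pd.DataFrame(rows)
    field = DisplacementField(data=final, spacing=fixed.spacing, origin=fixed.origin)
    return field, trace
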