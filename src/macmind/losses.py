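"""Registration loss terms: descriptor similarity, smoothness, label Dice.

The registration objective is

    E_reg = lambda_sim * E_sim + lambda_label * E_label + lambda_smo * E_smo

with E_sim the mean squared macMIND channel-vector difference between the
fixed image and the warped moving image, E_label a soft-Dice loss between
the fixed and warped label masks, and E_smo a diffusion regularizer (sum of
squared forward-difference spatial gradients of the displacement field).
``lambda_sim`` defaults to 1 at the library level; the shipped default
configuration carries (20, 2, 0.5).

All functions are pure and operate on plain arrays or the core data types,
so any optimizer can drive them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import DisplacementField, LabelMask
from .descriptors import FeatureMap

__all__ = [
    "RegLossConfig",
    "LossReport",
    "sim_loss",
    "smoothness_loss",
    "dice_label_loss",
    "seg_consistency_loss",
    "total_loss",
]

DICE_EPS = 1e-6


@dataclass(frozen=True)
class RegLossConfig:
    lambda_sim: float = 1.0
    lambda_label: float = 2.0
    lambda_smo: float = 0.5

    def __post_init__(self):
        for name in ("lambda_sim", "lambda_label", "lambda_smo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class LossReport:
    """Loss decomposition; ``e_total`` is the weighted sum."""

    e_sim: float
    e_label: float
    e_smo: float
    weights: RegLossConfig

    @property
    def weighted(self) -> dict[str, float]:
        return {
            "sim": self.weights.lambda_sim * self.e_sim,
            "label": self.weights.lambda_label * self.e_label,
            "smo": self.weights.lambda_smo * self.e_smo,
        }

    @property
    def e_total(self) -> float:
        return float(sum(self.weighted.values()))

    def to_dict(self) -> dict[str, float]:
        return {
            "e_sim": self.e_sim,
            "e_label": self.e_label,
            "e_smo": self.e_smo,
            "e_total": self.e_total,
            "lambda_sim": self.weights.lambda_sim,
            "lambda_label": self.weights.lambda_label,
            "lambda_smo": self.weights.lambda_smo,
        }


def _feature_data(f) -> np.ndarray:
    return f.data if isinstance(f, FeatureMap) else np.asarray(f)


def sim_loss(feat_fixed, feat_warped) -> float:
    """Mean over voxels of the squared channel-vector difference.

    The channel difference is summed over channels and averaged over the
    voxel domain, i.e. (1/|Omega|) sum_p ||f_F(p) - f_W(p)||^2.
    """
    a = _feature_data(feat_fixed)
    b = _feature_data(feat_warped)
    if a.shape != b.shape:
        raise ValueError(f"feature grids differ: {a.shape} vs {b.shape}")
    if (
        isinstance(feat_fixed, FeatureMap)
        and isinstance(feat_warped, FeatureMap)
        and feat_fixed.channel_meta
        and feat_warped.channel_meta
        and feat_fixed.channel_meta != feat_warped.channel_meta
    ):
        raise ValueError("feature maps have mismatching channel metadata")
    diff = a.astype(np.float64) - b.astype(np.float64)
    per_voxel = np.square(diff).sum(axis=-1)
    return float(per_voxel.mean())


def smoothness_loss(phi) -> float:
    """Diffusion regularizer: sum over voxels of the squared forward-difference
    spatial gradients of all three displacement components (gradients taken
    in voxel units; zero at the far boundary)."""
    data = phi.data if isinstance(phi, DisplacementField) else np.asarray(phi)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError("expected a (x, y, z, 3) displacement array")
    total = 0.0
    for axis in range(3):
        d = np.diff(data, axis=axis)
        total += float(np.square(d).sum())
    return total


def _mask_data(m) -> np.ndarray:
    if isinstance(m, LabelMask):
        return (m.data > 0).astype(np.float64)
    return np.asarray(m, dtype=np.float64)


def dice_label_loss(mask_a, mask_b) -> float:
    """1 - soft Dice; accepts binary or soft (interpolated) masks."""
    a = _mask_data(mask_a)
    b = _mask_data(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    inter = float((a * b).sum())
    dice = (2.0 * inter + DICE_EPS) / (float(a.sum()) + float(b.sum()) + DICE_EPS)
    return 1.0 - dice


def seg_consistency_loss(
    lseg_f, lseg_m, phi: DisplacementField | None = None,
    lgt_f=None, lgt_m=None,
) -> float:
    """Segmentation consistency loss with two branches.

    With ground-truth labels for both modalities the loss is the sum of the
    two prediction-vs-ground-truth Dice losses; without ground truth it is the
    Dice loss between the fixed prediction and the warped moving prediction
    (requiring the displacement field).
    """
    if lgt_f is not None and lgt_m is not None:
        return dice_label_loss(lseg_f, lgt_f) + dice_label_loss(lseg_m, lgt_m)
    if phi is None:
        raise ValueError(
            "without ground-truth labels a displacement field is required "
            "to warp the moving prediction"
        )
    from .registration import warp_mask_soft  # local import to avoid cycle

    warped = warp_mask_soft(lseg_m, phi)
    return dice_label_loss(lseg_f, warped)


def total_loss(
    e_sim: float, e_label: float, e_smo: float, cfg: RegLossConfig | None = None
) -> LossReport:
    cfg = cfg or RegLossConfig()
    report = LossReport(e_sim=float(e_sim), e_label=float(e_label),
                        e_smo=float(e_smo), weights=cfg)
    if not np.isfinite(report.e_total):
        bad = [k for k, v in report.weighted.items() if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite loss terms: {bad}")
    return report
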