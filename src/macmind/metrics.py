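"""Evaluation panel for deformable registration and segmentation.

Registration accuracy: target registration error (TRE, mm between
corresponding landmarks), Dice similarity coefficient (DSC, %), 95th
percentile symmetric surface distance (Hd95, mm).  Whole-image quality:
mutual information (MI, nats from a joint histogram) and a global structural
similarity index (SSIM).  Segmentation agreement: absolute relative volume
difference (RVDabs, %) and volumetric overlap error (VOE, %).

MI and SSIM are reported raw (MI in nats, SSIM in [-1, 1]); any percentage
normalization applied elsewhere to these two is not standardized and is not
attempted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import DisplacementField, LabelMask, LandmarkSet, Volume, physical_to_index

logger = logging.getLogger(__name__)

__all__ = [
    "MetricPanel",
    "mutual_information",
    "ssim",
    "dsc",
    "hd95",
    "tre",
    "rvd_abs",
    "voe",
    "evaluate_panel",
]


def _vol_data(v) -> np.ndarray:
    return np.asarray(v.data if isinstance(v, Volume) else v, dtype=np.float64)


def _mask_bool(m, label: int | None = None) -> np.ndarray:
    data = np.asarray(m.data if isinstance(m, LabelMask) else m)
    if label is None:
        return data > 0
    return data == label


def mutual_information(a, b, bins: int = 32) -> float:
    """Shannon mutual information (nats) from an equal-width joint histogram
    over each image's min-max range; constant images give 0 with a warning."""
    x = _vol_data(a).ravel()
    y = _vol_data(b).ravel()
    if x.shape != y.shape:
        raise ValueError("images must share a grid")
    if x.min() == x.max() or y.min() == y.max():
        logger.warning("constant image in MI computation; returning 0")
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / outer[nz])))


def entropy(a, bins: int = 32) -> float:
    """Marginal Shannon entropy (nats) with the same binning as MI."""
    x = _vol_data(a).ravel()
    if x.min() == x.max():
        return 0.0
    hist, _ = np.histogram(x, bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _minmax01(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def ssim(
    a, b, c1: float = 0.01 ** 2, c2: float = 0.03 ** 2,
    literal_form: bool = False,
) -> float:
    """Global (whole-volume) structural similarity.

    Both images are min-max normalized to [0, 1] before computing global
    means, variances and covariance.  The default is the standard product
    form ((2*mu_a*mu_b + c1)(2*cov + c2)) / ((mu_a^2 + mu_b^2 + c1)
    (var_a + var_b + c2)).  ``literal_form=True`` replaces the numerator
    product with a sum, a printed variant kept inspectable for comparison;
    note the literal form does not attain 1 for identical images.
    """
    x = _minmax01(_vol_data(a)).ravel()
    y = _minmax01(_vol_data(b)).ravel()
    if x.shape != y.shape:
        raise ValueError("images must share a grid")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = float(((x - mx) * (y - my)).mean())
    if literal_form:
        num = (2 * mx * my + c1) + (2 * cov + c2)
    else:
        num = (2 * mx * my + c1) * (2 * cov + c2)
    den = (mx ** 2 + my ** 2 + c1) * (vx + vy + c2)
    return float(num / den)


def dsc(a, b, label: int | None = None, strict: bool = False) -> float:
    """Dice similarity coefficient in percent: 100 * 2|A^B| / (|A|+|B|)."""
    ma = _mask_bool(a, label)
    mb = _mask_bool(b, label)
    if ma.shape != mb.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(ma.sum()), int(mb.sum())
    if na == 0 and nb == 0:
        if strict:
            raise ValueError(f"label {label} absent from both masks")
        logger.warning("both masks empty in DSC; returning 100")
        return 100.0
    return 100.0 * 2.0 * int((ma & mb).sum()) / (na + nb)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one background 6-neighbour."""
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def hd95(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of pooled symmetric surface-to-surface distances (mm).

    Surfaces are 6-connectivity boundaries; distances come from the exact
    Euclidean distance transform scaled by the voxel spacing; the percentile
    uses linear interpolation on the pooled distances.
    """
    ma = _mask_bool(a)
    mb = _mask_bool(b)
    if ma.shape != mb.shape:
        raise ValueError("masks must share a grid")
    if not ma.any() or not mb.any():
        raise ValueError("hd95 requires both masks non-empty")
    sa = _surface(ma)
    sb = _surface(mb)
    spacing = tuple(float(s) for s in spacing)
    dt_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    pooled = np.concatenate([dt_b[sa], dt_a[sb]])
    return float(np.percentile(pooled, 95))


def _interp_field(phi: DisplacementField, voxel_pos: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the field at one fractional voxel position."""
    shape = np.asarray(phi.grid_shape)
    p = np.clip(np.asarray(voxel_pos, dtype=np.float64), 0, shape - 1)
    p0 = np.floor(p).astype(int)
    p0 = np.minimum(p0, shape - 2) if (shape > 1).all() else p0
    p0 = np.maximum(p0, 0)
    w = p - p0
    out = np.zeros(3)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wt = (
                    (w[0] if dx else 1 - w[0])
                    * (w[1] if dy else 1 - w[1])
                    * (w[2] if dz else 1 - w[2])
                )
                if wt == 0.0:
                    continue
                idx = np.minimum(p0 + [dx, dy, dz], shape - 1)
                out += wt * phi.data[idx[0], idx[1], idx[2], :]
    return out


def tre(
    fixed_lms: LandmarkSet,
    moving_lms: LandmarkSet,
    phi: DisplacementField | None = None,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Per-landmark target registration error in mm.

    Each fixed-frame landmark is mapped through the field (interpolated
    trilinearly at its voxel position, displacement converted from voxel
    units to mm) and compared with its corresponding moving-frame landmark.
    With ``phi=None`` the field is taken as zero, giving the unregistered
    baseline.  Landmarks are matched by id; the result follows the order of
    ``fixed_lms.ids``.
    """
    pf, pm = fixed_lms.aligned_points(moving_lms)
    spacing = np.asarray(spacing, dtype=np.float64)
    out = np.empty(len(pf))
    for k, (xf, xm) in enumerate(zip(pf, pm)):
        if phi is None:
            mapped = xf
        else:
            v = physical_to_index(xf, phi.spacing, phi.origin)
            if ((v < -0.5) | (v > np.asarray(phi.grid_shape) - 0.5)).any():
                raise ValueError(
                    f"landmark {fixed_lms.ids[k]} at voxel {v} lies outside "
                    f"the field domain {phi.grid_shape}"
                )
            d_vox = _interp_field(phi, v)
            mapped = xf + d_vox * np.asarray(phi.spacing)
        out[k] = float(np.linalg.norm(mapped - xm))
    return out


def rvd_abs(seg, gt) -> float:
    """Absolute relative volume difference in percent: |V_seg/V_gt - 1|*100."""
    vs = int(_mask_bool(seg).sum())
    vg = int(_mask_bool(gt).sum())
    if vg == 0:
        raise ValueError("rvd_abs requires a non-empty ground-truth mask")
    return abs(vs / vg - 1.0) * 100.0


def voe(a, b) -> float:
    """Volumetric overlap error in percent: (1 - |A^B| / |AvB|) * 100."""
    ma = _mask_bool(a)
    mb = _mask_bool(b)
    if ma.shape != mb.shape:
        raise ValueError("masks must share a grid")
    union = int((ma | mb).sum())
    if union == 0:
        raise ValueError("voe requires at least one non-empty mask")
    inter = int((ma & mb).sum())
    return (1.0 - inter / union) * 100.0


@dataclass
class MetricPanel:
    """The full evaluation panel; missing inputs leave entries at None."""

    tre_mm: dict[str, float] | None = None
    tre_mean_mm: float | None = None
    dsc_percent: float | None = None
    hd95_mm: float | None = None
    mi: float | None = None
    ssim: float | None = None
    rvd_abs_percent: float | None = None
    voe_percent: float | None = None

    def to_dict(self) -> dict:
        return {
            "tre_mm": self.tre_mm,
            "tre_mean_mm": self.tre_mean_mm,
            "dsc_percent": self.dsc_percent,
            "hd95_mm": self.hd95_mm,
            "mi": self.mi,
            "ssim": self.ssim,
            "rvd_abs_percent": self.rvd_abs_percent,
            "voe_percent": self.voe_percent,
        }


def evaluate_panel(
    fixed: Volume,
    warped: Volume,
    fixed_label: LabelMask | None = None,
    warped_label: LabelMask | None = None,
    fixed_lms: LandmarkSet | None = None,
    moving_lms: LandmarkSet | None = None,
    phi: DisplacementField | None = None,
    mi_bins: int = 32,
) -> MetricPanel:
    """Compute every metric the provided inputs allow."""
    panel = MetricPanel(
        mi=mutual_information(fixed, warped, bins=mi_bins),
        ssim=ssim(fixed, warped),
    )
    if fixed_label is not None and warped_label is not None:
        panel.dsc_percent = dsc(fixed_label, warped_label)
        if _mask_bool(fixed_label).any() and _mask_bool(warped_label).any():
            panel.hd95_mm = hd95(fixed_label, warped_label, fixed.spacing)
        panel.rvd_abs_percent = rvd_abs(warped_label, fixed_label)
        panel.voe_percent = voe(fixed_label, warped_label)
    if fixed_lms is not None and moving_lms is not None:
        errs = tre(fixed_lms, moving_lms, phi, fixed.spacing, fixed.origin)
        panel.tre_mm = dict(zip(fixed_lms.ids, (float(e) for e in errs)))
        panel.tre_mean_mm = float(errs.mean())
    return panel
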