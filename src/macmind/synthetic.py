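"""Synthetic multimodal phantom cases with ground truth.

Each case contains one shared anatomy — a lobulated ellipsoidal "organ" with
an interior ellipsoidal "lesion" and a few background structures — rendered
under two modality-specific intensity mappings:

* modality A ("CT-like"): per-class intensity plus a shared smooth texture,
  additive Gaussian noise;
* modality B ("MR-like"): a different per-class monotone mapping with the
  organ/lesion contrast inverted (lesion brighter than organ in B, darker in
  A; within the lesion the texture slope is also inverted), Rician-like
  noise (magnitude of a complex Gaussian), rendered in a deformed frame via
  a known smooth displacement field.

The ground-truth field, per-modality labels and corresponding landmark sets
make every registration and metric component testable without any data
download.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_io import (
    DisplacementField,
    LabelMask,
    LandmarkSet,
    Volume,
    index_to_physical,
    read_displacement_field,
    read_label,
    read_landmarks,
    read_volume,
    write_displacement_field,
    write_label,
    write_landmarks,
    write_volume,
)
from .registration import _sample_stack, jacobian_report

logger = logging.getLogger(__name__)

__all__ = ["PhantomConfig", "PhantomCase", "generate_deformation",
           "generate_phantom", "write_phantom", "read_phantom"]

# per-tissue-class intensity models: class -> (mean, texture slope)
#  classes: 0 background, 1 organ, 2 lesion, 3..5 background structures
_MODALITY_A = {
    0: (0.05, 0.015),
    1: (0.60, 0.060),
    2: (0.30, 0.050),
    3: (0.85, 0.040),
    4: (0.45, 0.040),
    5: (0.70, 0.040),
}
_MODALITY_B = {
    0: (0.10, 0.020),
    1: (0.35, 0.070),
    2: (0.80, -0.060),  # inverted contrast and inverted texture slope
    3: (0.50, 0.050),
    4: (0.90, 0.045),
    5: (0.25, 0.050),
}


@dataclass(frozen=True)
class PhantomConfig:
    size: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    amplitude: float = 4.0  # max displacement, voxels
    smoothness: float = 6.0  # Gaussian sigma of the deformation, voxels
    noise_a: float = 0.02  # Gaussian noise sd, fraction of dynamic range
    noise_b: float = 0.04  # Rician sigma, fraction of dynamic range
    n_landmarks: int = 8
    strict: bool = False

    def __post_init__(self):
        if min(self.size) < 16:
            raise ValueError("each axis must be >= 16 voxels")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be > 0")
        if self.n_landmarks < 1:
            raise ValueError("need at least one landmark")
        object.__setattr__(self, "size", tuple(int(s) for s in self.size))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    def to_dict(self) -> dict:
        return {
            "size": list(self.size),
            "spacing": list(self.spacing),
            "seed": self.seed,
            "amplitude": self.amplitude,
            "smoothness": self.smoothness,
            "noise_a": self.noise_a,
            "noise_b": self.noise_b,
            "n_landmarks": self.n_landmarks,
            "strict": self.strict,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for key in ("size", "spacing"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomCase:
    vol_a: Volume
    vol_b: Volume
    label_organ_a: LabelMask
    label_lesion_a: LabelMask
    label_organ_b: LabelMask
    label_lesion_b: LabelMask
    phi_true: DisplacementField  # b-frame -> a-frame, voxel units
    landmarks_a: LandmarkSet
    landmarks_b: LandmarkSet
    config: PhantomConfig


def _taper(shape, width: int = 4) -> np.ndarray:
    """Cosine attenuation to zero over ``width`` voxels at every face.

    The caller scales ``width`` with the displacement amplitude: a cosine
    ramp carrying a peak displacement ``a`` over ``w`` voxels has gradient up
    to ``pi * a / (2 w)``, so ``w >= 2 a`` keeps the taper itself fold-free.
    """
    w = np.ones(shape)
    for axis, s in enumerate(shape):
        d = np.minimum(np.arange(s), np.arange(s)[::-1]).astype(float)
        t = np.where(d >= width, 1.0, 0.5 * (1 - np.cos(np.pi * d / width)))
        sl = [None] * len(shape)
        sl[axis] = slice(None)
        w = w * t[tuple(sl)]
    return w


def generate_deformation(cfg: PhantomConfig) -> DisplacementField:
    """Smooth random displacement field: i.i.d. Gaussian noise per component,
    Gaussian-smoothed, rescaled to the requested peak magnitude, attenuated
    to zero near the boundary.  Guaranteed fold-free (rescaled with a warning
    if needed; error in strict mode)."""
    rng = np.random.default_rng(cfg.seed)
    data = rng.normal(size=cfg.size + (3,))
    if cfg.amplitude == 0:
        return DisplacementField(
            data=np.zeros(cfg.size + (3,)), spacing=cfg.spacing
        )
    for c in range(3):
        data[..., c] = gaussian_filter(data[..., c], cfg.smoothness)
    width = max(4, int(np.ceil(2.0 * cfg.amplitude)))
    data *= _taper(cfg.size, width)[..., None]
    mag = np.sqrt(np.square(data).sum(axis=-1)).max()
    data *= cfg.amplitude / mag
    for attempt in range(8):
        rep = jacobian_report(DisplacementField(data=data, spacing=cfg.spacing))
        if rep.folding_count == 0:
            break
        if cfg.strict:
            raise ValueError(
                f"deformation folds ({rep.folding_count} voxels) at amplitude "
                f"{cfg.amplitude} / smoothness {cfg.smoothness}"
            )
        logger.warning(
            "deformation folds (%d voxels); halving amplitude", rep.folding_count
        )
        data *= 0.5
    return DisplacementField(data=data, spacing=cfg.spacing)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    rho2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return rho2 <= 1.0


def _lobulated_organ(shape, center, radii, rng) -> np.ndarray:
    """Ellipsoid whose boundary radius is modulated by low-order angular
    harmonics (a lobulated, liver-like outline)."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    v = [(g - c) / r for g, c, r in zip(grids, center, radii)]
    rho = np.sqrt(sum(x ** 2 for x in v)) + 1e-12
    az = np.arctan2(v[1], v[0])
    pol = np.arccos(np.clip(v[2] / rho, -1, 1))
    coeff = rng.uniform(-1, 1, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    pert = (
        1.0
        + 0.07 * coeff[0] * np.cos(2 * az + phase[0]) * np.sin(pol) ** 2
        + 0.05 * coeff[1] * np.cos(3 * az + phase[1]) * np.sin(pol) ** 3
        + 0.05 * coeff[2] * np.cos(2 * pol + phase[2])
    )
    return rho <= pert


def _tissue_classes(cfg: PhantomConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Integer class volume and the lesion centre (voxel coordinates)."""
    shape = np.asarray(cfg.size)
    classes = np.zeros(cfg.size, dtype=np.int16)
    center = shape / 2.0 + rng.uniform(-1.5, 1.5, size=3)
    organ_radii = shape * np.array([0.32, 0.28, 0.30])
    organ = _lobulated_organ(cfg.size, center, organ_radii, rng)

    lesion_radii = shape * rng.uniform(0.08, 0.12, size=3)
    for shrink in (1.0, 0.7, 0.45, 0.0):
        offset = rng.uniform(-0.25, 0.25, size=3) * organ_radii * shrink
        lesion_center = center + offset
        lesion = _ellipsoid(cfg.size, lesion_center, lesion_radii)
        if lesion.any() and (lesion <= organ).all():
            break
    else:
        raise ValueError("lesion does not fit inside organ at requested size")

    # background structures: a spine-like rod plus two small ellipsoids
    rod_center = np.array([shape[0] * 0.5, shape[1] * 0.12, shape[2] * 0.5])
    rod = _ellipsoid(cfg.size, rod_center, np.array([shape[0] * 0.06, shape[1] * 0.06, shape[2] * 0.45]))
    blob1 = _ellipsoid(
        cfg.size,
        np.array([shape[0] * 0.15, shape[1] * 0.78, shape[2] * 0.40]),
        shape * np.array([0.07, 0.08, 0.10]),
    )
    blob2 = _ellipsoid(
        cfg.size,
        np.array([shape[0] * 0.85, shape[1] * 0.75, shape[2] * 0.60]),
        shape * np.array([0.06, 0.07, 0.09]),
    )
    classes[organ] = 1
    classes[lesion] = 2
    for cls, m in ((3, rod), (4, blob1), (5, blob2)):
        classes[m & (classes == 0)] = cls
    return classes, lesion_center


def _render(classes: np.ndarray, texture: np.ndarray, model: dict) -> np.ndarray:
    out = np.zeros(classes.shape, dtype=np.float64)
    for cls, (mean, slope) in model.items():
        m = classes == cls
        out[m] = mean + slope * texture[m]
    return out


def _surface_extremes(mask: np.ndarray) -> list[np.ndarray]:
    """Extremal organ-boundary voxels along +/-x, +/-y, +/-z."""
    idx = np.argwhere(mask)
    out = []
    for axis in range(3):
        for pick in (np.argmax, np.argmin):
            out.append(idx[pick(idx[:, axis])].astype(float))
    return out


def _invert_field_at(phi: DisplacementField, point_vox: np.ndarray) -> np.ndarray:
    """Solve x_b + phi(x_b) = x_a for x_b by fixed-point iteration."""
    x_a = np.asarray(point_vox, dtype=np.float64)
    x_b = x_a.copy()
    for _ in range(100):
        d = _sample_stack(phi.data, x_b[None, :])[0]
        new = x_a - d
        if np.abs(new - x_b).max() < 1e-12:
            x_b = new
            break
        x_b = new
    return x_b


def generate_phantom(cfg: PhantomConfig | None = None) -> PhantomCase:
    """Generate one deterministic multimodal phantom case."""
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    classes, lesion_center = _tissue_classes(cfg, rng)
    texture = gaussian_filter(rng.normal(size=cfg.size), 3.0)
    texture /= max(texture.std(), 1e-12)

    clean_a = _render(classes, texture, _MODALITY_A)
    clean_b = _render(classes, texture, _MODALITY_B)

    vol_a = Volume(
        data=clean_a + rng.normal(0, cfg.noise_a, size=cfg.size),
        spacing=cfg.spacing,
    )

    phi = generate_deformation(cfg)
    coords = (
        np.stack(
            np.meshgrid(*[np.arange(s, dtype=np.float64) for s in cfg.size],
                        indexing="ij"),
            axis=-1,
        )
        + phi.data
    )
    warped_b = _sample_stack(clean_b[..., None], coords)[..., 0]
    n_re = rng.normal(0, cfg.noise_b, size=cfg.size)
    n_im = rng.normal(0, cfg.noise_b, size=cfg.size)
    vol_b = Volume(
        data=np.sqrt((warped_b + n_re) ** 2 + n_im ** 2),
        spacing=cfg.spacing,
    )

    organ_a = (classes == 1) | (classes == 2)
    lesion_a = classes == 2
    organ_b = _sample_stack(organ_a.astype(np.float64)[..., None], coords)[..., 0] >= 0.5
    lesion_b = _sample_stack(lesion_a.astype(np.float64)[..., None], coords)[..., 0] >= 0.5

    pts_a_vox = [lesion_center, np.argwhere(organ_a).mean(axis=0)]
    pts_a_vox += _surface_extremes(organ_a)
    while len(pts_a_vox) < cfg.n_landmarks:
        # extra boundary points along random directions from the centroid
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        centroid = pts_a_vox[1]
        t_hit = 0.0
        for t in np.linspace(0, max(cfg.size), 200):
            p = centroid + t * d
            if (p < 0).any() or (p >= np.asarray(cfg.size)).any():
                break
            if organ_a[tuple(np.round(p).astype(int))]:
                t_hit = t
        pts_a_vox.append(centroid + t_hit * d)
    pts_a_vox = pts_a_vox[: cfg.n_landmarks]
    ids = [f"lm{i:02d}" for i in range(len(pts_a_vox))]
    pts_a_mm = np.array(
        [index_to_physical(p, cfg.spacing) for p in pts_a_vox]
    )
    pts_b_vox = [_invert_field_at(phi, p) for p in pts_a_vox]
    pts_b_mm = np.array(
        [index_to_physical(p, cfg.spacing) for p in pts_b_vox]
    )

    return PhantomCase(
        vol_a=vol_a,
        vol_b=vol_b,
        label_organ_a=LabelMask(data=organ_a.astype(np.int16), spacing=cfg.spacing),
        label_lesion_a=LabelMask(data=lesion_a.astype(np.int16), spacing=cfg.spacing),
        label_organ_b=LabelMask(data=organ_b.astype(np.int16), spacing=cfg.spacing),
        label_lesion_b=LabelMask(data=lesion_b.astype(np.int16), spacing=cfg.spacing),
        phi_true=phi,
        landmarks_a=LandmarkSet(ids=ids, points=pts_a_mm),
        landmarks_b=LandmarkSet(ids=list(ids), points=pts_b_mm),
        config=cfg,
    )


_FILES = {
    "vol_a": "vol_a.nii.gz",
    "vol_b": "vol_b.nii.gz",
    "label_organ_a": "label_organ_a.nii.gz",
    "label_lesion_a": "label_lesion_a.nii.gz",
    "label_organ_b": "label_organ_b.nii.gz",
    "label_lesion_b": "label_lesion_b.nii.gz",
    "phi_true": "phi_true.nii.gz",
    "landmarks_a": "landmarks_a.csv",
    "landmarks_b": "landmarks_b.csv",
}


def write_phantom(case: PhantomCase, out_dir) -> None:
    """Write all nine case components plus a regeneration manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(case.vol_a, out / _FILES["vol_a"])
    write_volume(case.vol_b, out / _FILES["vol_b"])
    write_label(case.label_organ_a, out / _FILES["label_organ_a"])
    write_label(case.label_lesion_a, out / _FILES["label_lesion_a"])
    write_label(case.label_organ_b, out / _FILES["label_organ_b"])
    write_label(case.label_lesion_b, out / _FILES["label_lesion_b"])
    write_displacement_field(case.phi_true, out / _FILES["phi_true"])
    write_landmarks(case.landmarks_a, out / _FILES["landmarks_a"])
    write_landmarks(case.landmarks_b, out / _FILES["landmarks_b"])
    manifest = {"generator": "macmind.synthetic", "config": case.config.to_dict()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_phantom(case_dir) -> PhantomCase:
    """Load a written phantom case back from disk."""
    d = Path(case_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg = PhantomConfig.from_dict(manifest["config"])
    return PhantomCase(
        vol_a=read_volume(d / _FILES["vol_a"]),
        vol_b=read_volume(d / _FILES["vol_b"]),
        label_organ_a=read_label(d / _FILES["label_organ_a"]),
        label_lesion_a=read_label(d / _FILES["label_lesion_a"]),
        label_organ_b=read_label(d / _FILES["label_organ_b"]),
        label_lesion_b=read_label(d / _FILES["label_lesion_b"]),
        phi_true=read_displacement_field(d / _FILES["phi_true"]),
        landmarks_a=read_landmarks(d / _FILES["landmarks_a"]),
        landmarks_b=read_landmarks(d / _FILES["landmarks_b"]),
        config=cfg,
    )
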