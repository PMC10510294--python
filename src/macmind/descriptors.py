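"""Modality-independent neighborhood descriptors: MIND, SSC, msSSC, macMIND.

All descriptors are built from the same primitive: the mean squared
difference (patch SSD) between two small patches displaced from the voxel
under consideration, turned into a similarity in (0, 1] by a normalized
exponential.  MIND uses the 6 centre-to-neighbour patch pairs; the
self-similarity context (SSC) uses all 18 non-collinear pairwise connections
among the centre patch and its 6-neighbourhood (9 undirected orientations);
msSSC is a weighted sum of SSC maps over K neighbourhood scales; macMIND
finally average-pools the msSSC map over N cylindrical log-polar bins in an
R2-wide supporting window, giving an M x N-channel feature map per voxel.

Because every channel is a ratio of local patch SSDs, the descriptors are
exactly invariant to positive affine intensity rescaling (I -> a*I + b,
a > 0), which is what makes them usable across imaging modalities.

The implementations here are the fast shift-and-convolve path; the
per-voxel loop reference implementations used as oracles live in
:mod:`macmind.reference`.  Both paths use a single edge-replication padding
of the input (pad width = patch radius + largest offset), so they agree at
every voxel including borders.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy.ndimage import uniform_filter

from .core_io import Volume, _affine_from

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorConfig",
    "ConnectionLayout",
    "FeatureMap",
    "BinAssignment",
    "build_connection_layout",
    "mind_sublayout",
    "patch_ssd_map",
    "mind_descriptor",
    "ssc_feature_map",
    "msssc",
    "build_bin_assignment",
    "aggregate_macmind",
    "macmind",
]

#: absolute lower bound for any SSD-normalising denominator
ABS_FLOOR = 1e-12

# fixed neighbour order: +x, -x, +y, -y, +z, -z (offset index 1..6; 0 = centre)
_NEIGHBOR_DIRS = np.array(
    [
        [1, 0, 0],
        [-1, 0, 0],
        [0, 1, 0],
        [0, -1, 0],
        [0, 0, 1],
        [0, 0, -1],
    ],
    dtype=int,
)


@dataclass(frozen=True)
class DescriptorConfig:
    """Configuration of the descriptor family.

    Parameters
    ----------
    L : base neighbourhood distance in voxels (scale k samples at k*L).
    R1 : edge length (odd) of the patches whose SSD is compared.
    R2 : edge length (odd) of the log-polar aggregation window.
    K : number of neighbourhood scales in msSSC.
    alphas : per-scale weights; normalised to sum to 1 on construction.
    Na, Nr, Nh : angular / radial / height bin counts of the aggregation
        (N = Na * Nr * Nh macMIND bins).
    eps_rel : relative floor for the SSD-normalising denominator, as a
        fraction of the volume-wide mean denominator.
    """

    L: int = 2
    R1: int = 5
    R2: int = 5
    K: int = 2
    alphas: tuple[float, ...] = (0.7, 0.3)
    Na: int = 8
    Nr: int = 2
    Nh: int = 2
    eps_rel: float = 1e-6

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        for name in ("R1", "R2"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {v}")
        if min(self.Na, self.Nr, self.Nh) < 1:
            raise ValueError("Na, Nr, Nh must all be >= 1")
        alphas = np.asarray(self.alphas, dtype=float)
        if alphas.shape != (self.K,):
            raise ValueError(f"need {self.K} alphas, got {alphas.shape}")
        if (alphas < 0).any() or alphas.sum() <= 0:
            raise ValueError("alphas must be non-negative with positive sum")
        object.__setattr__(
            self, "alphas", tuple(float(a) for a in alphas / alphas.sum())
        )

    @property
    def n_bins(self) -> int:
        return self.Na * self.Nr * self.Nh

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "R1": self.R1,
            "R2": self.R2,
            "K": self.K,
            "alphas": list(self.alphas),
            "Na": self.Na,
            "Nr": self.Nr,
            "Nh": self.Nh,
            "eps_rel": self.eps_rel,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorConfig":
        d = dict(d)
        if "alphas" in d:
            d["alphas"] = tuple(d["alphas"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DescriptorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = raw.get("descriptor", raw)
        known = {k: raw[k] for k in cls.__dataclass_fields__ if k in raw}
        return cls.from_dict(known)


def _canonical_direction(vec: np.ndarray) -> tuple[int, int, int]:
    """Undirected orientation class of an integer direction vector."""
    v = np.asarray(vec, dtype=int)
    g = math.gcd(math.gcd(abs(int(v[0])), abs(int(v[1]))), abs(int(v[2])))
    if g == 0:
        raise ValueError("zero direction vector")
    v = v // g
    for c in v:
        if c != 0:
            if c < 0:
                v = -v
            break
    return tuple(int(c) for c in v)


@dataclass(frozen=True)
class ConnectionLayout:
    """Patch-pair sampling pattern of one SSC scale.

    7 patch centres (the voxel itself and its 6 axis neighbours at distance
    ``scale * L``); all pairwise connections except the 3 collinear
    opposite-neighbour pairs, giving 18 pairs in 9 orientation classes.
    """

    scale: int
    distance: int  # scale * L, voxels
    offsets: np.ndarray  # (7, 3) int
    pairs: tuple[tuple[int, int], ...]
    orientation_class: tuple[tuple[int, int, int], ...]  # per pair

    @property
    def e_p(self) -> int:
        return len(self.pairs)

    @property
    def n_orientations(self) -> int:
        return len(set(self.orientation_class))

    @property
    def max_offset(self) -> int:
        return int(np.abs(self.offsets).max())


def build_connection_layout(scale: int, L: int) -> ConnectionLayout:
    """Enumerate the SSC patch pairs at neighbourhood distance ``scale * L``."""
    if scale < 1 or L < 1:
        raise ValueError("scale and L must be >= 1")
    d = scale * L
    offsets = np.vstack([[0, 0, 0], _NEIGHBOR_DIRS * d])
    pairs = []
    for i in range(7):
        for j in range(i + 1, 7):
            diff = offsets[j] - offsets[i]
            # exclude the 3 collinear opposite-neighbour pairs (+a, -a)
            if i >= 1 and np.array_equal(offsets[j], -offsets[i]):
                continue
            pairs.append(((i, j), _canonical_direction(diff)))
    # frozen channel order: by (orientation class, offset index pair)
    pairs.sort(key=lambda t: (t[1], t[0]))
    return ConnectionLayout(
        scale=scale,
        distance=d,
        offsets=offsets,
        pairs=tuple(p for p, _ in pairs),
        orientation_class=tuple(c for _, c in pairs),
    )


def mind_sublayout(layout: ConnectionLayout) -> ConnectionLayout:
    """The centre-to-neighbour sub-layout (6 pairs, 3 orientations) of MIND."""
    keep = [(p, c) for p, c in zip(layout.pairs, layout.orientation_class) if p[0] == 0]
    return ConnectionLayout(
        scale=layout.scale,
        distance=layout.distance,
        offsets=layout.offsets,
        pairs=tuple(p for p, _ in keep),
        orientation_class=tuple(c for _, c in keep),
    )


@dataclass
class FeatureMap:
    """Per-voxel channel vectors aligned to a volume grid."""

    data: np.ndarray  # (X, Y, Z, C)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel_meta: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("feature map must be 4D (x, y, z, channel)")
        if self.channel_meta and len(self.channel_meta) != self.data.shape[-1]:
            raise ValueError("one channel_meta entry per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def save(self, path) -> None:
        """Write as 4D NIfTI plus a JSON sidecar with the channel metadata."""
        path = Path(path)
        img = nib.Nifti1Image(
            np.asarray(self.data, dtype=np.float32),
            _affine_from(self.spacing, self.origin),
        )
        nib.save(img, str(path))
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
        sidecar = sidecar.parent / (sidecar.name + ".channels.json")
        sidecar.write_text(json.dumps(self.channel_meta, indent=1) + "\n")


# ---------------------------------------------------------------------------
# patch SSD primitive

def _padded(data: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(data, pad, mode="edge")


def _shifted_window(padded: np.ndarray, offset, pad: int, shape, margin: int) -> np.ndarray:
    """View of the padded array: element [u] = padded[u - margin + pad + offset]."""
    slices = tuple(
        slice(pad + int(o) - margin, pad + int(o) - margin + s + 2 * margin)
        for o, s in zip(offset, shape)
    )
    return padded[slices]


def _pair_ssd(padded: np.ndarray, oi, oj, pad: int, shape, r: int) -> np.ndarray:
    """Mean squared patch difference map for one offset pair (float64)."""
    a = _shifted_window(padded, oi, pad, shape, r)
    b = _shifted_window(padded, oj, pad, shape, r)
    sq = np.square(a.astype(np.float64) - b.astype(np.float64))
    m = uniform_filter(sq, size=2 * r + 1)
    core = tuple(slice(r, r + s) for s in shape)
    return m[core]


def patch_ssd_map(vol: Volume, offset_pair, R1: int) -> np.ndarray:
    """Map of mean squared differences between the R1^3 patches at
    ``p + offset_i`` and ``p + offset_j`` for every voxel p."""
    if R1 < 1 or R1 % 2 == 0:
        raise ValueError(f"R1 must be odd, got {R1}")
    oi, oj = (np.asarray(o, dtype=int) for o in offset_pair)
    r = R1 // 2
    pad = r + int(max(np.abs(oi).max(), np.abs(oj).max()))
    padded = _padded(np.asarray(vol.data, dtype=np.float64), pad)
    return _pair_ssd(padded, oi, oj, pad, vol.shape, r)


def _floored(denom: np.ndarray, eps_rel: float) -> np.ndarray:
    floor = max(eps_rel * float(denom.mean()), ABS_FLOOR)
    return np.maximum(denom, floor)


# ---------------------------------------------------------------------------
# MIND

def mind_descriptor(vol: Volume, L: int = 2, R1: int = 5, eps_rel: float = 1e-6) -> FeatureMap:
    """Classic 6-channel MIND: exp(-D_n / V) with V the mean of the six
    centre-to-neighbour patch distances D_n, V floored on flat regions."""
    shape = vol.shape
    if min(shape) < L + R1 // 2 + 1:
        raise ValueError(
            f"image {shape} smaller than the MIND footprint; each axis must "
            f"be >= {L + R1 // 2 + 1}"
        )
    r = R1 // 2
    pad = r + L
    padded = _padded(np.asarray(vol.data, dtype=np.float64), pad)
    center = np.zeros(3, dtype=int)
    dists = np.stack(
        [_pair_ssd(padded, center, d * L, pad, shape, r) for d in _NEIGHBOR_DIRS],
        axis=-1,
    )
    v = _floored(dists.mean(axis=-1), eps_rel)
    data = np.exp(-dists / v[..., None])
    meta = [
        {"descriptor": "MIND", "L": L, "R1": R1, "neighbor": d.tolist()}
        for d in _NEIGHBOR_DIRS
    ]
    return FeatureMap(
        data=data.astype(np.float32),
        spacing=vol.spacing,
        origin=vol.origin,
        channel_meta=meta,
    )


# ---------------------------------------------------------------------------
# SSC / msSSC

def _ssc_ssd_stack(vol_data: np.ndarray, layout: ConnectionLayout, R1: int) -> np.ndarray:
    shape = vol_data.shape
    r = R1 // 2
    pad = r + layout.max_offset
    padded = _padded(np.asarray(vol_data, dtype=np.float64), pad)
    return np.stack(
        [
            _pair_ssd(padded, layout.offsets[i], layout.offsets[j], pad, shape, r)
            for i, j in layout.pairs
        ],
        axis=-1,
    )


def ssc_feature_map(
    vol: Volume, layout: ConnectionLayout, R1: int = 5, eps_rel: float = 1e-6
) -> FeatureMap:
    """Self-similarity context: one channel per patch pair,
    exp(-e_P * SSD_ij / sum_pairs SSD) = exp(-SSD_ij / mean SSD)."""
    ssd = _ssc_ssd_stack(vol.data, layout, R1)
    denom = _floored(ssd.mean(axis=-1), eps_rel)
    data = np.exp(-ssd / denom[..., None])
    meta = [
        {
            "descriptor": "SSC",
            "scale": layout.scale,
            "pair": list(p),
            "orientation": list(c),
            "R1": R1,
        }
        for p, c in zip(layout.pairs, layout.orientation_class)
    ]
    return FeatureMap(
        data=data.astype(np.float32),
        spacing=vol.spacing,
        origin=vol.origin,
        channel_meta=meta,
    )


def msssc(vol: Volume, cfg: DescriptorConfig) -> FeatureMap:
    """Multi-scale SSC: channel-wise weighted sum over K scale layouts,
    channels aligned by pair identity across scales (M stays 18)."""
    shape = vol.shape
    min_ax = cfg.K * cfg.L + cfg.R1 // 2 + 1
    if min(shape) < min_ax:
        raise ValueError(
            f"image {shape} smaller than the msSSC footprint; each axis must "
            f"be >= {min_ax}"
        )
    acc = None
    meta = None
    for k in range(1, cfg.K + 1):
        layout = build_connection_layout(k, cfg.L)
        ssd = _ssc_ssd_stack(vol.data, layout, cfg.R1)
        denom = _floored(ssd.mean(axis=-1), cfg.eps_rel)
        ssc = np.exp(-ssd / denom[..., None])
        w = cfg.alphas[k - 1]
        acc = w * ssc if acc is None else acc + w * ssc
        if meta is None:
            meta = [
                {
                    "descriptor": "msSSC",
                    "pair": list(p),
                    "orientation": list(c),
                    "K": cfg.K,
                    "alphas": list(cfg.alphas),
                    "L": cfg.L,
                    "R1": cfg.R1,
                }
                for p, c in zip(layout.pairs, layout.orientation_class)
            ]
    return FeatureMap(
        data=acc.astype(np.float32),
        spacing=vol.spacing,
        origin=vol.origin,
        channel_meta=meta,
    )


# ---------------------------------------------------------------------------
# log-polar bin assignment and aggregation

#: geometric ratio between successive radial shell edges
RADIAL_RATIO = math.sqrt(2.0)


@dataclass
class BinAssignment:
    """Partition of the R2-wide aggregation window into cylindrical
    log-polar bins (azimuth sectors x log-radial shells x height slabs).

    Offsets whose in-plane radius exceeds R2/2 fall outside the inscribed
    cylinder and are unassigned.  The r=0 column sits in the innermost shell
    of azimuth sector 0 (documented tie-break).
    """

    R2: int
    Na: int
    Nr: int
    Nh: int
    two_d: bool
    bin_of_offset: dict  # (dx, dy, dz) -> bin index
    offsets_by_bin: list  # per bin, list of (dx, dy, dz)

    @property
    def n_bins(self) -> int:
        return self.Na * self.Nr * self.Nh

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(o) for o in self.offsets_by_bin], dtype=int)

    @property
    def n_assigned(self) -> int:
        return len(self.bin_of_offset)

    @property
    def empty_bins(self) -> list[int]:
        return [n for n, offs in enumerate(self.offsets_by_bin) if not offs]

    def kernels(self) -> np.ndarray:
        """The averaging convolution kernels, one R2^3 (or R2^2x1) array per
        bin; each sums to 1 over its bin, or is all-zero for an empty bin."""
        nz = 1 if self.two_d else self.R2
        h = self.R2 // 2
        hz = 0 if self.two_d else h
        out = np.zeros((self.n_bins, self.R2, self.R2, nz))
        for n, offs in enumerate(self.offsets_by_bin):
            for (dx, dy, dz) in offs:
                out[n, dx + h, dy + h, dz + hz] = 1.0
            if offs:
                out[n] /= len(offs)
        return out


def build_bin_assignment(
    R2: int, Na: int = 8, Nr: int = 2, Nh: int = 2, two_d: bool = False
) -> BinAssignment:
    """Assign every voxel offset of the R2-wide window to a log-polar bin.

    Azimuth: Na half-open sectors starting at +x, counter-clockwise.
    Radius (in the x-y plane): Nr geometric shells with edge ratio sqrt(2),
    outermost edge at R2/2; the innermost shell extends to r = 0.
    Height: Nh equal slabs of the z extent [-R2/2, R2/2].
    Bin index = ((height * Nr) + shell) * Na + sector.
    """
    if R2 < 1 or R2 % 2 == 0:
        raise ValueError(f"R2 must be odd, got {R2}")
    if min(Na, Nr, Nh) < 1:
        raise ValueError("Na, Nr, Nh must all be >= 1")
    h = R2 // 2
    r_max = R2 / 2.0
    # shell upper edges, innermost first
    edges = [r_max * RADIAL_RATIO ** (-(Nr - 1 - i)) for i in range(Nr)]
    sector_width = 2.0 * math.pi / Na
    zs = [0] if two_d else range(-h, h + 1)
    n_bins = Na * Nr * Nh
    bin_of = {}
    by_bin = [[] for _ in range(n_bins)]
    for dx in range(-h, h + 1):
        for dy in range(-h, h + 1):
            r = math.hypot(dx, dy)
            if r > r_max + 1e-12:
                continue  # outside the inscribed cylinder
            if r == 0.0:
                sector, shell = 0, 0
            else:
                az = math.atan2(dy, dx) % (2.0 * math.pi)
                sector = min(int(az / sector_width), Na - 1)
                shell = next(i for i, e in enumerate(edges) if r <= e + 1e-12)
            for dz in zs:
                slab = min(int((dz + r_max) / (R2 / Nh)), Nh - 1)
                n = (slab * Nr + shell) * Na + sector
                bin_of[(dx, dy, dz)] = n
                by_bin[n].append((dx, dy, dz))
    ba = BinAssignment(
        R2=R2, Na=Na, Nr=Nr, Nh=Nh, two_d=two_d,
        bin_of_offset=bin_of, offsets_by_bin=by_bin,
    )
    if ba.empty_bins:
        logger.warning(
            "log-polar binning R2=%d Na=%d Nr=%d Nh=%d leaves %d empty bins: %s",
            R2, Na, Nr, Nh, len(ba.empty_bins), ba.empty_bins,
        )
    return ba


def aggregate_macmind(mss: FeatureMap, bins: BinAssignment) -> FeatureMap:
    """Average-pool each msSSC channel over every log-polar bin.

    Output channel (m, n) at voxel p is the mean of msSSC channel m over the
    offsets of bin n centred at p (edge replication at the borders); empty
    bins yield all-zero channels with a logged warning.  Channels are ordered
    bin-major: index = n * M + m.
    """
    X, Y, Z, M = mss.data.shape
    h = bins.R2 // 2
    hz = 0 if bins.two_d else h
    if min(X, Y) < bins.R2 or (not bins.two_d and Z < 1):
        raise ValueError(f"feature grid {mss.grid_shape} smaller than R2={bins.R2}")
    src = np.asarray(mss.data, dtype=np.float32)
    padded = np.pad(src, ((h, h), (h, h), (hz, hz), (0, 0)), mode="edge")
    out = np.zeros((X, Y, Z, bins.n_bins * M), dtype=np.float32)
    if bins.empty_bins:
        logger.warning(
            "aggregation: %d empty bins filled with 0: %s",
            len(bins.empty_bins), bins.empty_bins,
        )
    for n, offs in enumerate(bins.offsets_by_bin):
        if not offs:
            continue
        acc = np.zeros((X, Y, Z, M), dtype=np.float64)
        for (dx, dy, dz) in offs:
            acc += padded[
                h + dx : h + dx + X,
                h + dy : h + dy + Y,
                hz + dz : hz + dz + Z,
                :,
            ]
        out[..., n * M : (n + 1) * M] = (acc / len(offs)).astype(np.float32)
    meta = []
    for n in range(bins.n_bins):
        for m in range(M):
            entry = {"descriptor": "macMIND", "bin": n, "msssc_channel": m}
            if mss.channel_meta:
                entry["pair"] = mss.channel_meta[m].get("pair")
                entry["orientation"] = mss.channel_meta[m].get("orientation")
            meta.append(entry)
    return FeatureMap(
        data=out, spacing=mss.spacing, origin=mss.origin, channel_meta=meta
    )


def macmind(vol: Volume, cfg: DescriptorConfig | None = None) -> FeatureMap:
    """Full cascade: msSSC followed by log-polar average pooling.

    Returns an M x N-channel feature map (M = 18 pairs, N = Na*Nr*Nh bins;
    576 channels at the defaults), deterministic given (volume, config).
    """
    cfg = cfg or DescriptorConfig()
    min_ax = cfg.K * cfg.L + cfg.R1 // 2 + cfg.R2 // 2 + 1
    if min(vol.shape) < min_ax:
        raise ValueError(
            f"image {vol.shape} smaller than the macMIND footprint; each axis "
            f"must be >= {min_ax} for L={cfg.L}, K={cfg.K}, R1={cfg.R1}, "
            f"R2={cfg.R2}"
        )
    mss = msssc(vol, cfg)
    bins = build_bin_assignment(cfg.R2, cfg.Na, cfg.Nr, cfg.Nh)
    out = aggregate_macmind(mss, bins)
    for entry in out.channel_meta:
        entry["config"] = "see sidecar"
    return out
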