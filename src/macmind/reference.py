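"""Naive per-voxel reference implementations of the descriptors.

These implement the descriptor definitions literally — explicit loops over
voxels, patch pairs and patch displacements, no shift-and-convolve tricks —
and exist to validate the fast path in :mod:`macmind.descriptors` on small
volumes.  They share only the boundary convention (a single edge-replication
padding of the input) so that fast and naive agree at every voxel.

They are orders of magnitude slower; use them on volumes of about 16^3 or
less.
"""

from __future__ import annotations

import numpy as np

from .core_io import Volume
from .descriptors import (
    ABS_FLOOR,
    BinAssignment,
    ConnectionLayout,
    DescriptorConfig,
    FeatureMap,
    _NEIGHBOR_DIRS,
    build_bin_assignment,
    build_connection_layout,
)

__all__ = [
    "naive_patch_ssd_map",
    "naive_mind",
    "naive_ssc",
    "naive_msssc",
    "naive_aggregate",
    "naive_macmind",
]


def _patch(padded: np.ndarray, center, pad: int, r: int) -> np.ndarray:
    c = [int(ci) + pad for ci in center]
    return padded[
        c[0] - r : c[0] + r + 1,
        c[1] - r : c[1] + r + 1,
        c[2] - r : c[2] + r + 1,
    ]


def naive_patch_ssd_map(vol: Volume, offset_pair, R1: int) -> np.ndarray:
    """Patch-pair mean squared difference by explicit per-voxel patch loops."""
    oi, oj = (np.asarray(o, dtype=int) for o in offset_pair)
    r = R1 // 2
    pad = r + int(max(np.abs(oi).max(), np.abs(oj).max()))
    padded = np.pad(np.asarray(vol.data, dtype=np.float64), pad, mode="edge")
    out = np.empty(vol.shape, dtype=np.float64)
    for x in range(vol.shape[0]):
        for y in range(vol.shape[1]):
            for z in range(vol.shape[2]):
                p = np.array([x, y, z])
                a = _patch(padded, p + oi, pad, r)
                b = _patch(padded, p + oj, pad, r)
                out[x, y, z] = np.mean((a - b) ** 2)
    return out


def _ssd_stack(vol: Volume, layout: ConnectionLayout, R1: int) -> np.ndarray:
    return np.stack(
        [
            naive_patch_ssd_map(
                vol, (layout.offsets[i], layout.offsets[j]), R1
            )
            for i, j in layout.pairs
        ],
        axis=-1,
    )


def naive_mind(vol: Volume, L: int = 2, R1: int = 5, eps_rel: float = 1e-6) -> np.ndarray:
    """6-channel MIND from per-voxel patch loops (float64)."""
    dists = np.stack(
        [
            naive_patch_ssd_map(vol, (np.zeros(3, int), d * L), R1)
            for d in _NEIGHBOR_DIRS
        ],
        axis=-1,
    )
    v = dists.mean(axis=-1)
    floor = max(eps_rel * float(v.mean()), ABS_FLOOR)
    v = np.maximum(v, floor)
    return np.exp(-dists / v[..., None])


def naive_ssc(
    vol: Volume, layout: ConnectionLayout, R1: int = 5, eps_rel: float = 1e-6
) -> np.ndarray:
    """SSC channels computed literally as exp(-e_P * SSD_ij / sum SSD)."""
    ssd = _ssd_stack(vol, layout, R1)
    e_p = layout.e_p
    total = ssd.sum(axis=-1)
    floor = e_p * max(eps_rel * float(total.mean() / e_p), ABS_FLOOR)
    total = np.maximum(total, floor)
    return np.exp(-e_p * ssd / total[..., None])


def naive_msssc(vol: Volume, cfg: DescriptorConfig) -> np.ndarray:
    acc = None
    for k in range(1, cfg.K + 1):
        layout = build_connection_layout(k, cfg.L)
        ssc = naive_ssc(vol, layout, cfg.R1, cfg.eps_rel)
        term = cfg.alphas[k - 1] * ssc
        acc = term if acc is None else acc + term
    return acc


def naive_aggregate(mss_data: np.ndarray, bins: BinAssignment) -> np.ndarray:
    """Bin-average by explicit per-voxel, per-bin, per-offset loops."""
    X, Y, Z, M = mss_data.shape
    h = bins.R2 // 2
    hz = 0 if bins.two_d else h
    padded = np.pad(
        np.asarray(mss_data, dtype=np.float64),
        ((h, h), (h, h), (hz, hz), (0, 0)),
        mode="edge",
    )
    out = np.zeros((X, Y, Z, bins.n_bins * M), dtype=np.float64)
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                for n, offs in enumerate(bins.offsets_by_bin):
                    if not offs:
                        continue
                    vals = [
                        padded[x + h + dx, y + h + dy, z + hz + dz, :]
                        for (dx, dy, dz) in offs
                    ]
                    out[x, y, z, n * M : (n + 1) * M] = np.mean(vals, axis=0)
    return out


def naive_macmind(vol: Volume, cfg: DescriptorConfig | None = None) -> np.ndarray:
    cfg = cfg or DescriptorConfig()
    mss = naive_msssc(vol, cfg)
    bins = build_bin_assignment(cfg.R2, cfg.Na, cfg.Nr, cfg.Nh)
    return naive_aggregate(mss, bins)
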