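"""Texture matrix construction for the five 3D matrix families.

All families work on a :class:`~lesionsr.radiomics.quantize.QuantizedROI`
at voxel distance 1 in 3D:

* GLCM / GLRLM accumulate over the 13 unique direction vectors (one of
  each antipodal pair of the 26-neighbourhood), symmetrically;
* GLDM / NGTDM use the full 26-neighbourhood;
* GLSZM zones are 26-connected components of constant gray level.

Matrices are dense over levels ``1..max_level``; unoccupied levels simply
carry zero mass (feature sums skip them naturally).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "OFFSETS_26",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_stats",
]

# one representative of each antipodal offset pair in the 26-neighbourhood
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)


def _crop(levels: np.ndarray) -> np.ndarray:
    """Crop to the mask bounding box (levels are 0 outside the mask)."""
    idx = np.argwhere(levels > 0)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return levels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]


def _shifted_views(arr: np.ndarray, d: tuple[int, int, int]):
    """Overlapping views (a, b) with b displaced by +d relative to a."""
    sl_a, sl_b = [], []
    for dim, off in zip(arr.shape, d):
        if off >= 0:
            sl_a.append(slice(0, dim - off))
            sl_b.append(slice(off, dim))
        else:
            sl_a.append(slice(-off, dim))
            sl_b.append(slice(0, dim + off))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def glcm_matrices(q) -> np.ndarray:
    """Symmetric co-occurrence matrices, one per direction: (13, Ng, Ng).

    Entry [d, i-1, j-1] counts ordered in-mask voxel pairs at offset
    ±direction d with levels (i, j); each matrix is symmetric by
    construction (both orders counted).
    """
    ng = q.max_level
    lv = _crop(q.levels)
    out = np.zeros((len(DIRECTIONS_13), ng, ng), dtype=np.int64)
    for k, d in enumerate(DIRECTIONS_13):
        a, b = _shifted_views(lv, d)
        valid = (a > 0) & (b > 0)
        ai, bi = a[valid] - 1, b[valid] - 1
        flat = np.bincount(ai * ng + bi, minlength=ng * ng).reshape(ng, ng)
        out[k] = flat + flat.T
    return out


def _lines(shape: tuple[int, int, int], d: tuple[int, int, int]):
    """Start coordinates and lengths of all full lattice lines along +d."""
    nz, ny, nx = shape
    zz, yy, xx = np.indices(shape).reshape(3, -1)
    # a line start has no predecessor at -d inside the box
    pz, py, px = zz - d[0], yy - d[1], xx - d[2]
    is_start = (
        (pz < 0) | (pz >= nz) | (py < 0) | (py >= ny) | (px < 0) | (px >= nx)
    )
    starts = np.stack([zz, yy, xx], axis=1)[is_start]
    lens = np.full(len(starts), np.iinfo(np.int64).max, dtype=np.int64)
    for axis, (n, off) in enumerate(zip(shape, d)):
        if off > 0:
            lens = np.minimum(lens, n - starts[:, axis])
        elif off < 0:
            lens = np.minimum(lens, starts[:, axis] + 1)
    return starts, lens


def _run_lengths(seq: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode a 1D level sequence; level 0 (outside mask) breaks runs."""
    if seq.size == 0:
        return []
    change = np.nonzero(np.diff(seq))[0] + 1
    bounds = np.concatenate([[0], change, [seq.size]])
    return [
        (int(seq[b]), int(e - b))
        for b, e in zip(bounds[:-1], bounds[1:])
        if seq[b] > 0
    ]


def glrlm_matrices(q) -> np.ndarray:
    """Run-length matrices per direction: (13, Ng, Lmax).

    Entry [d, i-1, l-1] counts maximal runs of length l at level i along
    direction d (each antipodal pair counted once).
    """
    ng = q.max_level
    lv = _crop(q.levels)
    lmax = max(lv.shape)
    out = np.zeros((len(DIRECTIONS_13), ng, lmax), dtype=np.int64)
    t = np.arange(max(lv.shape))
    for k, d in enumerate(DIRECTIONS_13):
        starts, lens = _lines(lv.shape, d)
        for (z0, y0, x0), ln in zip(starts, lens):
            tt = t[:ln]
            seq = lv[z0 + tt * d[0], y0 + tt * d[1], x0 + tt * d[2]]
            for level, length in _run_lengths(seq):
                out[k, level - 1, length - 1] += 1
    return out


def glszm_matrix(q) -> np.ndarray:
    """Size-zone matrix (Ng, Smax): 26-connected constant-level zone sizes."""
    ng = q.max_level
    lv = _crop(q.levels)
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    for level in range(1, ng + 1):
        labeled, n = ndimage.label(lv == level, structure=structure)
        if n:
            sizes = np.bincount(labeled.ravel())[1:]
            zones.extend((level, int(s)) for s in sizes)
    smax = max((s for _, s in zones), default=1)
    out = np.zeros((ng, smax), dtype=np.int64)
    for level, s in zones:
        out[level - 1, s - 1] += 1
    return out


def gldm_matrix(q, alpha: int = 0) -> np.ndarray:
    """Dependence matrix (Ng, 27) indexed by (level, dependent-neighbour count).

    A 26-neighbour is dependent on the centre when both lie in the mask and
    their level difference is <= ``alpha``.  Column j holds the count of
    voxels with exactly j dependent neighbours (j = 0 for isolated voxels).
    """
    ng = q.max_level
    lv = _crop(q.levels)
    pad = np.pad(lv, 1)
    centre = pad[1:-1, 1:-1, 1:-1]
    dep = np.zeros(lv.shape, dtype=np.int64)
    for dz, dy, dx in OFFSETS_26:
        nb = pad[1 + dz : pad.shape[0] - 1 + dz,
                 1 + dy : pad.shape[1] - 1 + dy,
                 1 + dx : pad.shape[2] - 1 + dx]
        dep += (nb > 0) & (np.abs(nb - centre) <= alpha)
    inside = centre > 0
    out = np.zeros((ng, 27), dtype=np.int64)
    np.add.at(out, (centre[inside] - 1, dep[inside]), 1)
    return out


def ngtdm_stats(q) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Neighbourhood gray-tone difference statistics.

    Returns ``(n_i, p_i, s_i, n_valid)`` over levels 1..Ng, where n_i counts
    ROI voxels of level i having at least one in-mask 26-neighbour,
    p_i = n_i / n_valid, and s_i sums |i - mean(neighbour levels)| over
    those voxels.
    """
    ng = q.max_level
    lv = _crop(q.levels)
    pad = np.pad(lv, 1)
    centre = pad[1:-1, 1:-1, 1:-1]
    nb_sum = np.zeros(lv.shape, dtype=np.int64)
    nb_cnt = np.zeros(lv.shape, dtype=np.int64)
    for dz, dy, dx in OFFSETS_26:
        nb = pad[1 + dz : pad.shape[0] - 1 + dz,
                 1 + dy : pad.shape[1] - 1 + dy,
                 1 + dx : pad.shape[2] - 1 + dx]
        nb_sum += np.where(nb > 0, nb, 0)
        nb_cnt += nb > 0
    valid = (centre > 0) & (nb_cnt > 0)
    n_valid = int(valid.sum())
    diffs = np.abs(centre[valid] - nb_sum[valid] / nb_cnt[valid])
    lv_valid = centre[valid]
    n_i = np.bincount(lv_valid - 1, minlength=ng).astype(float)
    s_i = np.bincount(lv_valid - 1, weights=diffs, minlength=ng)
    p_i = n_i / n_valid if n_valid else n_i
    return n_i, p_i, s_i, n_valid
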