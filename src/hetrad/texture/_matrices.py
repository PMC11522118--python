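"""Second-order texture matrix builders.

All builders operate on a level grid: a 3-D int array where 0 marks
voxels outside the lesion and 1..Ng are discretized gray levels.  The five
matrix families follow the image-biomarker reference definitions:

* GLCM  — co-occurrence counts of level pairs at Chebyshev distance
  ``distance`` along each of the 13 unique 3-D directions, symmetrized
  (transpose added) and normalized to a joint probability per direction.
* GLRLM — maximal runs of equal level along each of the 13 directions,
  counted by (level, run length).
* GLSZM — 26-connected iso-level zones, counted by (level, zone size);
  direction-free.
* GLDM  — per-voxel dependence counts: 26-neighbours inside the mask with
  absolute level difference <= alpha; counted by (level, dependence + 1).
* NGTDM — per-level voxel counts, probabilities and summed absolute
  differences between a voxel's level and its in-mask neighbourhood mean.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: 13 unique direction offsets at Chebyshev distance 1 (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: All 26 neighbour offsets.
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _shifted_views(grid: np.ndarray, offset: tuple[int, int, int]):
    """Pair of views (src, dst) such that dst = src translated by offset."""
    slices_src, slices_dst = [], []
    for d, n in zip(offset, grid.shape):
        if d > 0:
            slices_src.append(slice(0, n - d))
            slices_dst.append(slice(d, n))
        elif d < 0:
            slices_src.append(slice(-d, n))
            slices_dst.append(slice(0, n + d))
        else:
            slices_src.append(slice(0, n))
            slices_dst.append(slice(0, n))
    return grid[tuple(slices_src)], grid[tuple(slices_dst)]


def glcm_per_angle(grid: np.ndarray, n_levels: int, distance: int = 1) -> np.ndarray:
    """Symmetric, per-angle normalized GLCMs, shape (13, Ng, Ng).

    Angles with no in-mask voxel pair are left all-zero (callers treat them
    as missing when averaging features over angles).
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    ng = n_levels
    out = np.zeros((len(DIRECTIONS_13), ng, ng), dtype=float)
    for a, (dx, dy, dz) in enumerate(DIRECTIONS_13):
        off = (dx * distance, dy * distance, dz * distance)
        src, dst = _shifted_views(grid, off)
        valid = (src > 0) & (dst > 0)
        if not valid.any():
            continue
        i = src[valid] - 1
        j = dst[valid] - 1
        counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
        counts = counts + counts.T  # symmetrize: fold opposite direction
        out[a] = counts / counts.sum()
    return out


def glrlm_per_angle(grid: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-angle run-length count matrices, shape (13, Ng, Nr).

    A run is a maximal sequence of collinear in-mask voxels sharing one
    level; Nr is the longest possible run (the largest grid extent).
    """
    ng = n_levels
    nr = max(grid.shape)
    out = np.zeros((len(DIRECTIONS_13), ng, nr), dtype=float)
    coords_all = np.argwhere(grid > 0)
    if coords_all.size == 0:
        return out
    shape = np.array(grid.shape)
    for a, direction in enumerate(DIRECTIONS_13):
        d = np.array(direction)
        # run starts: in-mask voxels whose predecessor is outside or differs
        prev = coords_all - d
        ok = np.all((prev >= 0) & (prev < shape), axis=1)
        prev_lv = np.zeros(len(coords_all), dtype=grid.dtype)
        prev_lv[ok] = grid[tuple(prev[ok].T)]
        starts = coords_all[prev_lv != grid[tuple(coords_all.T)]]
        levels = grid[tuple(starts.T)]
        # walk each run forward until the level changes or the grid ends
        pos = starts.copy()
        length = np.ones(len(starts), dtype=np.intp)
        alive = np.ones(len(starts), dtype=bool)
        while alive.any():
            nxt = pos[alive] + d
            inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(len(nxt), dtype=bool)
            cont[inb] = grid[tuple(nxt[inb].T)] == levels[alive][inb]
            idx = np.flatnonzero(alive)
            length[idx[cont]] += 1
            pos[idx[cont]] += d
            alive[idx[~cont]] = False
        np.add.at(out[a], (levels - 1, length - 1), 1.0)
    return out


def glszm(grid: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix, shape (Ng, Ns): 26-connected iso-level zones."""
    ng = n_levels
    ns = int((grid > 0).sum())
    out = np.zeros((ng, max(ns, 1)), dtype=float)
    for level in range(1, ng + 1):
        blob = grid == level
        if not blob.any():
            continue
        lab, n_zones = ndimage.label(blob, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            out[level - 1, s - 1] += 1.0
    return out


def _neighbour_stacks(grid: np.ndarray):
    """In-mask 26-neighbour levels per voxel via a padded grid.

    Returns (levels, neighbour level stack, neighbour in-mask stack) where
    the stacks have shape (26, *grid.shape).
    """
    padded = np.pad(grid, 1, constant_values=0)
    nx, ny, nz = grid.shape
    nb = np.empty((len(OFFSETS_26),) + grid.shape, dtype=grid.dtype)
    for k, (dx, dy, dz) in enumerate(OFFSETS_26):
        nb[k] = padded[1 + dx : 1 + dx + nx, 1 + dy : 1 + dy + ny, 1 + dz : 1 + dz + nz]
    return nb


def gldm(grid: np.ndarray, n_levels: int, alpha: float = 0.0) -> np.ndarray:
    """Dependence count matrix, shape (Ng, Nd).

    A 26-neighbour is dependent when it is inside the mask and its level
    differs from the centre voxel's by at most ``alpha``.  Column j holds
    voxels with j-1 dependent neighbours (dependence + 1 indexing).
    """
    ng = n_levels
    nb = _neighbour_stacks(grid)
    inmask = grid > 0
    dep = ((nb > 0) & (np.abs(nb - grid) <= alpha) & inmask).sum(axis=0)
    levels = grid[inmask] - 1
    deps = dep[inmask]
    nd = int(deps.max()) + 1 if deps.size else 1
    out = np.zeros((ng, nd), dtype=float)
    np.add.at(out, (levels, deps), 1.0)
    return out


def ngtdm(grid: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbouring gray tone difference triples (n_i, p_i, s_i), length Ng.

    Only voxels with at least one in-mask 26-neighbour contribute; p_i is
    normalized over those voxels.
    """
    ng = n_levels
    nb = _neighbour_stacks(grid)
    inmask = grid > 0
    nb_in = nb > 0
    cnt = nb_in.sum(axis=0)
    valid = inmask & (cnt > 0)
    n = np.zeros(ng, dtype=float)
    s = np.zeros(ng, dtype=float)
    if valid.any():
        mean_nb = nb.sum(axis=0, where=nb_in, dtype=float)[valid] / cnt[valid]
        lv = grid[valid]
        diff = np.abs(lv - mean_nb)
        n = np.bincount(lv - 1, minlength=ng).astype(float)
        s = np.bincount(lv - 1, weights=diff, minlength=ng)
    total = n.sum()
    p = n / total if total > 0 else n.copy()
    return n, p, s
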