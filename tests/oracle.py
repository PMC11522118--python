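"""Independent brute-force oracle for texture matrices and features.

Everything here is written as plain per-voxel / per-cell loops straight
from the matrix and feature definitions, deliberately sharing no code
with the vectorized implementation in ``hetrad.texture``.  It is slow and
only meant for small grids and fixture lesions.
"""

from __future__ import annotations

import math

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
OFFS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(grid, p):
    return all(0 <= c < n for c, n in zip(p, grid.shape)) and grid[p] > 0


def naive_glcm(grid, ng, direction, distance=1):
    """Symmetric normalized co-occurrence matrix for one direction."""
    d = tuple(c * distance for c in direction)
    counts = np.zeros((ng, ng))
    for p in np.ndindex(grid.shape):
        if grid[p] == 0:
            continue
        for sign in (+1, -1):
            q = tuple(a + sign * b for a, b in zip(p, d))
            if _inside(grid, q):
                counts[grid[p] - 1, grid[q] - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def naive_glrlm(grid, ng, direction):
    """Run-length count matrix for one direction (max run = max extent)."""
    nr = max(grid.shape)
    counts = np.zeros((ng, nr))
    for p in np.ndindex(grid.shape):
        if grid[p] == 0:
            continue
        prev = tuple(a - b for a, b in zip(p, direction))
        if _inside(grid, prev) and grid[prev] == grid[p]:
            continue  # not a run start
        length = 1
        q = tuple(a + b for a, b in zip(p, direction))
        while _inside(grid, q) and grid[q] == grid[p]:
            length += 1
            q = tuple(a + b for a, b in zip(q, direction))
        counts[grid[p] - 1, length - 1] += 1
    return counts


def naive_glszm(grid, ng):
    """Zone count matrix via breadth-first flood fill, 26-connectivity."""
    ns = int((grid > 0).sum())
    counts = np.zeros((ng, max(ns, 1)))
    seen = np.zeros(grid.shape, dtype=bool)
    for p in np.ndindex(grid.shape):
        if grid[p] == 0 or seen[p]:
            continue
        level = grid[p]
        queue = [p]
        seen[p] = True
        size = 0
        while queue:
            cur = queue.pop()
            size += 1
            for off in OFFS_26:
                q = tuple(a + b for a, b in zip(cur, off))
                if _inside(grid, q) and not seen[q] and grid[q] == level:
                    seen[q] = True
                    queue.append(q)
        counts[level - 1, size - 1] += 1
    return counts


def naive_gldm(grid, ng, alpha=0.0):
    """Dependence count matrix; column j holds voxels with j-1 dependents."""
    rows = {}
    max_dep = 0
    for p in np.ndindex(grid.shape):
        if grid[p] == 0:
            continue
        dep = 0
        for off in OFFS_26:
            q = tuple(a + b for a, b in zip(p, off))
            if _inside(grid, q) and abs(int(grid[q]) - int(grid[p])) <= alpha:
                dep += 1
        rows[(grid[p] - 1, dep)] = rows.get((grid[p] - 1, dep), 0) + 1
        max_dep = max(max_dep, dep)
    counts = np.zeros((ng, max_dep + 1))
    for (i, dep), c in rows.items():
        counts[i, dep] = c
    return counts


def naive_ngtdm(grid, ng):
    """(n_i, p_i, s_i) triples over voxels with >= 1 in-mask neighbour."""
    n = np.zeros(ng)
    s = np.zeros(ng)
    for p in np.ndindex(grid.shape):
        if grid[p] == 0:
            continue
        levels = []
        for off in OFFS_26:
            q = tuple(a + b for a, b in zip(p, off))
            if _inside(grid, q):
                levels.append(int(grid[q]))
        if not levels:
            continue
        n[grid[p] - 1] += 1
        s[grid[p] - 1] += abs(float(grid[p]) - sum(levels) / len(levels))
    total = n.sum()
    p_arr = n / total if total > 0 else n.copy()
    return n, p_arr, s


# ---------------------------------------------------------------------------
# naive feature formulas (scalar accumulation, one matrix at a time)


def _log2(x):
    return math.log(x, 2)


def naive_glcm_features(P, ng):
    """24 co-occurrence features from one angle's normalized matrix."""
    iv = list(range(1, ng + 1))
    px = [sum(P[i - 1, j - 1] for j in iv) for i in iv]
    mu = sum(i * px[i - 1] for i in iv)
    var = sum(px[i - 1] * (i - mu) ** 2 for i in iv)

    f = {k: 0.0 for k in (
        "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
        "Contrast", "DifferenceAverage", "Id", "Idm", "Idmn", "Idn",
        "InverseVariance", "JointEnergy", "JointEntropy", "MaximumProbability",
    )}
    hxy1 = 0.0
    for i in iv:
        for j in iv:
            p = P[i - 1, j - 1]
            f["Autocorrelation"] += p * i * j
            f["ClusterProminence"] += p * (i + j - 2 * mu) ** 4
            f["ClusterShade"] += p * (i + j - 2 * mu) ** 3
            f["ClusterTendency"] += p * (i + j - 2 * mu) ** 2
            f["Contrast"] += p * (i - j) ** 2
            f["Id"] += p / (1 + abs(i - j))
            f["Idm"] += p / (1 + (i - j) ** 2)
            f["Idmn"] += p / (1 + (i - j) ** 2 / ng**2)
            f["Idn"] += p / (1 + abs(i - j) / ng)
            f["JointEnergy"] += p * p
            if i != j:
                f["InverseVariance"] += p / (i - j) ** 2
            if p > 0:
                f["JointEntropy"] -= p * _log2(p)
                hxy1 -= p * _log2(px[i - 1] * px[j - 1])
            f["MaximumProbability"] = max(f["MaximumProbability"], p)

    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in iv:
        for j in iv:
            p_sum[i + j] += P[i - 1, j - 1]
            p_diff[abs(i - j)] += P[i - 1, j - 1]
    da = sum(k * v for k, v in p_diff.items())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(v * _log2(v) for v in p_diff.values() if v > 0)
    f["DifferenceVariance"] = sum(v * (k - da) ** 2 for k, v in p_diff.items())
    f["SumAverage"] = sum(k * v for k, v in p_sum.items())
    f["SumEntropy"] = -sum(v * _log2(v) for v in p_sum.values() if v > 0)
    f["SumSquares"] = var
    f["JointAverage"] = mu
    f["Correlation"] = (f["Autocorrelation"] - mu * mu) / var if var > 0 else 1.0

    hx = -sum(v * _log2(v) for v in px if v > 0)
    hxy2 = -sum(
        px[i - 1] * px[j - 1] * _log2(px[i - 1] * px[j - 1])
        for i in iv for j in iv if px[i - 1] * px[j - 1] > 0
    )
    f["Imc1"] = (f["JointEntropy"] - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - f["JointEntropy"]))
    f["Imc2"] = math.sqrt(arg) if arg > 0 else 0.0

    present = [i for i in iv if px[i - 1] > 0]
    if len(present) < 2:
        f["MCC"] = 1.0
    else:
        q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(
                    P[i - 1, k - 1] * P[j - 1, k - 1] / (px[i - 1] * px[k - 1])
                    for k in present
                )
        eig = sorted(np.real(np.linalg.eigvals(q)))
        f["MCC"] = math.sqrt(max(eig[-2], 0.0))
    return f


def naive_rl_family(M, ng, size_label):
    """Shared run-length / size-zone style features on a (Ng, N2) count matrix.

    ``size_label`` selects the naming: 'run', 'zone' or 'dependence'.
    """
    n2 = M.shape[1]
    iv = list(range(1, ng + 1))
    jv = list(range(1, n2 + 1))
    total = M.sum()
    nvox = sum(M[i - 1, j - 1] * j for i in iv for j in jv)
    pg = [sum(M[i - 1, j - 1] for j in jv) for i in iv]
    pj = [sum(M[i - 1, j - 1] for i in iv) for j in jv]
    mu_i = sum(i * pg[i - 1] for i in iv) / total
    mu_j = sum(j * pj[j - 1] for j in jv) / total

    out = {
        "short": sum(pj[j - 1] / j**2 for j in jv) / total,
        "long": sum(pj[j - 1] * j**2 for j in jv) / total,
        "gln": sum(g**2 for g in pg) / total,
        "glnn": sum(g**2 for g in pg) / total**2,
        "jn": sum(v**2 for v in pj) / total,
        "jnn": sum(v**2 for v in pj) / total**2,
        "percentage": total / nvox,
        "glv": sum(M[i - 1, j - 1] / total * (i - mu_i) ** 2 for i in iv for j in jv),
        "jv": sum(M[i - 1, j - 1] / total * (j - mu_j) ** 2 for i in iv for j in jv),
        "entropy": -sum(
            M[i - 1, j - 1] / total * _log2(M[i - 1, j - 1] / total)
            for i in iv for j in jv if M[i - 1, j - 1] > 0
        ),
        "lgl": sum(pg[i - 1] / i**2 for i in iv) / total,
        "hgl": sum(pg[i - 1] * i**2 for i in iv) / total,
        "short_lgl": sum(M[i - 1, j - 1] / (i**2 * j**2) for i in iv for j in jv) / total,
        "short_hgl": sum(M[i - 1, j - 1] * i**2 / j**2 for i in iv for j in jv) / total,
        "long_lgl": sum(M[i - 1, j - 1] * j**2 / i**2 for i in iv for j in jv) / total,
        "long_hgl": sum(M[i - 1, j - 1] * i**2 * j**2 for i in iv for j in jv) / total,
    }
    return out


def naive_glrlm_features(R, ng):
    g = naive_rl_family(R, ng, "run")
    return {
        "GrayLevelNonUniformity": g["gln"],
        "GrayLevelNonUniformityNormalized": g["glnn"],
        "GrayLevelVariance": g["glv"],
        "HighGrayLevelRunEmphasis": g["hgl"],
        "LongRunEmphasis": g["long"],
        "LongRunHighGrayLevelEmphasis": g["long_hgl"],
        "LongRunLowGrayLevelEmphasis": g["long_lgl"],
        "LowGrayLevelRunEmphasis": g["lgl"],
        "RunEntropy": g["entropy"],
        "RunLengthNonUniformity": g["jn"],
        "RunLengthNonUniformityNormalized": g["jnn"],
        "RunPercentage": g["percentage"],
        "RunVariance": g["jv"],
        "ShortRunEmphasis": g["short"],
        "ShortRunHighGrayLevelEmphasis": g["short_hgl"],
        "ShortRunLowGrayLevelEmphasis": g["short_lgl"],
    }


def naive_glszm_features(Z, ng):
    g = naive_rl_family(Z, ng, "zone")
    return {
        "GrayLevelNonUniformity": g["gln"],
        "GrayLevelNonUniformityNormalized": g["glnn"],
        "GrayLevelVariance": g["glv"],
        "HighGrayLevelZoneEmphasis": g["hgl"],
        "LargeAreaEmphasis": g["long"],
        "LargeAreaHighGrayLevelEmphasis": g["long_hgl"],
        "LargeAreaLowGrayLevelEmphasis": g["long_lgl"],
        "LowGrayLevelZoneEmphasis": g["lgl"],
        "SizeZoneNonUniformity": g["jn"],
        "SizeZoneNonUniformityNormalized": g["jnn"],
        "SmallAreaEmphasis": g["short"],
        "SmallAreaHighGrayLevelEmphasis": g["short_hgl"],
        "SmallAreaLowGrayLevelEmphasis": g["short_lgl"],
        "ZoneEntropy": g["entropy"],
        "ZonePercentage": g["percentage"],
        "ZoneVariance": g["jv"],
    }


def naive_gldm_features(D, ng):
    g = naive_rl_family(D, ng, "dependence")
    # dependence counts are per voxel: total == voxel count, so the
    # 'percentage' analogue is not part of this 14-feature family
    return {
        "DependenceEntropy": g["entropy"],
        "DependenceNonUniformity": g["jn"],
        "DependenceNonUniformityNormalized": g["jnn"],
        "DependenceVariance": g["jv"],
        "GrayLevelNonUniformity": g["gln"],
        "GrayLevelVariance": g["glv"],
        "HighGrayLevelEmphasis": g["hgl"],
        "LargeDependenceEmphasis": g["long"],
        "LargeDependenceHighGrayLevelEmphasis": g["long_hgl"],
        "LargeDependenceLowGrayLevelEmphasis": g["long_lgl"],
        "LowGrayLevelEmphasis": g["lgl"],
        "SmallDependenceEmphasis": g["short"],
        "SmallDependenceHighGrayLevelEmphasis": g["short_hgl"],
        "SmallDependenceLowGrayLevelEmphasis": g["short_lgl"],
    }


def naive_ngtdm_features(n, p, s):
    ng = len(p)
    present = [i for i in range(1, ng + 1) if p[i - 1] > 0]
    nvp = float(sum(n))
    ngp = len(present)
    ps = sum(p[i - 1] * s[i - 1] for i in present)
    coarseness = 1.0 / ps if ps > 0 else 1e6

    contrast = busyness = complexity = strength = 0.0
    if ngp > 1 and nvp > 0:
        contrast = (
            sum(p[i - 1] * p[j - 1] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * (sum(s[i - 1] for i in present) / nvp)
        den = sum(
            abs(i * p[i - 1] - j * p[j - 1]) for i in present for j in present
        )
        busyness = ps / den if den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i - 1] * s[i - 1] + p[j - 1] * s[j - 1]) / (p[i - 1] + p[j - 1])
            for i in present for j in present
        ) / nvp
        ssum = sum(s[i - 1] for i in present)
        strength = (
            sum((p[i - 1] + p[j - 1]) * (i - j) ** 2 for i in present for j in present) / ssum
            if ssum > 0 else 0.0
        )
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


def naive_discretize(intensities, bin_width):
    lo = min(intensities)
    levels = [int(math.floor((x - lo) / bin_width)) + 1 for x in intensities]
    ng = int(math.floor((max(intensities) - lo) / bin_width)) + 1
    return levels, ng


def naive_compute_features(region, bin_width=25.0, distance=1, gldm_alpha=0.0):
    """All 75 features, brute force, matching the canonical naming."""
    levels, ng = naive_discretize(list(region.voxel_intensities), bin_width)
    coords = region.voxel_coordinates
    lo = coords.min(axis=0)
    shape = tuple(coords.max(axis=0) - lo + 1)
    grid = np.zeros(shape, dtype=int)
    for (x, y, z), lv in zip(coords - lo, levels):
        grid[x, y, z] = lv

    out = {}
    per_angle = []
    for direction in DIRS_13:
        P = naive_glcm(grid, ng, direction, distance)
        if P.sum() > 0:
            per_angle.append(naive_glcm_features(P, ng))
    for name in per_angle[0]:
        out[f"original_glcm_{name}"] = sum(f[name] for f in per_angle) / len(per_angle)

    rl_angle = [naive_glrlm_features(naive_glrlm(grid, ng, d), ng) for d in DIRS_13]
    for name in rl_angle[0]:
        out[f"original_glrlm_{name}"] = sum(f[name] for f in rl_angle) / len(rl_angle)

    out.update({f"original_glszm_{k}": v
                for k, v in naive_glszm_features(naive_glszm(grid, ng), ng).items()})
    out.update({f"original_gldm_{k}": v
                for k, v in naive_gldm_features(naive_gldm(grid, ng, gldm_alpha), ng).items()})
    n, p, s = naive_ngtdm(grid, ng)
    out.update({f"original_ngtdm_{k}": v for k, v in naive_ngtdm_features(n, p, s).items()})
    return out


def naive_wilcoxon_rank_sum_exact(x, y):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    from itertools import combinations

    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "exact enumeration assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    n = len(pooled)
    stats = [sum(c) for c in combinations(range(1, n + 1), len(x))]
    mean = sum(stats) / len(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(stats)
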