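"""Feature evaluation on the five texture-matrix families.

Angle-dependent families (GLCM, GLRLM) are evaluated per direction and the
13 per-angle values averaged; direction-free families (GLSZM, GLDM, NGTDM)
are evaluated once.  Formulas follow the image-biomarker reference
definitions.  Degenerate (flat-texture) inputs never yield NaN:

* GLCM Correlation on a single gray level is 1; MCC likewise.
* NGTDM Coarseness on a flat region (zero denominator) is capped at 1e6.
* Busyness and Strength return 0 on a zero denominator.
* Entropies sum only over positive probabilities, so a one-entry matrix
  gives exactly 0.
"""

from __future__ import annotations

import numpy as np

COARSENESS_CAP = 1e6


def _entropy(p: np.ndarray, axis=None) -> np.ndarray:
    """Shannon entropy in bits, summing only where p > 0."""
    safe = np.where(p > 0, p, 1.0)
    return -(p * np.log2(safe)).sum(axis=axis)


# ---------------------------------------------------------------------------
# GLCM


def glcm_features(P: np.ndarray, n_levels: int) -> dict[str, float]:
    """24 co-occurrence features, averaged over valid angles.

    ``P``: (n_angles, Ng, Ng) symmetric per-angle probability matrices;
    all-zero slices mark directions without voxel pairs.
    """
    ng = n_levels
    sums = P.sum(axis=(1, 2))
    valid = sums > 0
    if not valid.any():
        # single-voxel degenerate case: model as a flat one-pair texture
        P = np.zeros((1, ng, ng))
        P[0, 0, 0] = 1.0
        valid = np.array([True])
    P = P[valid]
    na = P.shape[0]

    ivals = np.arange(1, ng + 1, dtype=float)
    I = np.repeat(ivals, ng).reshape(ng, ng)
    J = I.T
    px = P.sum(axis=2)  # (na, ng); == py by symmetry
    mu = (px * ivals).sum(axis=1)  # (na,)
    sigma2 = (px * (ivals[None, :] - mu[:, None]) ** 2).sum(axis=1)
    sigma = np.sqrt(sigma2)

    flatP = P.reshape(na, -1)
    # p_{x+y} over k = 2..2Ng and p_{x-y} over k = 0..Ng-1
    sum_idx = (I + J).astype(int).ravel() - 2
    diff_idx = np.abs(I - J).astype(int).ravel()
    S = np.zeros((ng * ng, 2 * ng - 1))
    S[np.arange(ng * ng), sum_idx] = 1.0
    D = np.zeros((ng * ng, ng))
    D[np.arange(ng * ng), diff_idx] = 1.0
    p_sum = flatP @ S  # (na, 2Ng-1)
    p_diff = flatP @ D  # (na, Ng)
    ksum = np.arange(2, 2 * ng + 1, dtype=float)
    kdiff = np.arange(0, ng, dtype=float)

    auto = (P * (I * J)).sum(axis=(1, 2))
    cluster = (I + J)[None, :, :] - 2.0 * mu[:, None, None]
    contrast = (P * (I - J) ** 2).sum(axis=(1, 2))
    corr = np.ones(na)
    nz = sigma2 > 0
    corr[nz] = (auto[nz] - mu[nz] ** 2) / sigma2[nz]

    diff_avg = (p_diff * kdiff).sum(axis=1)
    joint_ent = _entropy(flatP, axis=1)

    # information measures of correlation
    hx = _entropy(px, axis=1)
    pxpy = px[:, :, None] * px[:, None, :]  # outer product per angle
    safe = np.where(pxpy > 0, pxpy, 1.0)
    log_pxpy = np.log2(safe)
    hxy1 = -(P * log_pxpy).sum(axis=(1, 2))
    hxy2 = -(pxpy * log_pxpy).sum(axis=(1, 2))
    imc1 = np.zeros(na)
    hmax = hx  # HX == HY by symmetry
    nzh = hmax > 0
    imc1[nzh] = (joint_ent[nzh] - hxy1[nzh]) / hmax[nzh]
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - joint_ent)), 0.0, None))

    absdiff = np.abs(I - J)
    inv_var = np.zeros(na)
    offdiag = absdiff > 0
    if offdiag.any():
        inv_var = (P[:, offdiag] / (I - J)[offdiag] ** 2).sum(axis=1)

    mcc = np.empty(na)
    for a in range(na):
        present = px[a] > 0
        if present.sum() < 2:
            mcc[a] = 1.0
            continue
        sub = P[a][np.ix_(present, present)]
        pxs = sub.sum(axis=1)
        A = sub / pxs[:, None]
        B = sub / pxs[None, :]  # py == px by symmetry
        eigs = np.sort(np.real(np.linalg.eigvals(A @ B.T)))
        mcc[a] = np.sqrt(max(eigs[-2], 0.0))

    feats = {
        "Autocorrelation": auto,
        "ClusterProminence": (P * cluster**4).sum(axis=(1, 2)),
        "ClusterShade": (P * cluster**3).sum(axis=(1, 2)),
        "ClusterTendency": (P * cluster**2).sum(axis=(1, 2)),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff, axis=1),
        "DifferenceVariance": (p_diff * (kdiff[None, :] - diff_avg[:, None]) ** 2).sum(axis=1),
        "Id": (P / (1.0 + absdiff)).sum(axis=(1, 2)),
        "Idm": (P / (1.0 + absdiff**2)).sum(axis=(1, 2)),
        "Idmn": (P / (1.0 + absdiff**2 / ng**2)).sum(axis=(1, 2)),
        "Idn": (P / (1.0 + absdiff / ng)).sum(axis=(1, 2)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": (P**2).sum(axis=(1, 2)),
        "JointEntropy": joint_ent,
        "MCC": mcc,
        "MaximumProbability": P.max(axis=(1, 2)),
        "SumAverage": (p_sum * ksum).sum(axis=1),
        "SumEntropy": _entropy(p_sum, axis=1),
        "SumSquares": sigma2,
    }
    return {name: float(np.mean(vals)) for name, vals in feats.items()}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_features(R: np.ndarray, n_levels: int) -> dict[str, float]:
    """16 run-length features, averaged over valid angles.

    ``R``: (n_angles, Ng, Nr) run-count matrices.
    """
    sums = R.sum(axis=(1, 2))
    R = R[sums > 0]
    na, ng, nr = R.shape
    ivals = np.arange(1, ng + 1, dtype=float)
    rvals = np.arange(1, nr + 1, dtype=float)
    n_runs = R.sum(axis=(1, 2))
    n_vox = (R * rvals[None, None, :]).sum(axis=(1, 2))
    pg = R.sum(axis=2)  # (na, ng)
    pr = R.sum(axis=1)  # (na, nr)
    p = R / n_runs[:, None, None]
    mu_i = (p.sum(axis=2) * ivals).sum(axis=1)
    mu_r = (p.sum(axis=1) * rvals).sum(axis=1)

    i2 = ivals**2
    r2 = rvals**2
    feats = {
        "GrayLevelNonUniformity": (pg**2).sum(axis=1) / n_runs,
        "GrayLevelNonUniformityNormalized": (pg**2).sum(axis=1) / n_runs**2,
        "GrayLevelVariance": (p * ((ivals[None, :, None] - mu_i[:, None, None]) ** 2)).sum(axis=(1, 2)),
        "HighGrayLevelRunEmphasis": (pg * i2).sum(axis=1) / n_runs,
        "LongRunEmphasis": (pr * r2).sum(axis=1) / n_runs,
        "LongRunHighGrayLevelEmphasis": (R * (i2[:, None] * r2[None, :])).sum(axis=(1, 2)) / n_runs,
        "LongRunLowGrayLevelEmphasis": (R * (r2[None, :] / i2[:, None])).sum(axis=(1, 2)) / n_runs,
        "LowGrayLevelRunEmphasis": (pg / i2).sum(axis=1) / n_runs,
        "RunEntropy": _entropy(p.reshape(na, -1), axis=1),
        "RunLengthNonUniformity": (pr**2).sum(axis=1) / n_runs,
        "RunLengthNonUniformityNormalized": (pr**2).sum(axis=1) / n_runs**2,
        "RunPercentage": n_runs / n_vox,
        "RunVariance": (p * ((rvals[None, None, :] - mu_r[:, None, None]) ** 2)).sum(axis=(1, 2)),
        "ShortRunEmphasis": (pr / r2).sum(axis=1) / n_runs,
        "ShortRunHighGrayLevelEmphasis": (R * (i2[:, None] / r2[None, :])).sum(axis=(1, 2)) / n_runs,
        "ShortRunLowGrayLevelEmphasis": (R / (i2[:, None] * r2[None, :])).sum(axis=(1, 2)) / n_runs,
    }
    return {name: float(np.mean(vals)) for name, vals in feats.items()}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_features(Z: np.ndarray, n_levels: int) -> dict[str, float]:
    """16 size-zone features on the (Ng, Ns) zone-count matrix."""
    ng, ns = Z.shape
    ivals = np.arange(1, ng + 1, dtype=float)
    svals = np.arange(1, ns + 1, dtype=float)
    n_zones = Z.sum()
    n_vox = (Z * svals[None, :]).sum()
    pg = Z.sum(axis=1)
    ps = Z.sum(axis=0)
    p = Z / n_zones
    mu_i = (p.sum(axis=1) * ivals).sum()
    mu_s = (p.sum(axis=0) * svals).sum()
    i2 = ivals**2
    s2 = svals**2
    return {
        "GrayLevelNonUniformity": float((pg**2).sum() / n_zones),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / n_zones**2),
        "GrayLevelVariance": float((p * (ivals[:, None] - mu_i) ** 2).sum()),
        "HighGrayLevelZoneEmphasis": float((pg * i2).sum() / n_zones),
        "LargeAreaEmphasis": float((ps * s2).sum() / n_zones),
        "LargeAreaHighGrayLevelEmphasis": float((Z * (i2[:, None] * s2[None, :])).sum() / n_zones),
        "LargeAreaLowGrayLevelEmphasis": float((Z * (s2[None, :] / i2[:, None])).sum() / n_zones),
        "LowGrayLevelZoneEmphasis": float((pg / i2).sum() / n_zones),
        "SizeZoneNonUniformity": float((ps**2).sum() / n_zones),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum() / n_zones**2),
        "SmallAreaEmphasis": float((ps / s2).sum() / n_zones),
        "SmallAreaHighGrayLevelEmphasis": float((Z * (i2[:, None] / s2[None, :])).sum() / n_zones),
        "SmallAreaLowGrayLevelEmphasis": float((Z / (i2[:, None] * s2[None, :])).sum() / n_zones),
        "ZoneEntropy": float(_entropy(p)),
        "ZonePercentage": float(n_zones / n_vox),
        "ZoneVariance": float((p * (svals[None, :] - mu_s) ** 2).sum()),
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_features(Dm: np.ndarray, n_levels: int) -> dict[str, float]:
    """14 dependence features on the (Ng, Nd) matrix (column = dependence+1)."""
    ng, nd = Dm.shape
    ivals = np.arange(1, ng + 1, dtype=float)
    jvals = np.arange(1, nd + 1, dtype=float)
    nz = Dm.sum()
    pg = Dm.sum(axis=1)
    pd = Dm.sum(axis=0)
    p = Dm / nz
    mu_i = (p.sum(axis=1) * ivals).sum()
    mu_j = (p.sum(axis=0) * jvals).sum()
    i2 = ivals**2
    j2 = jvals**2
    return {
        "DependenceEntropy": float(_entropy(p)),
        "DependenceNonUniformity": float((pd**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / nz**2),
        "DependenceVariance": float((p * (jvals[None, :] - mu_j) ** 2).sum()),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelVariance": float((p * (ivals[:, None] - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((pg * i2).sum() / nz),
        "LargeDependenceEmphasis": float((pd * j2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((Dm * (i2[:, None] * j2[None, :])).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((Dm * (j2[None, :] / i2[:, None])).sum() / nz),
        "LowGrayLevelEmphasis": float((pg / i2).sum() / nz),
        "SmallDependenceEmphasis": float((pd / j2).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((Dm * (i2[:, None] / j2[None, :])).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((Dm / (i2[:, None] * j2[None, :])).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(n: np.ndarray, p: np.ndarray, s: np.ndarray) -> dict[str, float]:
    """5 neighbouring gray tone difference features from (n_i, p_i, s_i)."""
    present = p > 0
    iv = np.arange(1, len(p) + 1, dtype=float)[present]
    pv = p[present]
    sv = s[present]
    ngp = int(present.sum())
    nvp = n.sum()

    ps = (pv * sv).sum()
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP

    if ngp > 1 and nvp > 0:
        di = iv[:, None] - iv[None, :]
        contrast = ((pv[:, None] * pv[None, :] * di**2).sum() / (ngp * (ngp - 1))) * (sv.sum() / nvp)
        ipi = iv * pv
        busy_den = np.abs(ipi[:, None] - ipi[None, :]).sum()
        busyness = ps / busy_den if busy_den > 0 else 0.0
        pssum = pv[:, None] * sv[:, None] + pv[None, :] * sv[None, :]
        complexity = (np.abs(di) * pssum / (pv[:, None] + pv[None, :])).sum() / nvp
        ssum = sv.sum()
        strength = ((pv[:, None] + pv[None, :]) * di**2).sum() / ssum if ssum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": float(complexity),
        "Contrast": float(contrast),
        "Strength": float(strength),
    }
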