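"""The 75 three-dimensional texture features (24+14+16+16+5 by family).

Formulations follow the IBSI-aligned conventions: direction-dependent
matrices (GLCM, GLRLM) compute each feature per direction and report the
unweighted mean over the 13 directions; 0 * log(0) terms are dropped
exactly; degenerate single-gray-level ROIs yield documented sentinel
values (GLCM Correlation/MCC = 1, IMC1/IMC2 = 0, NGTDM Contrast = 0,
Coarseness capped at 1e6) rather than NaN.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .matrices import (
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_stats,
)
from .quantize import QuantizedROI, quantize

__all__ = [
    "glcm_features",
    "gldm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "extract_features",
    "FEATURE_NAMES",
    "FAMILY_COUNTS",
]

COARSENESS_CAP = 1e6

FAMILY_COUNTS = {"GLCM": 24, "GLDM": 14, "GLRLM": 16, "GLSZM": 16, "NGTDM": 5}


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 * log(0) = 0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _mcc(p: np.ndarray, px: np.ndarray) -> float:
    """Maximal correlation coefficient of one normalized GLCM."""
    present = px > 0
    if present.sum() <= 1:
        return 1.0
    sub = p[np.ix_(present, present)]
    marg = px[present]
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)); symmetric GLCM -> py = px
    q = (sub / marg[:, None]) @ (sub / marg[None, :]).T
    ev = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
    if ev.size < 2:
        return 1.0
    return float(np.sqrt(max(ev[1], 0.0)))


def glcm_features(q: QuantizedROI) -> "OrderedDict[str, float]":
    """24 co-occurrence features, averaged over the 13 directions."""
    mats = glcm_matrices(q)
    ng = q.max_level
    i = np.arange(1, ng + 1, dtype=float)
    ii = i[:, None] * np.ones((1, ng))
    jj = ii.T
    ksum = np.arange(2, 2 * ng + 1, dtype=float)
    kdiff = np.arange(0, ng, dtype=float)

    per_dir: dict[str, list[float]] = {}

    def put(name: str, value: float) -> None:
        per_dir.setdefault(name, []).append(float(value))

    for counts in mats:
        total = counts.sum()
        p = counts / total if total else counts.astype(float)
        px = p.sum(axis=1)
        ux = float(np.sum(i * px))
        sigx = float(np.sqrt(np.sum(px * (i - ux) ** 2)))
        sum_idx = (ii + jj).astype(int).ravel()
        diff_idx = np.abs(ii - jj).astype(int).ravel()
        psum = np.bincount(sum_idx, weights=p.ravel(), minlength=2 * ng + 1)[2:]
        pdiff = np.bincount(diff_idx, weights=p.ravel(), minlength=ng)[:ng]
        hx = float(-np.sum(_xlog2(px)))
        hxy = float(-np.sum(_xlog2(p)))
        pxpy = px[:, None] * px[None, :]
        mask_nz = p > 0
        hxy1 = float(-np.sum(p[mask_nz] * np.log2(pxpy[mask_nz])))
        hxy2 = float(-np.sum(_xlog2(pxpy)))

        put("GLCM_Autocorrelation", np.sum(p * ii * jj))
        put("GLCM_JointAverage", ux)
        put("GLCM_ClusterProminence", np.sum(p * (ii + jj - 2 * ux) ** 4))
        put("GLCM_ClusterShade", np.sum(p * (ii + jj - 2 * ux) ** 3))
        put("GLCM_ClusterTendency", np.sum(p * (ii + jj - 2 * ux) ** 2))
        put("GLCM_Contrast", np.sum(p * (ii - jj) ** 2))
        if sigx > 0:
            put("GLCM_Correlation", (np.sum(p * ii * jj) - ux * ux) / (sigx * sigx))
        else:
            put("GLCM_Correlation", 1.0)  # sentinel: single gray level
        da = float(np.sum(kdiff * pdiff))
        put("GLCM_DifferenceAverage", da)
        put("GLCM_DifferenceEntropy", -np.sum(_xlog2(pdiff)))
        put("GLCM_DifferenceVariance", np.sum((kdiff - da) ** 2 * pdiff))
        put("GLCM_JointEnergy", np.sum(p**2))
        put("GLCM_JointEntropy", hxy)
        # symmetric GLCM: HY equals HX
        put("GLCM_Imc1", (hxy - hxy1) / hx if hx > 0 else 0.0)
        put(
            "GLCM_Imc2",
            float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0))),
        )
        put("GLCM_Idm", np.sum(pdiff / (1.0 + kdiff**2)))
        put("GLCM_MCC", _mcc(p, px))
        put("GLCM_Idmn", np.sum(pdiff / (1.0 + (kdiff / ng) ** 2)))
        put("GLCM_Id", np.sum(pdiff / (1.0 + kdiff)))
        put("GLCM_Idn", np.sum(pdiff / (1.0 + kdiff / ng)))
        inv_var = pdiff[1:] / kdiff[1:] ** 2 if ng > 1 else np.zeros(0)
        put("GLCM_InverseVariance", inv_var.sum() if inv_var.size else 0.0)
        put("GLCM_MaximumProbability", p.max() if p.size else 0.0)
        put("GLCM_SumAverage", np.sum(ksum * psum))
        put("GLCM_SumEntropy", -np.sum(_xlog2(psum)))
        put("GLCM_SumSquares", np.sum(p * (ii - ux) ** 2))

    return OrderedDict((k, float(np.mean(v))) for k, v in per_dir.items())


def gldm_features(q: QuantizedROI, alpha: int = 0) -> "OrderedDict[str, float]":
    """14 dependence-matrix features (26-neighbourhood, tolerance alpha).

    Matrix columns index the dependent-neighbour *count* (0 for isolated
    voxels); emphasis formulas use dependence size = count + 1 so that an
    isolated voxel has size 1.
    """
    mat = gldm_matrix(q, alpha=alpha).astype(float)
    nz = mat.sum()
    p = mat / nz
    ng = mat.shape[0]
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = (np.arange(mat.shape[1], dtype=float) + 1.0)[None, :]  # dependence size

    pg = p.sum(axis=1)  # per gray level
    pd = p.sum(axis=0)  # per dependence size
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))

    out: "OrderedDict[str, float]" = OrderedDict()
    out["GLDM_SmallDependenceEmphasis"] = float(np.sum(p / j**2))
    out["GLDM_LargeDependenceEmphasis"] = float(np.sum(p * j**2))
    out["GLDM_GrayLevelNonUniformity"] = float(np.sum(mat.sum(axis=1) ** 2) / nz)
    out["GLDM_DependenceNonUniformity"] = float(np.sum(mat.sum(axis=0) ** 2) / nz)
    out["GLDM_DependenceNonUniformityNormalized"] = float(
        np.sum(mat.sum(axis=0) ** 2) / nz**2
    )
    out["GLDM_GrayLevelVariance"] = float(np.sum(p * (i - mu_i) ** 2))
    out["GLDM_DependenceVariance"] = float(np.sum(p * (j - mu_j) ** 2))
    out["GLDM_DependenceEntropy"] = float(-np.sum(_xlog2(p)))
    out["GLDM_LowGrayLevelEmphasis"] = float(np.sum(p / i**2))
    out["GLDM_HighGrayLevelEmphasis"] = float(np.sum(p * i**2))
    out["GLDM_SmallDependenceLowGrayLevelEmphasis"] = float(np.sum(p / (i**2 * j**2)))
    out["GLDM_SmallDependenceHighGrayLevelEmphasis"] = float(np.sum(p * i**2 / j**2))
    out["GLDM_LargeDependenceLowGrayLevelEmphasis"] = float(np.sum(p * j**2 / i**2))
    out["GLDM_LargeDependenceHighGrayLevelEmphasis"] = float(np.sum(p * i**2 * j**2))
    return out


def _rl_family(mat: np.ndarray, n_voxels: float, prefix: str, unit: str) -> "OrderedDict[str, float]":
    """Shared 16-feature formulas for run-length and size-zone matrices."""
    mat = mat.astype(float)
    nz = mat.sum()
    p = mat / nz if nz else mat
    ng, lmax = mat.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, lmax + 1, dtype=float)[None, :]
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))

    short, long_ = ("ShortRun", "LongRun") if unit == "Run" else ("SmallArea", "LargeArea")
    gl = "Run" if unit == "Run" else "Zone"

    out: "OrderedDict[str, float]" = OrderedDict()
    out[f"{prefix}_{short}Emphasis"] = float(np.sum(p / j**2))
    out[f"{prefix}_{long_}Emphasis"] = float(np.sum(p * j**2))
    out[f"{prefix}_GrayLevelNonUniformity"] = float(np.sum(mat.sum(axis=1) ** 2) / nz)
    out[f"{prefix}_GrayLevelNonUniformityNormalized"] = float(
        np.sum(mat.sum(axis=1) ** 2) / nz**2
    )
    nu_name = "RunLength" if unit == "Run" else "SizeZone"
    out[f"{prefix}_{nu_name}NonUniformity"] = float(np.sum(mat.sum(axis=0) ** 2) / nz)
    out[f"{prefix}_{nu_name}NonUniformityNormalized"] = float(
        np.sum(mat.sum(axis=0) ** 2) / nz**2
    )
    out[f"{prefix}_{gl}Percentage"] = float(nz / n_voxels)
    out[f"{prefix}_GrayLevelVariance"] = float(np.sum(p * (i - mu_i) ** 2))
    out[f"{prefix}_{gl}Variance"] = float(np.sum(p * (j - mu_j) ** 2))
    out[f"{prefix}_{gl}Entropy"] = float(-np.sum(_xlog2(p)))
    out[f"{prefix}_LowGrayLevel{unit}Emphasis"] = float(np.sum(p / i**2))
    out[f"{prefix}_HighGrayLevel{unit}Emphasis"] = float(np.sum(p * i**2))
    out[f"{prefix}_{short}LowGrayLevelEmphasis"] = float(np.sum(p / (i**2 * j**2)))
    out[f"{prefix}_{short}HighGrayLevelEmphasis"] = float(np.sum(p * i**2 / j**2))
    out[f"{prefix}_{long_}LowGrayLevelEmphasis"] = float(np.sum(p * j**2 / i**2))
    out[f"{prefix}_{long_}HighGrayLevelEmphasis"] = float(np.sum(p * i**2 * j**2))
    return out


def glrlm_features(q: QuantizedROI) -> "OrderedDict[str, float]":
    """16 run-length features, averaged over the 13 directions."""
    mats = glrlm_matrices(q)
    n_vox = float(q.mask.sum())
    acc: dict[str, list[float]] = {}
    for mat in mats:
        for name, value in _rl_family(mat, n_vox, "GLRLM", "Run").items():
            acc.setdefault(name, []).append(value)
    return OrderedDict((k, float(np.mean(v))) for k, v in acc.items())


def glszm_features(q: QuantizedROI) -> "OrderedDict[str, float]":
    """16 size-zone features from the single 26-connected zone matrix."""
    mat = glszm_matrix(q)
    return _rl_family(mat, float(q.mask.sum()), "GLSZM", "Zone")


def ngtdm_features(q: QuantizedROI) -> "OrderedDict[str, float]":
    """5 neighbourhood gray-tone difference features."""
    n_i, p_i, s_i, n_valid = ngtdm_stats(q)
    ng = p_i.size
    i = np.arange(1, ng + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())

    ps = float(np.sum(p_i * s_i))
    out: "OrderedDict[str, float]" = OrderedDict()
    out["NGTDM_Coarseness"] = float(1.0 / ps) if ps > 0 else COARSENESS_CAP

    if ngp > 1 and n_valid > 0:
        ip = i[present]
        pp = p_i[present]
        sp = s_i[present]
        d2 = (ip[:, None] - ip[None, :]) ** 2
        out["NGTDM_Contrast"] = float(
            np.sum(pp[:, None] * pp[None, :] * d2)
            / (ngp * (ngp - 1))
            * (s_i.sum() / n_valid)
        )
        out["NGTDM_Busyness"] = _ngtdm_busyness(ip, pp, sp)
        pairs = np.abs(ip[:, None] - ip[None, :]) * (
            (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
            / (pp[:, None] + pp[None, :])
        )
        out["NGTDM_Complexity"] = float(pairs.sum() / n_valid)
        s_tot = float(s_i.sum())
        strength = np.sum((pp[:, None] + pp[None, :]) * d2)
        out["NGTDM_Strength"] = float(strength / s_tot) if s_tot > 0 else 0.0
    else:
        out["NGTDM_Contrast"] = 0.0
        out["NGTDM_Busyness"] = 0.0
        out["NGTDM_Complexity"] = 0.0
        out["NGTDM_Strength"] = 0.0
    return out


def _ngtdm_busyness(ip: np.ndarray, pp: np.ndarray, sp: np.ndarray) -> float:
    denom = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
    if denom == 0.0:
        return 0.0
    return float(np.sum(pp * sp) / denom)


def extract_features(
    volume: np.ndarray, mask: np.ndarray, n_bins: int
) -> "OrderedDict[str, float]":
    """Quantize the ROI and compute all 75 texture features.

    No resampling and no image filters are applied; the volume is used at
    its native grid.  Feature names are namespaced by family and stable
    across calls.
    """
    q = quantize(volume, mask, n_bins)
    out: "OrderedDict[str, float]" = OrderedDict()
    out.update(glcm_features(q))
    out.update(gldm_features(q))
    out.update(glrlm_features(q))
    out.update(glszm_features(q))
    out.update(ngtdm_features(q))
    assert len(out) == 75, f"expected 75 features, got {len(out)}"
    return out


def _feature_names() -> list[str]:
    vol = np.zeros((3, 3, 3))
    vol[1, 1, 1] = 1.0
    mask = np.ones((3, 3, 3), dtype=bool)
    return list(extract_features(vol, mask, 2))


FEATURE_NAMES: list[str] = _feature_names()
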