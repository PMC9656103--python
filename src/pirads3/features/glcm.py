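"""Grey-level co-occurrence matrix (GLCM) and its 24-feature set.

Co-occurrences are counted between in-mask voxel pairs at Chebyshev distance 1
along each of the 13 unique 3D directions; each directional matrix is
symmetrized and normalized, then the matrices are averaged with equal weight
over the directions that contain at least one pair.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import QuantizedROI
from ._offsets import OFFSETS_13, shifted_pairs

__all__ = ["build_glcm", "glcm_features", "GLCM_FEATURE_NAMES"]

GLCM_FEATURE_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

_EPS = np.spacing(1.0)


def build_glcm(q: QuantizedROI) -> np.ndarray:
    """Direction-averaged symmetric joint probability matrix, shape (Ng, Ng)."""
    ng = q.n_bins
    mats = []
    for off in OFFSETS_13:
        a, b = shifted_pairs(q.labels, q.mask, off)
        if a.size == 0:
            continue
        m = np.zeros((ng, ng), dtype=np.float64)
        np.add.at(m, (a - 1, b - 1), 1.0)
        m = m + m.T
        mats.append(m / m.sum())
    if not mats:
        raise ValueError("ROI has no valid voxel pairs; GLCM undefined")
    return np.mean(mats, axis=0)


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """The 24 GLCM features from a normalized symmetric matrix.

    Degenerate single-level matrices follow the conventional limits:
    Correlation and MCC are 1, Imc1/Imc2 are 0.
    """
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # == py by symmetry
    mu = float((ii * p).sum())
    sigma2 = float(((ii - mu) ** 2 * p).sum())
    sigma = np.sqrt(sigma2)

    # sum / difference distributions
    ksum = (ii + jj).astype(int)
    kdiff = np.abs(ii - jj).astype(int)
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=ng)
    ks = np.arange(2, 2 * ng + 1, dtype=np.float64)
    kd = np.arange(0, ng, dtype=np.float64)

    diff_avg = float((kd * p_diff).sum())

    hx = -float((px * np.log2(px + _EPS)).sum())
    hxy = -float((p * np.log2(p + _EPS)).sum())
    pxpy = np.outer(px, px)
    hxy1 = -float((p * np.log2(pxpy + _EPS)).sum())
    hxy2 = -float((pxpy * np.log2(pxpy + _EPS)).sum())

    f: dict[str, float] = {}
    f["Autocorrelation"] = float((ii * jj * p).sum())
    f["JointAverage"] = mu
    f["ClusterProminence"] = float(((ii + jj - 2 * mu) ** 4 * p).sum())
    f["ClusterShade"] = float(((ii + jj - 2 * mu) ** 3 * p).sum())
    f["ClusterTendency"] = float(((ii + jj - 2 * mu) ** 2 * p).sum())
    f["Contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sigma2 > 0:
        f["Correlation"] = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    else:
        f["Correlation"] = 1.0
    f["DifferenceAverage"] = diff_avg
    f["DifferenceEntropy"] = -float((p_diff * np.log2(p_diff + _EPS)).sum())
    f["DifferenceVariance"] = float(((kd - diff_avg) ** 2 * p_diff).sum())
    f["JointEnergy"] = float((p**2).sum())
    f["JointEntropy"] = hxy
    if hx > 0:
        f["Imc1"] = (hxy - hxy1) / hx
    else:
        f["Imc1"] = 0.0
    f["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    f["Idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    f["Idmn"] = float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum())
    f["Id"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    f["Idn"] = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    off_diag = ii != jj
    with np.errstate(divide="ignore", invalid="ignore"):
        iv = np.where(off_diag, p / np.where(off_diag, (ii - jj) ** 2, 1.0), 0.0)
    f["InverseVariance"] = float(iv.sum())
    f["MaximumProbability"] = float(p.max())
    f["SumAverage"] = float((ks * p_sum).sum())
    f["SumEntropy"] = -float((p_sum * np.log2(p_sum + _EPS)).sum())
    f["SumSquares"] = sigma2
    f["MCC"] = _mcc(p, px)
    return f


def _mcc(p: np.ndarray, px: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second largest eigenvalue
    of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)), over occupied levels."""
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    psub = p[np.ix_(keep, keep)]
    pxs = px[keep]
    q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
    eig = np.linalg.eigvals(q)
    eig = np.sort(np.real(eig))[::-1]
    if eig.size < 2:
        return 1.0
    return float(np.sqrt(max(0.0, eig[1])))
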