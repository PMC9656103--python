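"""Grey-level dependence matrix (GLDM, alpha = 0) and its 14-feature set.

A neighbour at Chebyshev distance 1 is *dependent* on the centre voxel when
their grey levels are equal (equality tolerance alpha = 0). The dependence
size of a voxel is 1 + its number of dependent in-mask neighbours, so an
isolated voxel has dependence size 1.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import QuantizedROI
from ._offsets import neighbor_stack

__all__ = ["build_gldm", "gldm_features", "GLDM_FEATURE_NAMES"]

GLDM_FEATURE_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

_EPS = np.spacing(1.0)


def build_gldm(q: QuantizedROI) -> np.ndarray:
    """Dependence count matrix, shape (Ng, max_dependence_size)."""
    dep = np.zeros(q.labels.shape, dtype=np.int32)
    for nb, ok in neighbor_stack(q.labels, q.mask):
        dep += (ok & (nb == q.labels)).astype(np.int32)
    sizes = dep[q.mask] + 1
    levels = q.labels[q.mask]
    m = np.zeros((q.n_bins, int(sizes.max())), dtype=np.float64)
    np.add.at(m, (levels - 1, sizes - 1), 1.0)
    return m


def gldm_features(m: np.ndarray) -> dict[str, float]:
    ng, nd = m.shape
    iv = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    jv = np.arange(1, nd + 1, dtype=np.float64)[None, :]
    nz = m.sum()
    p = m / nz
    mu_i = (iv * p).sum()
    mu_j = (jv * p).sum()
    f = {
        "SmallDependenceEmphasis": (m / jv**2).sum() / nz,
        "LargeDependenceEmphasis": (m * jv**2).sum() / nz,
        "GrayLevelNonUniformity": (m.sum(axis=1) ** 2).sum() / nz,
        "DependenceNonUniformity": (m.sum(axis=0) ** 2).sum() / nz,
        "DependenceNonUniformityNormalized": (m.sum(axis=0) ** 2).sum() / nz**2,
        "GrayLevelVariance": (((iv - mu_i) ** 2) * p).sum(),
        "DependenceVariance": (((jv - mu_j) ** 2) * p).sum(),
        "DependenceEntropy": -(p * np.log2(p + _EPS)).sum(),
        "LowGrayLevelEmphasis": (m / iv**2).sum() / nz,
        "HighGrayLevelEmphasis": (m * iv**2).sum() / nz,
        "SmallDependenceLowGrayLevelEmphasis": (m / (iv**2 * jv**2)).sum() / nz,
        "SmallDependenceHighGrayLevelEmphasis": (m * iv**2 / jv**2).sum() / nz,
        "LargeDependenceLowGrayLevelEmphasis": (m * jv**2 / iv**2).sum() / nz,
        "LargeDependenceHighGrayLevelEmphasis": (m * iv**2 * jv**2).sum() / nz,
    }
    return {k: float(v) for k, v in f.items()}
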