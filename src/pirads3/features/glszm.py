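"""Grey-level size-zone matrix (GLSZM) and its 16-feature set.

A zone is a maximal 26-connected set of in-mask voxels sharing one grey
level. The matrix counts zones by (grey level, zone size); it is orientation
free, so no direction aggregation is involved.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..preprocess import QuantizedROI

__all__ = ["build_glszm", "glszm_features", "GLSZM_FEATURE_NAMES"]

GLSZM_FEATURE_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

_EPS = np.spacing(1.0)
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def build_glszm(q: QuantizedROI) -> np.ndarray:
    """Zone count matrix, shape (Ng, max_zone_size)."""
    ng = q.n_bins
    zones: list[tuple[int, int]] = []
    for g in range(1, ng + 1):
        comp, n_comp = ndimage.label(q.labels == g, structure=_STRUCT26)
        if n_comp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    m = np.zeros((ng, max_size), dtype=np.float64)
    for g, s in zones:
        m[g - 1, s - 1] += 1.0
    return m


def glszm_features(m: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, ns = m.shape
    iv = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    jv = np.arange(1, ns + 1, dtype=np.float64)[None, :]
    nz = m.sum()
    p = m / nz
    mu_i = (iv * p).sum()
    mu_j = (jv * p).sum()
    f = {
        "SmallAreaEmphasis": (m / jv**2).sum() / nz,
        "LargeAreaEmphasis": (m * jv**2).sum() / nz,
        "GrayLevelNonUniformity": (m.sum(axis=1) ** 2).sum() / nz,
        "GrayLevelNonUniformityNormalized": (m.sum(axis=1) ** 2).sum() / nz**2,
        "SizeZoneNonUniformity": (m.sum(axis=0) ** 2).sum() / nz,
        "SizeZoneNonUniformityNormalized": (m.sum(axis=0) ** 2).sum() / nz**2,
        "ZonePercentage": nz / n_voxels,
        "GrayLevelVariance": (((iv - mu_i) ** 2) * p).sum(),
        "ZoneVariance": (((jv - mu_j) ** 2) * p).sum(),
        "ZoneEntropy": -(p * np.log2(p + _EPS)).sum(),
        "LowGrayLevelZoneEmphasis": (m / iv**2).sum() / nz,
        "HighGrayLevelZoneEmphasis": (m * iv**2).sum() / nz,
        "SmallAreaLowGrayLevelEmphasis": (m / (iv**2 * jv**2)).sum() / nz,
        "SmallAreaHighGrayLevelEmphasis": (m * iv**2 / jv**2).sum() / nz,
        "LargeAreaLowGrayLevelEmphasis": (m * jv**2 / iv**2).sum() / nz,
        "LargeAreaHighGrayLevelEmphasis": (m * iv**2 * jv**2).sum() / nz,
    }
    return {k: float(v) for k, v in f.items()}
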