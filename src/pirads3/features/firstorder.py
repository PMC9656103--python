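"""First-order intensity statistics (18 features) of masked voxels.

Entropy and Uniformity are computed on a fixed-bin-number histogram with the
preset bin count; skewness and kurtosis use population moments (kurtosis is
not excess-corrected, so a normal sample gives ~3). Zero-variance ROIs return
0 for skewness and kurtosis.
"""

from __future__ import annotations

import numpy as np

from ..volume import ImageVolume, MaskVolume

__all__ = ["firstorder_features", "FIRSTORDER_FEATURE_NAMES"]

FIRSTORDER_FEATURE_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

_EPS = np.spacing(1.0)


def firstorder_features(
    image: ImageVolume, mask: MaskVolume, n_bins: int = 32
) -> dict[str, float]:
    if not image.same_grid(mask):
        raise ValueError("mask must share the image grid")
    v = image.voxels[mask.voxels].astype(np.float64)
    if v.size == 0:
        raise ValueError("mask is empty")
    mean = float(v.mean())
    var = float(v.var())
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]

    # FBN histogram for entropy/uniformity
    vmin, vmax = float(v.min()), float(v.max())
    if vmax > vmin:
        lab = np.minimum(
            np.floor(n_bins * (v - vmin) / (vmax - vmin)).astype(int), n_bins - 1
        )
        p = np.bincount(lab, minlength=n_bins).astype(float) / v.size
    else:
        p = np.array([1.0])

    if var > 0:
        m = v - mean
        skew = float((m**3).mean() / var**1.5)
        kurt = float((m**4).mean() / var**2)
    else:
        skew = kurt = 0.0

    energy = float((v**2).sum())
    f = {
        "Energy": energy,
        "TotalEnergy": energy * image.voxel_volume,
        "Entropy": -float((p * np.log2(p + _EPS)).sum()),
        "Minimum": vmin,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": vmax,
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": vmax - vmin,
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
    return f
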