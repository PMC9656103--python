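"""Grey-level run-length matrix (GLRLM) and its 16-feature set.

Runs are maximal straight segments of equal-label in-mask voxels along each of
the 13 unique 3D directions; out-of-mask voxels break runs. One matrix is
built per direction, features are computed per direction and averaged with
equal weight.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import QuantizedROI
from ._offsets import OFFSETS_13

__all__ = ["build_glrlm", "glrlm_features", "GLRLM_FEATURE_NAMES"]

GLRLM_FEATURE_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

_EPS = np.spacing(1.0)


def _runs_one_direction(
    labels: np.ndarray, offset: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Run labels and lengths along ``offset`` (out-of-mask label must be 0).

    Voxels are sorted lexicographically by (line identifier, position along
    the line); consecutive sorted voxels on the same line are lattice
    neighbours, so run boundaries are label changes or line changes.
    """
    shape = labels.shape
    coords = np.indices(shape).reshape(3, -1)
    d = np.asarray(offset)
    axis = int(np.nonzero(d)[0][0])
    t = coords[axis] * d[axis]
    # line id: starting point of the line through each voxel
    start = coords - t[None, :] * d[:, None]
    key = np.ravel_multi_index(
        [s - s.min() for s in start], [int(s.max() - s.min()) + 1 for s in start]
    )
    order = np.lexsort((t, key))
    lab = labels.ravel()[order]
    key_s = key[order]
    n = lab.size
    brk = np.empty(n, dtype=bool)
    brk[0] = True
    brk[1:] = (key_s[1:] != key_s[:-1]) | (lab[1:] != lab[:-1])
    run_id = np.cumsum(brk) - 1
    lengths = np.bincount(run_id)
    run_labels = lab[brk]
    in_roi = run_labels > 0
    return run_labels[in_roi], lengths[in_roi]


def build_glrlm(q: QuantizedROI) -> list[np.ndarray]:
    """Per-direction run-length count matrices, each shape (Ng, max_len)."""
    ng = q.n_bins
    out = []
    for off in OFFSETS_13:
        labs, lens = _runs_one_direction(q.labels, off)
        m = np.zeros((ng, int(lens.max())), dtype=np.float64)
        np.add.at(m, (labs - 1, lens - 1), 1.0)
        out.append(m)
    return out


def _features_one(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, nl = r.shape
    iv = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    jv = np.arange(1, nl + 1, dtype=np.float64)[None, :]
    nr = r.sum()
    pr = r / nr
    mu_i = (iv * pr).sum()
    mu_j = (jv * pr).sum()
    f = {
        "ShortRunEmphasis": (r / jv**2).sum() / nr,
        "LongRunEmphasis": (r * jv**2).sum() / nr,
        "GrayLevelNonUniformity": (r.sum(axis=1) ** 2).sum() / nr,
        "GrayLevelNonUniformityNormalized": (r.sum(axis=1) ** 2).sum() / nr**2,
        "RunLengthNonUniformity": (r.sum(axis=0) ** 2).sum() / nr,
        "RunLengthNonUniformityNormalized": (r.sum(axis=0) ** 2).sum() / nr**2,
        "RunPercentage": nr / n_voxels,
        "GrayLevelVariance": (((iv - mu_i) ** 2) * pr).sum(),
        "RunVariance": (((jv - mu_j) ** 2) * pr).sum(),
        "RunEntropy": -(pr * np.log2(pr + _EPS)).sum(),
        "LowGrayLevelRunEmphasis": (r / iv**2).sum() / nr,
        "HighGrayLevelRunEmphasis": (r * iv**2).sum() / nr,
        "ShortRunLowGrayLevelEmphasis": (r / (iv**2 * jv**2)).sum() / nr,
        "ShortRunHighGrayLevelEmphasis": (r * iv**2 / jv**2).sum() / nr,
        "LongRunLowGrayLevelEmphasis": (r * jv**2 / iv**2).sum() / nr,
        "LongRunHighGrayLevelEmphasis": (r * iv**2 * jv**2).sum() / nr,
    }
    return {k: float(v) for k, v in f.items()}


def glrlm_features(matrices: list[np.ndarray], n_voxels: int) -> dict[str, float]:
    """Feature values averaged over the 13 directional matrices."""
    per_dir = [_features_one(m, n_voxels) for m in matrices]
    return {
        name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_FEATURE_NAMES
    }
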