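"""Neighbourhood grey-tone difference matrix (NGTDM) and its 5-feature set.

For every in-mask voxel with at least one in-mask 26-neighbour, the absolute
difference between its grey level and the mean level of those neighbours is
accumulated per grey level.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import QuantizedROI
from ._offsets import neighbor_stack

__all__ = ["build_ngtdm", "ngtdm_features", "NGTDM_FEATURE_NAMES"]

NGTDM_FEATURE_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def build_ngtdm(q: QuantizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Per-level arrays (n_i, s_i): voxel counts and summed absolute
    deviations from the neighbourhood mean, each of length Ng."""
    shape = q.labels.shape
    nb_sum = np.zeros(shape, dtype=np.float64)
    nb_cnt = np.zeros(shape, dtype=np.int32)
    for nb, ok in neighbor_stack(q.labels, q.mask):
        nb_sum += np.where(ok, nb, 0)
        nb_cnt += ok.astype(np.int32)
    valid = q.mask & (nb_cnt > 0)
    levels = q.labels[valid]
    dev = np.abs(levels - nb_sum[valid] / nb_cnt[valid])
    n_i = np.bincount(levels - 1, minlength=q.n_bins).astype(np.float64)
    s_i = np.bincount(levels - 1, weights=dev, minlength=q.n_bins)
    return n_i, s_i


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    n_total = n_i.sum()
    if n_total == 0:
        raise ValueError("ROI too small for any 26-neighbourhood; NGTDM undefined")
    p = n_i / n_total
    ivals = np.arange(1, len(n_i) + 1, dtype=np.float64)
    occ = p > 0
    ngp = int(occ.sum())
    pi, ii, si = p[occ], ivals[occ], s_i[occ]

    f: dict[str, float] = {}
    denom = float((pi * si).sum())
    f["Coarseness"] = 1.0 / denom if denom > 0 else 1e6  # capped degenerate value

    if ngp > 1:
        pij2 = (
            pi[:, None] * pi[None, :] * (ii[:, None] - ii[None, :]) ** 2
        ).sum()
        f["Contrast"] = float(pij2 / (ngp * (ngp - 1)) * s_i.sum() / n_total)
    else:
        f["Contrast"] = 0.0

    busy_den = float(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum())
    f["Busyness"] = denom / busy_den if busy_den > 0 else 0.0

    comp = (
        np.abs(ii[:, None] - ii[None, :])
        * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
        / (pi[:, None] + pi[None, :])
    ).sum()
    f["Complexity"] = float(comp / n_total)

    s_total = float(s_i.sum())
    if s_total > 0:
        strength = (
            (pi[:, None] + pi[None, :]) * (ii[:, None] - ii[None, :]) ** 2
        ).sum()
        f["Strength"] = float(strength / s_total)
    else:
        f["Strength"] = 0.0
    return f
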