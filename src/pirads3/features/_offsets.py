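"""Lattice neighbourhood utilities shared by the texture-matrix builders."""

from __future__ import annotations

import itertools

import numpy as np

#: The 13 unique direction offsets of the 26-connected neighbourhood at
#: Chebyshev distance 1 (one representative per +/- pair), as (dz, dy, dx).
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off > (0, 0, 0)
)

#: All 26 neighbour offsets.
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
)


def shifted_pairs(
    labels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Label values of all in-mask voxel pairs separated by ``offset``.

    Returns two equal-length 1D arrays (a, b) with a at the base voxel and b
    at the voxel displaced by ``offset``; only pairs where both ends are in
    the mask are kept.
    """
    sl_a, sl_b = [], []
    for d, n in zip(offset, labels.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    both = mask[sl_a] & mask[sl_b]
    return labels[sl_a][both], labels[sl_b][both]


def neighbor_stack(labels: np.ndarray, mask: np.ndarray):
    """Yield, for each of the 26 offsets, (neighbor_labels, neighbor_valid).

    Both returned arrays have the full grid shape; ``neighbor_valid`` marks
    voxels whose neighbour at that offset exists and is inside the mask.
    """
    shape = labels.shape
    for off in OFFSETS_26:
        nb = np.zeros(shape, dtype=labels.dtype)
        ok = np.zeros(shape, dtype=bool)
        sl_a, sl_b = [], []
        for d, n in zip(off, shape):
            if d >= 0:
                sl_a.append(slice(0, n - d))
                sl_b.append(slice(d, n))
            else:
                sl_a.append(slice(-d, n))
                sl_b.append(slice(0, n + d))
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        nb[sl_a] = labels[sl_b]
        ok[sl_a] = mask[sl_b]
        yield nb, ok
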