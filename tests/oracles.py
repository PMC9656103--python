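"""Independent brute-force oracles for texture matrices and statistics.

Everything here is written as plain nested loops / exhaustive enumeration,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

ALL_OFFSETS = [
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
]
HALF_OFFSETS = [off for off in ALL_OFFSETS if off > (0, 0, 0)]


def glcm_bruteforce(labels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Direction-averaged GLCM by explicit enumeration of all voxel pairs."""
    shape = labels.shape
    mats = []
    for off in HALF_OFFSETS:
        m = np.zeros((n_levels, n_levels))
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if not mask[z, y, x]:
                        continue
                    z2, y2, x2 = z + off[0], y + off[1], x + off[2]
                    if not (0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2]):
                        continue
                    if not mask[z2, y2, x2]:
                        continue
                    a, b = labels[z, y, x] - 1, labels[z2, y2, x2] - 1
                    m[a, b] += 1
                    m[b, a] += 1
        if m.sum() > 0:
            mats.append(m / m.sum())
    return np.mean(mats, axis=0)


def glszm_bruteforce(labels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone inventory by breadth-first flood fill with 26-connectivity."""
    visited = np.zeros(labels.shape, dtype=bool)
    zones: list[tuple[int, int]] = []
    coords = list(zip(*np.nonzero(mask)))
    for start in coords:
        if visited[start]:
            continue
        level = labels[start]
        queue = [start]
        visited[start] = True
        size = 0
        while queue:
            v = queue.pop()
            size += 1
            for off in ALL_OFFSETS:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if not all(0 <= w[i] < labels.shape[i] for i in range(3)):
                    continue
                if visited[w] or not mask[w] or labels[w] != level:
                    continue
                visited[w] = True
                queue.append(w)
        zones.append((int(level), size))
    max_size = max(s for _, s in zones)
    m = np.zeros((n_levels, max_size))
    for g, s in zones:
        m[g - 1, s - 1] += 1
    return m


def glrlm_bruteforce(
    labels: np.ndarray, mask: np.ndarray, n_levels: int
) -> list[np.ndarray]:
    """Per-direction run inventory by walking every lattice line."""
    shape = labels.shape
    out = []
    for off in HALF_OFFSETS:
        runs: list[tuple[int, int]] = []
        counted = np.zeros(shape, dtype=bool)
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if counted[z, y, x] or not mask[z, y, x]:
                        continue
                    # walk backwards to the start of this run
                    pz, py, px = z, y, x
                    while True:
                        qz, qy, qx = pz - off[0], py - off[1], px - off[2]
                        if (
                            0 <= qz < shape[0]
                            and 0 <= qy < shape[1]
                            and 0 <= qx < shape[2]
                            and mask[qz, qy, qx]
                            and labels[qz, qy, qx] == labels[z, y, x]
                        ):
                            pz, py, px = qz, qy, qx
                        else:
                            break
                    # walk forwards, marking
                    length = 0
                    while (
                        0 <= pz < shape[0]
                        and 0 <= py < shape[1]
                        and 0 <= px < shape[2]
                        and mask[pz, py, px]
                        and labels[pz, py, px] == labels[z, y, x]
                    ):
                        counted[pz, py, px] = True
                        length += 1
                        pz, py, px = pz + off[0], py + off[1], px + off[2]
                    runs.append((int(labels[z, y, x]), length))
        max_len = max(l for _, l in runs)
        m = np.zeros((n_levels, max_len))
        for g, l in runs:
            m[g - 1, l - 1] += 1
        out.append(m)
        counted[:] = False
    return out


def gldm_bruteforce(labels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence inventory by per-voxel neighbour scanning (alpha = 0)."""
    shape = labels.shape
    entries: list[tuple[int, int]] = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                dep = 1
                for off in ALL_OFFSETS:
                    w = (z + off[0], y + off[1], x + off[2])
                    if not all(0 <= w[i] < shape[i] for i in range(3)):
                        continue
                    if mask[w] and labels[w] == labels[z, y, x]:
                        dep += 1
                entries.append((int(labels[z, y, x]), dep))
    max_dep = max(d for _, d in entries)
    m = np.zeros((n_levels, max_dep))
    for g, d in entries:
        m[g - 1, d - 1] += 1
    return m


def ngtdm_bruteforce(
    labels: np.ndarray, mask: np.ndarray, n_levels: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level counts and absolute deviations from the neighbourhood mean."""
    shape = labels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                nb = []
                for off in ALL_OFFSETS:
                    w = (z + off[0], y + off[1], x + off[2])
                    if all(0 <= w[i] < shape[i] for i in range(3)) and mask[w]:
                        nb.append(labels[w])
                if not nb:
                    continue
                g = int(labels[z, y, x])
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - float(np.mean(nb)))
    return n_i, s_i


def glcm_features_bruteforce(p: np.ndarray) -> dict[str, float]:
    """Naive double-loop evaluation of all 24 GLCM feature formulas."""
    ng = p.shape[0]
    eps = np.spacing(1.0)
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * p[i][j] for i in range(ng) for j in range(ng))
    var = sum((i + 1 - mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]
    da = sum(k * v for k, v in p_diff.items())
    hx = -sum(v * np.log2(v + eps) for v in px)
    hxy = -sum(p[i][j] * np.log2(p[i][j] + eps) for i in range(ng) for j in range(ng))
    hxy1 = -sum(
        p[i][j] * np.log2(px[i] * px[j] + eps) for i in range(ng) for j in range(ng)
    )
    hxy2 = -sum(
        px[i] * px[j] * np.log2(px[i] * px[j] + eps)
        for i in range(ng)
        for j in range(ng)
    )
    f = {}
    f["Autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)
    )
    f["JointAverage"] = mu
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3), ("ClusterTendency", 2)):
        f[name] = sum(
            (i + j + 2 - 2 * mu) ** power * p[i][j] for i in range(ng) for j in range(ng)
        )
    f["Contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    f["Correlation"] = (
        sum((i + 1 - mu) * (j + 1 - mu) * p[i][j] for i in range(ng) for j in range(ng)) / var
        if var > 0
        else 1.0
    )
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(v * np.log2(v + eps) for v in p_diff.values())
    f["DifferenceVariance"] = sum((k - da) ** 2 * v for k, v in p_diff.items())
    f["JointEnergy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    f["JointEntropy"] = hxy
    f["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    f["Imc2"] = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))
    f["Idm"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["Idmn"] = sum(
        p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
    )
    f["Id"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["Idn"] = sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    f["InverseVariance"] = sum(
        p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["MaximumProbability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    f["SumAverage"] = sum(k * v for k, v in p_sum.items())
    f["SumEntropy"] = -sum(v * np.log2(v + eps) for v in p_sum.values())
    f["SumSquares"] = var
    # MCC via the Q matrix, restricted to occupied levels
    occ = [i for i in range(ng) if px[i] > 0]
    if len(occ) < 2:
        f["MCC"] = 1.0
    else:
        q = np.zeros((len(occ), len(occ)))
        for a, i in enumerate(occ):
            for b, j in enumerate(occ):
                q[a, b] = sum(
                    p[i][k] * p[j][k] / (px[i] * px[k]) for k in occ
                )
        eig = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
        f["MCC"] = float(np.sqrt(max(0.0, eig[1])))
    return {k: float(v) for k, v in f.items()}


def mann_whitney_permutation(x, y) -> float:
    """Exact two-sided p over the full permutation distribution of U."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, m = len(x), len(y)
    center = n * m / 2.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(n + m), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2.0
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return count / total


def youden_bruteforce(values, labels):
    """Exhaustive threshold/direction search over a dense candidate grid."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    uniq = np.unique(v)
    cands = [uniq[0] - 1.0]
    cands += [(a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:])]
    cands += [uniq[-1] + 1.0]
    best_j = -np.inf
    for t in cands:
        for direction in ("above", "below"):
            pred = v > t if direction == "above" else v < t
            sens = pred[y].mean()
            spec = (~pred[~y]).mean()
            best_j = max(best_j, sens + spec - 1.0)
    return best_j
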