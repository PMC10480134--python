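"""Independent brute-force oracles for texture features and agreement.

Everything here is written as direct loop-based evaluation of the textbook
definitions — no shared code with the package's vectorized implementation.
Intended for small arrays only.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

DIRECTIONS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def _voxels(levels):
    return [v for v in product(*map(range, levels.shape)) if levels[v] > 0]


def _plog2(p):
    return p * math.log2(p) if p > 0 else 0.0


# ---------------------------------------------------------------- GLCM


def glcm_matrix_oracle(levels: np.ndarray, ng: int, direction, distance: int = 1) -> np.ndarray:
    """Symmetrized co-occurrence counts for one direction via pair enumeration."""
    M = np.zeros((ng, ng))
    off = tuple(distance * c for c in direction)
    for v in _voxels(levels):
        w = tuple(v[a] + off[a] for a in range(3))
        if _inside(levels.shape, w) and levels[w] > 0:
            M[levels[v] - 1, levels[w] - 1] += 1
            M[levels[w] - 1, levels[v] - 1] += 1
    return M


def glcm_features_oracle(levels: np.ndarray, ng: int, distance: int = 1) -> dict[str, float]:
    per_dir: list[dict[str, float]] = []
    for direction in DIRECTIONS_13:
        M = glcm_matrix_oracle(levels, ng, direction, distance)
        if M.sum() == 0:
            continue
        P = M / M.sum()
        px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
        py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
        ux = sum((i + 1) * px[i] for i in range(ng))
        uy = sum((j + 1) * py[j] for j in range(ng))
        sx2 = sum(px[i] * (i + 1 - ux) ** 2 for i in range(ng))
        p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
        p_diff = {k: 0.0 for k in range(0, ng)}
        for i in range(ng):
            for j in range(ng):
                p_sum[i + j + 2] += P[i, j]
                p_diff[abs(i - j)] += P[i, j]
        da = sum(k * p for k, p in p_diff.items())
        hxy = -sum(_plog2(P[i, j]) for i in range(ng) for j in range(ng))
        hx = -sum(_plog2(p) for p in px)
        hxy1 = -sum(
            P[i, j] * math.log2(px[i] * py[j])
            for i in range(ng)
            for j in range(ng)
            if P[i, j] > 0 and px[i] * py[j] > 0
        )
        hxy2 = -sum(
            _plog2(px[i] * py[j]) for i in range(ng) for j in range(ng)
        )
        autoc = sum((i + 1) * (j + 1) * P[i, j] for i in range(ng) for j in range(ng))
        f = {
            "glcm_Autocorrelation": autoc,
            "glcm_ClusterProminence": sum(
                (i + j + 2 - ux - uy) ** 4 * P[i, j] for i in range(ng) for j in range(ng)
            ),
            "glcm_ClusterShade": sum(
                (i + j + 2 - ux - uy) ** 3 * P[i, j] for i in range(ng) for j in range(ng)
            ),
            "glcm_ClusterTendency": sum(
                (i + j + 2 - ux - uy) ** 2 * P[i, j] for i in range(ng) for j in range(ng)
            ),
            "glcm_Contrast": sum(
                (i - j) ** 2 * P[i, j] for i in range(ng) for j in range(ng)
            ),
            "glcm_Correlation": (autoc - ux * uy) / sx2 if sx2 > 0 else 1.0,
            "glcm_DifferenceAverage": da,
            "glcm_DifferenceEntropy": -sum(_plog2(p) for p in p_diff.values()),
            "glcm_DifferenceVariance": sum(
                (k - da) ** 2 * p for k, p in p_diff.items()
            ),
            "glcm_Id": sum(
                P[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
            ),
            "glcm_Idm": sum(
                P[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
            ),
            "glcm_Idmn": sum(
                P[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
            ),
            "glcm_Idn": sum(
                P[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
            ),
            "glcm_Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
            "glcm_Imc2": math.sqrt(max(1 - math.exp(-2 * (hxy2 - hxy)), 0.0)),
            "glcm_InverseVariance": sum(
                P[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
            ),
            "glcm_JointAverage": ux,
            "glcm_JointEnergy": sum(P[i, j] ** 2 for i in range(ng) for j in range(ng)),
            "glcm_JointEntropy": hxy,
            "glcm_MCC": _mcc_oracle(P, px, py, ng),
            "glcm_MaximumProbability": P.max(),
            "glcm_SumAverage": sum(k * p for k, p in p_sum.items()),
            "glcm_SumEntropy": -sum(_plog2(p) for p in p_sum.values()),
            "glcm_SumSquares": sx2,
        }
        per_dir.append(f)
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def _mcc_oracle(P, px, py, ng):
    if ng == 1:
        return 1.0
    Q = np.zeros((ng, ng))
    for i in range(ng):
        for j in range(ng):
            Q[i, j] = sum(
                P[i, k] * P[j, k] / (px[i] * py[k])
                for k in range(ng)
                if px[i] > 0 and py[k] > 0
            )
    ev = sorted(np.real(np.linalg.eigvals(Q)))
    return math.sqrt(max(ev[-2], 0.0))


# ---------------------------------------------------------------- GLRLM


def glrlm_matrix_oracle(levels: np.ndarray, ng: int, direction) -> dict[tuple[int, int], int]:
    """Counts of maximal runs (level, length) along one direction."""
    runs: dict[tuple[int, int], int] = {}
    for v in _voxels(levels):
        prev = tuple(v[a] - direction[a] for a in range(3))
        if _inside(levels.shape, prev) and levels[prev] == levels[v]:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = tuple(cur[a] + direction[a] for a in range(3))
            if _inside(levels.shape, nxt) and levels[nxt] == levels[v] and levels[nxt] > 0:
                length += 1
                cur = nxt
            else:
                break
        key = (int(levels[v]), length)
        runs[key] = runs.get(key, 0) + 1
    return runs


def _size_family_features(counts_ij, n_p):
    """Shared run/zone/dependence style feature formulas from (i, j) -> count."""
    n = sum(counts_ij.values())
    p = {k: c / n for k, c in counts_ij.items()}
    pg: dict[int, float] = {}
    pj: dict[int, float] = {}
    for (i, j), q in p.items():
        pg[i] = pg.get(i, 0.0) + q
        pj[j] = pj.get(j, 0.0) + q
    mu_g = sum(i * q for i, q in pg.items())
    mu_j = sum(j * q for j, q in pj.items())
    gln = sum((sum(c for (i, j), c in counts_ij.items() if i == lev)) ** 2 for lev in pg) / n
    jn = sum((sum(c for (i, j), c in counts_ij.items() if j == sz)) ** 2 for sz in pj) / n
    return {
        "gln": gln,
        "glnn": sum(q**2 for q in pg.values()),
        "glv": sum(q * (i - mu_g) ** 2 for i, q in pg.items()),
        "hgl": sum(q * i**2 for i, q in pg.items()),
        "lgl": sum(q / i**2 for i, q in pg.items()),
        "long": sum(q * j**2 for j, q in pj.items()),
        "short": sum(q / j**2 for j, q in pj.items()),
        "longhigh": sum(q * i**2 * j**2 for (i, j), q in p.items()),
        "longlow": sum(q * j**2 / i**2 for (i, j), q in p.items()),
        "shorthigh": sum(q * i**2 / j**2 for (i, j), q in p.items()),
        "shortlow": sum(q / (i**2 * j**2) for (i, j), q in p.items()),
        "jn": jn,
        "jnn": sum(q**2 for q in pj.values()),
        "jv": sum(q * (j - mu_j) ** 2 for j, q in pj.items()),
        "entropy": -sum(_plog2(q) for q in p.values()),
        "pct": n / n_p,
    }


def glrlm_features_oracle(levels: np.ndarray, ng: int) -> dict[str, float]:
    n_p = len(_voxels(levels))
    per_dir = []
    for direction in DIRECTIONS_13:
        runs = glrlm_matrix_oracle(levels, ng, direction)
        g = _size_family_features(runs, n_p)
        per_dir.append(
            {
                "glrlm_GrayLevelNonUniformity": g["gln"],
                "glrlm_GrayLevelNonUniformityNormalized": g["glnn"],
                "glrlm_GrayLevelVariance": g["glv"],
                "glrlm_HighGrayLevelRunEmphasis": g["hgl"],
                "glrlm_LongRunEmphasis": g["long"],
                "glrlm_LongRunHighGrayLevelEmphasis": g["longhigh"],
                "glrlm_LongRunLowGrayLevelEmphasis": g["longlow"],
                "glrlm_LowGrayLevelRunEmphasis": g["lgl"],
                "glrlm_RunEntropy": g["entropy"],
                "glrlm_RunLengthNonUniformity": g["jn"],
                "glrlm_RunLengthNonUniformityNormalized": g["jnn"],
                "glrlm_RunPercentage": g["pct"],
                "glrlm_RunVariance": g["jv"],
                "glrlm_ShortRunEmphasis": g["short"],
                "glrlm_ShortRunHighGrayLevelEmphasis": g["shorthigh"],
                "glrlm_ShortRunLowGrayLevelEmphasis": g["shortlow"],
            }
        )
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------- GLSZM


def glszm_zones_oracle(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """(level, zone size) counts via flood fill under 26-connectivity."""
    seen = np.zeros(levels.shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for v in _voxels(levels):
        if seen[v]:
            continue
        level = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS_26:
                w = tuple(cur[a] + off[a] for a in range(3))
                if _inside(levels.shape, w) and not seen[w] and levels[w] == level:
                    seen[w] = True
                    stack.append(w)
        key = (int(level), size)
        zones[key] = zones.get(key, 0) + 1
    return zones


def glszm_features_oracle(levels: np.ndarray, ng: int) -> dict[str, float]:
    n_p = len(_voxels(levels))
    g = _size_family_features(glszm_zones_oracle(levels), n_p)
    return {
        "glszm_GrayLevelNonUniformity": g["gln"],
        "glszm_GrayLevelNonUniformityNormalized": g["glnn"],
        "glszm_GrayLevelVariance": g["glv"],
        "glszm_HighGrayLevelZoneEmphasis": g["hgl"],
        "glszm_LargeAreaEmphasis": g["long"],
        "glszm_LargeAreaHighGrayLevelEmphasis": g["longhigh"],
        "glszm_LargeAreaLowGrayLevelEmphasis": g["longlow"],
        "glszm_LowGrayLevelZoneEmphasis": g["lgl"],
        "glszm_SizeZoneNonUniformity": g["jn"],
        "glszm_SizeZoneNonUniformityNormalized": g["jnn"],
        "glszm_SmallAreaEmphasis": g["short"],
        "glszm_SmallAreaHighGrayLevelEmphasis": g["shorthigh"],
        "glszm_SmallAreaLowGrayLevelEmphasis": g["shortlow"],
        "glszm_ZoneEntropy": g["entropy"],
        "glszm_ZonePercentage": g["pct"],
        "glszm_ZoneVariance": g["jv"],
    }


# ---------------------------------------------------------------- GLDM


def gldm_dependences_oracle(levels: np.ndarray, alpha: float = 0.0, distance: int = 1):
    """(level, dependence+1) counts by explicit neighbour enumeration."""
    deps: dict[tuple[int, int], int] = {}
    offs = [
        (dx, dy, dz)
        for dx in range(-distance, distance + 1)
        for dy in range(-distance, distance + 1)
        for dz in range(-distance, distance + 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for v in _voxels(levels):
        d = 0
        for off in offs:
            w = tuple(v[a] + off[a] for a in range(3))
            if _inside(levels.shape, w) and levels[w] > 0 and abs(int(levels[w]) - int(levels[v])) <= alpha:
                d += 1
        key = (int(levels[v]), d + 1)
        deps[key] = deps.get(key, 0) + 1
    return deps


def gldm_features_oracle(levels: np.ndarray, ng: int, alpha=0.0, distance=1) -> dict[str, float]:
    n_p = len(_voxels(levels))
    g = _size_family_features(gldm_dependences_oracle(levels, alpha, distance), n_p)
    return {
        "gldm_DependenceEntropy": g["entropy"],
        "gldm_DependenceNonUniformity": g["jn"],
        "gldm_DependenceNonUniformityNormalized": g["jnn"],
        "gldm_DependenceVariance": g["jv"],
        "gldm_GrayLevelNonUniformity": g["gln"],
        "gldm_GrayLevelVariance": g["glv"],
        "gldm_HighGrayLevelEmphasis": g["hgl"],
        "gldm_LargeDependenceEmphasis": g["long"],
        "gldm_LargeDependenceHighGrayLevelEmphasis": g["longhigh"],
        "gldm_LargeDependenceLowGrayLevelEmphasis": g["longlow"],
        "gldm_LowGrayLevelEmphasis": g["lgl"],
        "gldm_SmallDependenceEmphasis": g["short"],
        "gldm_SmallDependenceHighGrayLevelEmphasis": g["shorthigh"],
        "gldm_SmallDependenceLowGrayLevelEmphasis": g["shortlow"],
    }


# ---------------------------------------------------------------- NGTDM


def ngtdm_columns_oracle(levels: np.ndarray, ng: int, distance: int = 1):
    """(n_i, s_i) per level by explicit neighbourhood means."""
    offs = [
        (dx, dy, dz)
        for dx in range(-distance, distance + 1)
        for dy in range(-distance, distance + 1)
        for dz in range(-distance, distance + 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    n = np.zeros(ng)
    s = np.zeros(ng)
    for v in _voxels(levels):
        nbrs = [
            int(levels[tuple(v[a] + off[a] for a in range(3))])
            for off in offs
            if _inside(levels.shape, tuple(v[a] + off[a] for a in range(3)))
            and levels[tuple(v[a] + off[a] for a in range(3))] > 0
        ]
        if not nbrs:
            continue
        lev = int(levels[v])
        n[lev - 1] += 1
        s[lev - 1] += abs(lev - sum(nbrs) / len(nbrs))
    return n, s


def ngtdm_features_oracle(levels: np.ndarray, ng: int, distance: int = 1) -> dict[str, float]:
    n, s = ngtdm_columns_oracle(levels, ng, distance)
    nvp = n.sum()
    cap = 1e6
    if nvp == 0:
        return dict(
            ngtdm_Busyness=0.0, ngtdm_Coarseness=cap, ngtdm_Complexity=0.0,
            ngtdm_Contrast=0.0, ngtdm_Strength=0.0,
        )
    p = n / nvp
    occ = [i for i in range(ng) if p[i] > 0]
    ngp = len(occ)
    ps = sum(p[i] * s[i] for i in occ)
    coars = 1.0 / ps if ps > 0 else cap
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ) / (ngp * (ngp - 1))
        ) * (s.sum() / nvp)
        bden = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in occ for j in occ)
        busy = ps / bden if bden > 0 else 0.0
        compl = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in occ for j in occ
        ) / nvp
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in occ for j in occ) / s.sum()
            if s.sum() > 0 else 0.0
        )
    else:
        contrast = busy = compl = strength = 0.0
    return {
        "ngtdm_Busyness": busy,
        "ngtdm_Coarseness": min(coars, cap),
        "ngtdm_Complexity": compl,
        "ngtdm_Contrast": contrast,
        "ngtdm_Strength": strength,
    }


# ---------------------------------------------------------------- agreement


def lin_ccc_oracle(x, y) -> float:
    """Direct evaluation of Lin's formula with explicit sums (1/n moments)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = sum((v - mx) ** 2 for v in x) / n
    sy = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx + sy + (mx - my) ** 2)


def occc_oracle(mat) -> float:
    """Direct evaluation of the overall CCC with brute-force sums."""
    mat = [list(row) for row in mat]
    n = len(mat)
    J = len(mat[0])
    mu = [sum(row[j] for row in mat) / n for j in range(J)]
    var = [sum((row[j] - mu[j]) ** 2 for row in mat) / n for j in range(J)]
    num = 0.0
    pen = 0.0
    for j in range(J):
        for k in range(j + 1, J):
            cov = sum((row[j] - mu[j]) * (row[k] - mu[k]) for row in mat) / n
            num += 2 * cov
            pen += (mu[j] - mu[k]) ** 2
    return num / ((J - 1) * sum(var) + pen)
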