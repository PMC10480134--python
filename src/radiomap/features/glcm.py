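"""Gray level co-occurrence matrix (GLCM) features.

Co-occurrences are counted over the 13 unique 3-D direction vectors at a
given Chebyshev distance; both voxels of a pair must lie inside the mask.
Each per-direction matrix is symmetrized and normalized, the 24 features
are evaluated per direction, and the direction average is returned
(feature-level averaging aggregation).  Directions yielding no voxel pair
(possible for thin ROIs) are dropped from the average.

Degenerate rules: correlation-type features return 1 when the gray-level
variance is 0; entropy terms use 0*log 0 = 0; logs are base 2.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ._util import UNIT_DIRECTIONS, pair_slices, xlog2x
from .discretize import DiscretizedRoi
from .matrices import TextureMatrix

__all__ = ["GLCM_NAMES", "build_glcm", "glcm_features"]

GLCM_NAMES: tuple[str, ...] = (
    "glcm_Autocorrelation",
    "glcm_ClusterProminence",
    "glcm_ClusterShade",
    "glcm_ClusterTendency",
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_DifferenceAverage",
    "glcm_DifferenceEntropy",
    "glcm_DifferenceVariance",
    "glcm_Id",
    "glcm_Idm",
    "glcm_Idmn",
    "glcm_Idn",
    "glcm_Imc1",
    "glcm_Imc2",
    "glcm_InverseVariance",
    "glcm_JointAverage",
    "glcm_JointEnergy",
    "glcm_JointEntropy",
    "glcm_MCC",
    "glcm_MaximumProbability",
    "glcm_SumAverage",
    "glcm_SumEntropy",
    "glcm_SumSquares",
)


def build_glcm(droi: DiscretizedRoi, distance: int = 1) -> TextureMatrix:
    """Symmetrized per-direction co-occurrence counts, shape (n_dirs, Ng, Ng).

    Directions without any in-mask pair are omitted from the stack.
    """
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    ng = droi.n_levels
    lev = droi.levels
    stacks = []
    for d in UNIT_DIRECTIONS:
        off = tuple(distance * c for c in d)
        sl = pair_slices(lev.shape, off)
        if sl is None:
            continue
        a, b = lev[sl[0]], lev[sl[1]]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        counts = np.bincount(
            (a[valid] - 1) * ng + (b[valid] - 1), minlength=ng * ng
        ).reshape(ng, ng)
        stacks.append(counts + counts.T)
    if not stacks:
        raise ValueError("no co-occurring voxel pair in any direction")
    return TextureMatrix("GLCM", np.stack(stacks).astype(float))


@lru_cache(maxsize=64)
class _Weights:
    """Static index grids and scatter matrices for one gray-level count."""

    def __init__(self, ng: int) -> None:
        i = np.arange(1, ng + 1, dtype=float)
        ii = np.repeat(i, ng).reshape(ng, ng)
        jj = ii.T
        diff = ii - jj
        self.i = i
        self.prod = (ii * jj).ravel()
        self.sum2 = (ii + jj).ravel()
        self.diff2 = (diff**2).ravel()
        self.inv_id = (1.0 / (1.0 + np.abs(diff))).ravel()
        self.inv_idm = (1.0 / (1.0 + diff**2)).ravel()
        self.inv_idmn = (1.0 / (1.0 + diff**2 / ng**2)).ravel()
        self.inv_idn = (1.0 / (1.0 + np.abs(diff) / ng)).ravel()
        offdiag = diff != 0
        self.inv_var = np.where(offdiag, 1.0 / np.where(offdiag, diff**2, 1.0), 0.0).ravel()
        # one-hot scatter matrices mapping flat (i,j) to the i+j / |i-j| bands
        sum_idx = (ii + jj).astype(int).ravel() - 2  # 0 .. 2Ng-2
        diff_idx = np.abs(diff).astype(int).ravel()  # 0 .. Ng-1
        self.scatter_sum = np.zeros((ng * ng, 2 * ng - 1))
        self.scatter_sum[np.arange(ng * ng), sum_idx] = 1.0
        self.scatter_diff = np.zeros((ng * ng, ng))
        self.scatter_diff[np.arange(ng * ng), diff_idx] = 1.0
        self.k_sum = np.arange(2, 2 * ng + 1, dtype=float)
        self.k_diff = np.arange(0, ng, dtype=float)


def glcm_features(droi: DiscretizedRoi, distance: int = 1) -> dict[str, float]:
    ng = droi.n_levels
    P = build_glcm(droi, distance).normalize().entries  # (D, Ng, Ng)
    w = _Weights(ng)
    i = w.i
    Pf = P.reshape(P.shape[0], -1)  # (D, Ng*Ng)

    px = P.sum(axis=2)  # (D, Ng); symmetric => py == px
    ux = (px * i).sum(axis=1)  # (D,)
    sx2 = (px * (i[None, :] - ux[:, None]) ** 2).sum(axis=1)

    # diagonal-band marginals p_{x+y}, p_{x-y}
    p_sum = Pf @ w.scatter_sum
    p_diff = Pf @ w.scatter_diff
    k_sum, k_diff = w.k_sum, w.k_diff

    autoc = Pf @ w.prod
    contrast = Pf @ w.diff2
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(sx2 > 0, (autoc - ux**2) / sx2, 1.0)
    da = (p_diff * k_diff).sum(axis=1)
    dent = -xlog2x(p_diff).sum(axis=1)
    dvar = (p_diff * (k_diff[None, :] - da[:, None]) ** 2).sum(axis=1)
    idf = Pf @ w.inv_id
    idm = Pf @ w.inv_idm
    idmn = Pf @ w.inv_idmn
    idn = Pf @ w.inv_idn
    invvar = Pf @ w.inv_var
    hxy = -xlog2x(P).sum(axis=(1, 2))
    hx = -xlog2x(px).sum(axis=1)
    pxpy = px[:, :, None] * px[:, None, :]
    log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = -(P * log_pxpy).sum(axis=(1, 2))
    hxy2 = -xlog2x(pxpy).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        imc1 = np.where(hx > 0, (hxy - hxy1) / hx, 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))
    jene = (Pf**2).sum(axis=1)
    maxp = Pf.max(axis=1)
    savg = (p_sum * k_sum).sum(axis=1)
    sent = -xlog2x(p_sum).sum(axis=1)
    cdev = w.sum2[None, :] - 2 * ux[:, None]
    c2 = Pf * cdev**2
    ctend = c2.sum(axis=1)
    cshade = (c2 * cdev).sum(axis=1)
    cprom = (c2 * cdev**2).sum(axis=1)

    n_dirs = P.shape[0]
    mcc = np.empty(n_dirs)
    for d in range(n_dirs):
        mcc[d] = _mcc(P[d], px[d])

    feats = {
        "glcm_Autocorrelation": autoc,
        "glcm_ClusterProminence": cprom,
        "glcm_ClusterShade": cshade,
        "glcm_ClusterTendency": ctend,
        "glcm_Contrast": contrast,
        "glcm_Correlation": corr,
        "glcm_DifferenceAverage": da,
        "glcm_DifferenceEntropy": dent,
        "glcm_DifferenceVariance": dvar,
        "glcm_Id": idf,
        "glcm_Idm": idm,
        "glcm_Idmn": idmn,
        "glcm_Idn": idn,
        "glcm_Imc1": imc1,
        "glcm_Imc2": imc2,
        "glcm_InverseVariance": invvar,
        "glcm_JointAverage": ux,
        "glcm_JointEnergy": jene,
        "glcm_JointEntropy": hxy,
        "glcm_MCC": mcc,
        "glcm_MaximumProbability": maxp,
        "glcm_SumAverage": savg,
        "glcm_SumEntropy": sent,
        "glcm_SumSquares": sx2,
    }
    return {k: float(v.mean()) for k, v in feats.items()}


def _mcc(P: np.ndarray, px: np.ndarray) -> float:
    """Maximal correlation coefficient of one normalized GLCM."""
    ng = P.shape[0]
    if ng == 1:
        return 1.0
    pos = px > 0
    A = np.zeros_like(P)
    A[pos] = P[pos] / px[pos, None]  # row-normalized
    B = np.zeros_like(P)
    B[:, pos] = P[:, pos] / px[None, pos]  # column-normalized (py == px)
    Q = A @ B.T
    if ng == 2:
        # Q is row-stochastic: top eigenvalue 1, second = trace - 1
        return float(np.sqrt(max(Q[0, 0] + Q[1, 1] - 1.0, 0.0)))
    ev = np.sort(np.real(np.linalg.eigvals(Q)))
    return float(np.sqrt(max(ev[-2], 0.0)))
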