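"""Gray level run-length matrix (GLRLM) features.

Maximal runs of equal gray level are counted along each of the 13 unique
3-D directions (the two orientations of a direction describe the same run,
counted once).  The 16 features are computed per direction on the
normalized matrix and averaged over directions.
"""

from __future__ import annotations

import numpy as np

from ._util import UNIT_DIRECTIONS, pair_slices, xlog2x
from .discretize import DiscretizedRoi
from .matrices import TextureMatrix

__all__ = ["GLRLM_NAMES", "build_glrlm", "glrlm_features"]

GLRLM_NAMES: tuple[str, ...] = (
    "glrlm_GrayLevelNonUniformity",
    "glrlm_GrayLevelNonUniformityNormalized",
    "glrlm_GrayLevelVariance",
    "glrlm_HighGrayLevelRunEmphasis",
    "glrlm_LongRunEmphasis",
    "glrlm_LongRunHighGrayLevelEmphasis",
    "glrlm_LongRunLowGrayLevelEmphasis",
    "glrlm_LowGrayLevelRunEmphasis",
    "glrlm_RunEntropy",
    "glrlm_RunLengthNonUniformity",
    "glrlm_RunLengthNonUniformityNormalized",
    "glrlm_RunPercentage",
    "glrlm_RunVariance",
    "glrlm_ShortRunEmphasis",
    "glrlm_ShortRunHighGrayLevelEmphasis",
    "glrlm_ShortRunLowGrayLevelEmphasis",
)


def _runs_one_direction(lev: np.ndarray, ng: int, off: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts R(level, length) along one direction, shape (Ng, Lmax)."""
    inmask = lev > 0
    sl = pair_slices(lev.shape, off)
    if sl is None:  # offset exceeds the extent: every voxel is a length-1 run
        return np.bincount(lev[inmask], minlength=ng + 1)[1:].reshape(ng, 1)
    # chain[v]: v and its successor v+off are both in-mask with equal level
    chain = np.zeros(lev.shape, dtype=bool)
    sa, sb = sl
    chain[sa] = inmask[sa] & inmask[sb] & (lev[sa] == lev[sb])
    # run starts: in-mask voxels with no same-level predecessor at v-off
    start = inmask.copy()
    start[sb] &= ~chain[sa]
    # walk every run from its start; a walker at v continues iff chain[v]
    counts = []  # counts[L-1] = per-level histogram of runs of exact length L
    cur = start
    while cur.any():
        ended = cur & ~chain
        counts.append(np.bincount(lev[ended], minlength=ng + 1)[1:])
        adv = np.zeros(lev.shape, dtype=bool)
        adv[sb] = cur[sa] & chain[sa]
        cur = adv
    return np.stack(counts, axis=1)  # (Ng, Lmax)


def build_glrlm(droi: DiscretizedRoi) -> TextureMatrix:
    """Per-direction run-length counts, shape (13, Ng, Lmax)."""
    ng = droi.n_levels
    mats = [_runs_one_direction(droi.levels, ng, d) for d in UNIT_DIRECTIONS]
    lmax = max(m.shape[1] for m in mats)
    stack = np.zeros((len(mats), ng, lmax))
    for k, m in enumerate(mats):
        stack[k, :, : m.shape[1]] = m
    return TextureMatrix("GLRLM", stack)


def glrlm_features(droi: DiscretizedRoi) -> dict[str, float]:
    R = build_glrlm(droi).entries  # (13, Ng, Lmax) raw counts
    n_p = droi.n_voxels
    ng, lmax = R.shape[1], R.shape[2]
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, lmax + 1, dtype=float)
    nr = R.sum(axis=(1, 2))  # runs per direction; > 0 whenever mask nonempty
    p = R / nr[:, None, None]
    pg = p.sum(axis=2)  # (13, Ng)
    pr = p.sum(axis=1)  # (13, Lmax)
    mu_g = (pg * i).sum(axis=1)
    mu_r = (pr * j).sum(axis=1)

    feats = {
        "glrlm_GrayLevelNonUniformity": (R.sum(axis=2) ** 2).sum(axis=1) / nr,
        "glrlm_GrayLevelNonUniformityNormalized": (pg**2).sum(axis=1),
        "glrlm_GrayLevelVariance": (pg * (i[None, :] - mu_g[:, None]) ** 2).sum(axis=1),
        "glrlm_HighGrayLevelRunEmphasis": (pg * i**2).sum(axis=1),
        "glrlm_LongRunEmphasis": (pr * j**2).sum(axis=1),
        "glrlm_LongRunHighGrayLevelEmphasis": (p * (i[:, None] ** 2 * j[None, :] ** 2)).sum(
            axis=(1, 2)
        ),
        "glrlm_LongRunLowGrayLevelEmphasis": (p * (j[None, :] ** 2 / i[:, None] ** 2)).sum(
            axis=(1, 2)
        ),
        "glrlm_LowGrayLevelRunEmphasis": (pg / i**2).sum(axis=1),
        "glrlm_RunEntropy": -xlog2x(p).sum(axis=(1, 2)),
        "glrlm_RunLengthNonUniformity": (R.sum(axis=1) ** 2).sum(axis=1) / nr,
        "glrlm_RunLengthNonUniformityNormalized": (pr**2).sum(axis=1),
        "glrlm_RunPercentage": nr / n_p,
        "glrlm_RunVariance": (pr * (j[None, :] - mu_r[:, None]) ** 2).sum(axis=1),
        "glrlm_ShortRunEmphasis": (pr / j**2).sum(axis=1),
        "glrlm_ShortRunHighGrayLevelEmphasis": (p * (i[:, None] ** 2 / j[None, :] ** 2)).sum(
            axis=(1, 2)
        ),
        "glrlm_ShortRunLowGrayLevelEmphasis": (p / (i[:, None] ** 2 * j[None, :] ** 2)).sum(
            axis=(1, 2)
        ),
    }
    return {k: float(v.mean()) for k, v in feats.items()}
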