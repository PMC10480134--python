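"""Concordance correlation: Lin's CCC and the overall CCC (OCCC).

Lin's concordance correlation coefficient for two measurement methods is

    rho_c = 2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2),

penalizing both poor correlation and location/scale shift.  The overall
CCC generalizes it to J >= 2 methods:

    rho_o = 2 * sum_{j<k} cov_jk
            / [ (J-1) * sum_j var_j + sum_{j<k} (mu_j - mu_k)^2 ]

and equals the weighted average of the pairwise CCCs with weights
var_j + var_k + (mu_j - mu_k)^2.  Moments use the population (1/n)
denominator by default, matching Lin's original estimator; ``ddof=1``
reproduces the sample-moment convention of common epidemiology packages.

A feature is classified reproducible across VOI sizes when its OCCC is at
least the stability threshold (default 0.85, boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["AgreementResult", "lin_ccc", "occc", "classify", "STABILITY_THRESHOLD"]

STABILITY_THRESHOLD = 0.85


@dataclass
class AgreementResult:
    """Per-feature multi-method agreement summary."""

    occc: float
    pairwise_ccc: dict[tuple[str, str], float]
    means: np.ndarray
    variances: np.ndarray
    covariances: np.ndarray
    n_used: int
    threshold: float = STABILITY_THRESHOLD
    labels: tuple[str, ...] = field(default_factory=tuple)

    @property
    def stable(self) -> bool:
        return classify(self.occc, self.threshold)


def _moments(x: np.ndarray, y: np.ndarray, ddof: int):
    n = x.size
    mx, my = x.mean(), y.mean()
    sxy = ((x - mx) * (y - my)).sum() / (n - ddof)
    sx = ((x - mx) ** 2).sum() / (n - ddof)
    sy = ((y - my) ** 2).sum() / (n - ddof)
    return mx, my, sx, sy, sxy


def lin_ccc(x, y, ddof: int = 0) -> float:
    """Lin's concordance correlation coefficient of two paired vectors.

    Identical constant vectors score 1 (perfect agreement with no spread);
    a zero denominator with non-identical vectors is an error.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    mx, my, sx, sy, sxy = _moments(x, y, ddof)
    den = sx + sy + (mx - my) ** 2
    if den == 0:
        if np.array_equal(x, y):
            return 1.0
        raise ZeroDivisionError("degenerate CCC: both variances 0 with equal means")
    return float(2 * sxy / den)


def occc(values, labels: tuple[str, ...] | None = None, threshold: float = STABILITY_THRESHOLD,
         ddof: int = 0) -> AgreementResult:
    """Overall CCC of an n_subjects x J matrix (columns = methods).

    Rows containing non-finite entries are dropped listwise (``n_used``
    reports the retained count); the OCCC needs complete rows.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be an n_subjects x J matrix")
    n0, J = values.shape
    if J < 2:
        raise ValueError("need J >= 2 methods")
    keep = np.isfinite(values).all(axis=1)
    values = values[keep]
    n = values.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 complete subjects, have {n} of {n0}")
    if labels is None:
        labels = tuple(f"m{j}" for j in range(J))
    mu = values.mean(axis=0)
    centered = values - mu
    cov = centered.T @ centered / (n - ddof)
    var = np.diag(cov)

    num = 2 * sum(cov[j, k] for j, k in combinations(range(J), 2))
    den = (J - 1) * var.sum() + sum(
        (mu[j] - mu[k]) ** 2 for j, k in combinations(range(J), 2)
    )
    if den == 0:
        if all(np.array_equal(values[:, 0], values[:, j]) for j in range(1, J)):
            rho_o = 1.0
        else:
            raise ZeroDivisionError("degenerate OCCC: all variances 0 with equal means")
    else:
        rho_o = float(num / den)

    pairwise = {
        (labels[j], labels[k]): lin_ccc(values[:, j], values[:, k], ddof=ddof)
        for j, k in combinations(range(J), 2)
    }
    return AgreementResult(
        occc=rho_o,
        pairwise_ccc=pairwise,
        means=mu,
        variances=var.copy(),
        covariances=cov,
        n_used=n,
        threshold=threshold,
        labels=tuple(labels),
    )


def classify(occc_value: float, threshold: float = STABILITY_THRESHOLD) -> bool:
    """Reproducibility rule: stable iff OCCC >= threshold (inclusive)."""
    return bool(occc_value >= threshold)
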