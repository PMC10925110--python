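"""Reference global tests: Bonferroni min-p, Simes, ΣZ², and CPMA.

All are calibrated by the same Monte Carlo empirical-null machinery as the
ADELLE statistic; ``ORIENTATION`` records whether a small or a large value
of each statistic is extreme.
"""

from __future__ import annotations

import numpy as np

from .ell_core import two_sided_pvalues

__all__ = [
    "ORIENTATION",
    "minp_statistic",
    "simes_statistic",
    "sumz2_statistic",
    "cpma_statistic",
    "competitor_statistics_batch",
]

# True: small statistic is extreme (p-value-like); False: large is extreme.
ORIENTATION = {"adelle": True, "ell": True, "minp": True, "simes": True,
               "sumz2": False, "cpma": False}


def minp_statistic(zvec: np.ndarray) -> float:
    """Bonferroni-corrected minimum two-sided p-value, capped at 1."""
    p = two_sided_pvalues(zvec)
    return float(min(p.shape[0] * p.min(), 1.0))


def simes_statistic(zvec: np.ndarray) -> float:
    """min_i p(i)·D/i over the sorted two-sided p-values."""
    p = np.sort(two_sided_pvalues(zvec))
    d = p.shape[0]
    return float(np.min(p * d / np.arange(1, d + 1)))


def sumz2_statistic(zvec: np.ndarray) -> float:
    z = np.asarray(zvec, dtype=float)
    return float(z @ z)


def cpma_statistic(zvec: np.ndarray) -> float:
    """Likelihood-ratio test that −log p deviates from unit-rate exponential.

    With x_d = −log π_d and MLE λ̂ = 1/x̄, twice the log-likelihood ratio of
    Exp(λ̂) against Exp(1) is 2D(x̄ − 1 − log x̄).  Implemented unsigned; the
    empirical-null calibration makes the signed variant unnecessary.
    """
    p = two_sided_pvalues(zvec)
    if np.any(p <= 0):
        raise ValueError("p-values must be positive")
    xbar = max(float(np.mean(-np.log(p))), np.finfo(float).tiny)
    return float(2.0 * p.shape[0] * (xbar - 1.0 - np.log(xbar)))


def competitor_statistics_batch(z_block: np.ndarray,
                                sorted_p: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """All four statistics for each column of a (D, n) Z block."""
    d = z_block.shape[0]
    sumz2 = np.einsum("ij,ij->j", z_block, z_block)
    p = two_sided_pvalues(z_block)
    xbar = np.maximum(np.mean(-np.log(p), axis=0), np.finfo(float).tiny)
    cpma = 2.0 * d * (xbar - 1.0 - np.log(xbar))
    if sorted_p is None:
        sorted_p = np.sort(p, axis=0)
    minp = np.minimum(d * sorted_p[0], 1.0)
    simes = np.min(sorted_p * (d / np.arange(1, d + 1))[:, None], axis=0)
    return {"minp": minp, "simes": simes, "sumz2": sumz2, "cpma": cpma}
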