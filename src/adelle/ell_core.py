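"""Equal-local-levels (ELL) machinery for independent traits.

Under the global null with D independent, well-calibrated tests, the sorted
two-sided p-values π(1) ≤ … ≤ π(D) have Beta(d, D−d+1) marginals.  Each
order statistic is converted to an "l-value" — its own one-sided p-value
against that beta law — and the test statistic is the minimum l-value over
the smallest fraction q of order statistics (q = 0.2 by default: only a
small share of traits is expected to respond to a trans-eQTL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "DEFAULT_Q",
    "PValueVector",
    "LValueResult",
    "two_sided_pvalues",
    "order_statistics",
    "lvalues_independent",
    "ell_statistic",
    "ell_null_statistics",
    "ell_local_level",
]

DEFAULT_Q = 0.2
_TINY = np.finfo(float).tiny


@dataclass
class PValueVector:
    p: np.ndarray
    d: int
    q: float = DEFAULT_Q

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.d,):
            raise ValueError("p must have length D")
        if np.any((self.p <= 0) | (self.p > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        if not 0 < self.q < 1 or n_lvalues(self.d, self.q) < 1:
            raise ValueError("need floor(qD) >= 1 with q in (0, 1)")


@dataclass
class LValueResult:
    lvalues: np.ndarray
    argmin_d: int  # 1-based index d attaining the minimum
    statistic: float


def n_lvalues(d: int, q: float) -> int:
    return int(np.floor(q * d))


def two_sided_pvalues(zvec: np.ndarray) -> np.ndarray:
    """π_d = 2Φ(−|z_d|) on an underflow-safe path (erfc), clamped > 0.

    The statistic downstream is a minimum, so a p-value underflowing to an
    exact 0 would create spurious ties; the clamp keeps |z| up to ~38 useful.
    """
    z = np.asarray(zvec, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("Z scores must be finite")
    p = special.erfc(np.abs(z) / np.sqrt(2.0))
    return np.clip(p, _TINY, 1.0)


def order_statistics(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ascending sort with a stable permutation (ties keep original order)."""
    p = np.asarray(p, dtype=float)
    perm = np.argsort(p, kind="stable")
    return p[perm], perm


def lvalues_independent(sorted_p: np.ndarray, d: int, q: float = DEFAULT_Q) -> LValueResult:
    """l_d = pbeta(π(d); d, D−d+1) for d = 1..floor(qD); statistic = min l_d."""
    sorted_p = np.asarray(sorted_p, dtype=float)
    if sorted_p.shape != (d,):
        raise ValueError("sorted_p must have length D")
    if np.any(np.diff(sorted_p) < 0):
        raise ValueError("input p-values are not sorted ascending")
    m = n_lvalues(d, q)
    if m < 1:
        raise ValueError("floor(qD) must be at least 1")
    dd = np.arange(1, m + 1, dtype=float)
    lv = special.betainc(dd, d - dd + 1.0, sorted_p[:m])
    arg = int(np.argmin(lv))  # ties -> smallest d
    return LValueResult(lvalues=lv, argmin_d=arg + 1, statistic=float(lv[arg]))


def ell_statistic(zvec: np.ndarray, q: float = DEFAULT_Q) -> LValueResult:
    """T_ELL for a Z-score vector under the independence null."""
    p = two_sided_pvalues(zvec)
    sp, _ = order_statistics(p)
    return lvalues_independent(sp, p.shape[0], q)


def _batch_lvalue_min(sorted_top: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    m = sorted_top.shape[0]
    dd = np.arange(1, m + 1, dtype=float)[:, None]
    lv = special.betainc(dd, d - dd + 1.0, sorted_top)
    arg = np.argmin(lv, axis=0)
    return lv[arg, np.arange(lv.shape[1])], arg + 1


def ell_null_statistics(d: int, q: float, n_rep: int, seed: int,
                        block: int = 4096) -> np.ndarray:
    """Monte Carlo null T_ELL replicates from i.i.d. Uniform(0,1) vectors.

    Replaces an exact recursion for the independence-case level map α(η):
    the Monte Carlo route matches the dependent-case calibration pathway.
    Returned sorted ascending.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m = n_lvalues(d, q)
    out = np.empty(n_rep)
    for start in range(0, n_rep, block):
        stop = min(start + block, n_rep)
        u = rng.random((d, stop - start))
        u.sort(axis=0)
        out[start:stop], _ = _batch_lvalue_min(u[:m], d)
    return np.sort(out)


def ell_local_level(alpha: float, d: int, q: float = DEFAULT_Q,
                    n_rep: int = 100_000, seed: int = 0) -> float:
    """η such that P(T_ELL < η) ≈ α under the independence null."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    nulls = ell_null_statistics(d, q, n_rep, seed)
    return float(np.quantile(nulls, alpha))
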