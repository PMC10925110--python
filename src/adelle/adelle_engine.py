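"""Per-SNP ADELLE statistics and Monte Carlo significance.

The statistic for a SNP is the minimum dependent-null l-value over the
floor(qD) smallest order statistics of its trans-trait p-values.  Its null
distribution has no usable closed form, so significance is assessed against
R simulated null vectors Z̃ ~ N(0, Ω̂), drawn through the low-rank sampling
structure of the correlation estimate, and reported as the rank-based
empirical p-value (N(T)+1)/(R+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .competitors import ORIENTATION, competitor_statistics_batch
from .count_model import LValueGrid, precompute_lvalue_grid
from .covariance import CorrelationEstimate
from .ell_core import two_sided_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "GlobalTestResult",
    "adelle_statistic",
    "adelle_statistics_batch",
    "study_statistics_batch",
    "sample_null_statistics",
    "empirical_pvalue",
    "run_scan",
]

_BLOCK = 2048


@dataclass
class GlobalTestResult:
    snp_id: str
    d_m: int
    statistic: float
    pvalue: float
    argmin_d: int | None
    n_null_replicates: int
    method: str = "adelle"


def adelle_statistic(zvec: np.ndarray, grid: LValueGrid) -> tuple[float, int]:
    """T_ADELLE = min_{1≤d≤qD} l_d and the 1-based argmin (ties -> smallest d)."""
    z = np.asarray(zvec, dtype=float)
    if z.shape[0] != grid.d:
        raise ValueError(f"Z vector length {z.shape[0]} != grid dimension {grid.d}")
    p = np.sort(two_sided_pvalues(z))
    t, arg = grid.batch_min_lvalue(p[: grid.m, None])
    return float(t[0]), int(arg[0])


def adelle_statistics_batch(z_block: np.ndarray, grid: LValueGrid,
                            sorted_p: np.ndarray | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Statistics for each column of a (D, n) Z block."""
    if sorted_p is None:
        sorted_p = np.sort(two_sided_pvalues(z_block), axis=0)
    return grid.batch_min_lvalue(sorted_p[: grid.m])


def study_statistics_batch(z_block: np.ndarray, grid: LValueGrid,
                           methods: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Shared-computation evaluation of several global statistics per column."""
    p_sorted = np.sort(two_sided_pvalues(z_block), axis=0)
    out: dict[str, np.ndarray] = {}
    need_comp = [m for m in methods if m in {"minp", "simes", "sumz2", "cpma"}]
    if need_comp:
        comp = competitor_statistics_batch(z_block, sorted_p=p_sorted)
        out.update({m: comp[m] for m in need_comp})
    if "adelle" in methods or "ell" in methods:
        t, _ = adelle_statistics_batch(z_block, grid, sorted_p=p_sorted)
        if "adelle" in methods:
            out["adelle"] = t
        if "ell" in methods:
            out["ell"] = t
    return out


def sample_null_statistics(
    omega_estimate: CorrelationEstimate,
    grid: LValueGrid,
    n_replicates: int,
    seed: int | np.random.SeedSequence,
    methods: tuple[str, ...] = ("adelle",),
    block: int = _BLOCK,
) -> dict[str, np.ndarray]:
    """Sorted null statistics from R i.i.d. Z̃ ~ N(0, Ω̂) replicates.

    A single seed expands to per-block seeds through a SeedSequence so the
    stream is independent of block size and scheduling.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    n_blocks = (n_replicates + block - 1) // block
    child = ss.spawn(n_blocks)
    parts: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    done = 0
    for b in range(n_blocks):
        nb = min(block, n_replicates - done)
        rng = np.random.default_rng(child[b])
        zb = omega_estimate.rvs(nb, rng).T  # (D, nb)
        stats = study_statistics_batch(zb, grid, methods)
        for m in methods:
            parts[m].append(stats[m])
        done += nb
    return {m: np.sort(np.concatenate(parts[m])) for m in methods}


def empirical_pvalue(t, sorted_null_stats: np.ndarray,
                     small_is_extreme: bool = True) -> np.ndarray | float:
    """(N(T)+1)/(R+1) with N(T) the count of null statistics at least as
    extreme as T (≤ T for min-type statistics, ≥ T otherwise)."""
    t_arr = np.asarray(t, dtype=float)
    r = sorted_null_stats.shape[0]
    if small_is_extreme:
        n_t = np.searchsorted(sorted_null_stats, t_arr, side="right")
    else:
        n_t = r - np.searchsorted(sorted_null_stats, t_arr, side="left")
    p = (n_t + 1.0) / (r + 1.0)
    return float(p) if np.isscalar(t) or t_arr.ndim == 0 else p


def run_scan(
    zmat,
    mask,
    omega_estimate: CorrelationEstimate,
    n_replicates: int = 10_000,
    seed: int = 0,
    q: float = 0.2,
    method: str = "adelle",
    grid_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Global test of every SNP against its trans traits.

    SNPs sharing an identical trans set share one l-value grid and one
    Monte Carlo null.  Returns a table with columns snp_id, D_m, statistic,
    argmin_d, pvalue, R.
    """
    from .summary_io import TransMask, ZMatrix  # local import to avoid cycle

    if not isinstance(zmat, ZMatrix):
        raise TypeError("zmat must be a ZMatrix")
    if mask is None:
        full = np.ones((zmat.m, zmat.d), dtype=bool)
        mask = TransMask(full, zmat.snp_ids, zmat.trait_ids)
    small = ORIENTATION[method]
    ss = np.random.SeedSequence(seed)
    rows = []
    classes = mask.mask_classes()
    logger.info("run_scan: %d SNPs in %d mask classes", zmat.m, len(classes))
    for class_i, (key, snp_idx) in enumerate(sorted(classes.items())):
        trait_sel = np.frombuffer(key, dtype=bool)
        d_m = int(trait_sel.sum())
        if d_m == 0:
            for j in snp_idx:
                logger.warning("SNP %s has no trans traits; skipped",
                               zmat.snp_ids[j])
            continue
        omega_sub = omega_estimate.subset(np.flatnonzero(trait_sel))
        grid = precompute_lvalue_grid(omega_sub, q=q, **(grid_kwargs or {}))
        nulls = sample_null_statistics(
            omega_sub, grid, n_replicates,
            ss.spawn(1)[0], methods=(method,),
        )[method]
        zsub = zmat.values[np.ix_(trait_sel, snp_idx)]
        stats = study_statistics_batch(zsub, grid, (method,))[method]
        if method in {"adelle", "ell"}:
            _, args = adelle_statistics_batch(zsub, grid)
        else:
            args = np.full(len(snp_idx), -1)
        pvals = empirical_pvalue(stats, nulls, small_is_extreme=small)
        for k, j in enumerate(snp_idx):
            rows.append((zmat.snp_ids[j], d_m, float(stats[k]),
                         int(args[k]) if args[k] > 0 else None,
                         float(pvals[k]), n_replicates))
    out = pd.DataFrame(rows, columns=["snp_id", "D_m", "statistic",
                                      "argmin_d", "pvalue", "R"])
    order = {s: i for i, s in enumerate(zmat.snp_ids)}
    return out.sort_values("snp_id", key=lambda s: s.map(order),
                           ignore_index=True)
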