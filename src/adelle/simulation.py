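"""Synthetic trans-eQTL studies and operating-characteristic experiments.

The generator reproduces the rank structure of a real summary-statistic
study: N trait vectors Y ~ N_D(0, Ω) give a rank-(N−1) sample correlation
ĈY; given Y, the Z matrix has matrix-normal law MN(0, ĈY, I), so study
columns are drawn i.i.d. from N_D(0, ĈY).  The correlation estimate Ω̂ is
then formed from the simulated Z matrix exactly as it would be from data,
and the type-I error / power experiments evaluate each global test on fresh
draws from ĈY (the conditional truth) against a Monte Carlo null calibrated
from Ω̂ (the estimate) — the mismatch between the two is precisely what the
type-I experiment probes.

Defaults mirror a mouse advanced-intercross-line expression study scale:
D = 10^4 traits, N = 208 individuals, nominal level 0.01, 10^4 null
replicates and 10^3 alternative replicates per power cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adelle_engine import empirical_pvalue, sample_null_statistics, study_statistics_batch
from .count_model import LValueGrid, precompute_lvalue_grid
from .covariance import CorrelationEstimate, LowRankCorrelation, estimate_omega

logger = logging.getLogger(__name__)

__all__ = [
    "OmegaSpec",
    "SimulationConfig",
    "TraitSample",
    "StudyContext",
    "make_omega_true",
    "simulate_cy",
    "simulate_z_study",
    "add_signal",
    "build_study",
    "estimate_type1",
    "estimate_power",
    "calibrate_effect",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = ("adelle", "minp", "simes", "sumz2", "cpma")


@dataclass(frozen=True)
class OmegaSpec:
    """Recipe for the true trait-correlation model.

    kinds: ``identity``; ``equicorr`` (rho); ``block`` (block_size, rho);
    ``factor`` (k factors, geometric scale decay, communalities u_d drawn
    Uniform(commun_low, commun_high) from ``loading_seed``).
    """

    kind: str = "factor"
    rho: float = 0.0
    block_size: int = 10
    k: int = 30
    decay: float = 0.95
    commun_low: float = 0.01
    commun_high: float = 0.1
    loading_seed: int = 1234


@dataclass
class SimulationConfig:
    d: int = 10_000
    n_samples: int = 208
    m_snps: int = 50_000
    omega_spec: OmegaSpec = field(default_factory=OmegaSpec)
    r_assoc: int = 0
    effect_size: float = 0.0
    n_null_reps: int = 10_000
    n_alt_reps: int = 1_000
    alpha: float = 0.01
    q: float = 0.2
    seed: int = 0
    methods: tuple[str, ...] = DEFAULT_METHODS

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.r_assoc > self.d:
            raise ValueError("r_assoc cannot exceed the number of traits")


@dataclass
class TraitSample:
    """N i.i.d. trait draws and their rank-(N−1) sample correlation."""

    y: np.ndarray
    cy: LowRankCorrelation
    n_samples: int

    @property
    def cy_hat(self) -> np.ndarray:
        return self.cy.to_dense()


def make_omega_true(spec: OmegaSpec, d: int) -> LowRankCorrelation:
    """Construct Ω in factored form (never densified for large D)."""
    if spec.kind == "identity":
        return LowRankCorrelation.identity(d)
    if spec.kind == "equicorr":
        if not 0 <= spec.rho < 1:
            raise ValueError("equicorrelation must lie in [0, 1) for the "
                             "factored representation")
        u = np.full((d, 1), np.sqrt(spec.rho))
        return LowRankCorrelation(np.full(d, 1.0 - spec.rho), u)
    if spec.kind == "block":
        if not 0 <= spec.rho < 1:
            raise ValueError("block correlation must lie in [0, 1)")
        n_blocks = (d + spec.block_size - 1) // spec.block_size
        u = np.zeros((d, n_blocks))
        for b in range(n_blocks):
            lo, hi = b * spec.block_size, min((b + 1) * spec.block_size, d)
            u[lo:hi, b] = np.sqrt(spec.rho)
        return LowRankCorrelation(np.full(d, 1.0 - spec.rho), u)
    if spec.kind == "factor":
        rng = np.random.default_rng(spec.loading_seed)
        raw = rng.standard_normal((d, spec.k)) * (spec.decay ** np.arange(spec.k))
        commun = rng.uniform(spec.commun_low, spec.commun_high, d)
        raw *= (np.sqrt(commun) / np.linalg.norm(raw, axis=1))[:, None]
        return LowRankCorrelation(1.0 - commun, raw)
    raise ValueError(f"unknown omega kind '{spec.kind}'")


def simulate_cy(n: int, omega_true: LowRankCorrelation,
                seed: int | np.random.SeedSequence) -> TraitSample:
    """Draw N trait vectors and form the rank-(N−1) sample correlation ĈY,
    kept as a normalized factor (ĈY = G Gᵀ)."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    y = omega_true.rvs(n, rng)
    yc = y - y.mean(axis=0, keepdims=True)
    g = yc.T
    norms = np.linalg.norm(g, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate trait draw (zero variance)")
    cy = LowRankCorrelation(np.zeros(omega_true.d), g / norms[:, None],
                            validate=False)
    return TraitSample(y=y, cy=cy, n_samples=n)


def simulate_z_study(trait_sample: TraitSample, m: int,
                     seed: int | np.random.SeedSequence):
    """M i.i.d. study columns from N_D(0, ĈY) as a ZMatrix."""
    from .summary_io import ZMatrix

    rng = np.random.default_rng(seed)
    z = trait_sample.cy.rvs(m, rng).T
    d = trait_sample.cy.d
    return ZMatrix(z, [f"trait{i}" for i in range(d)],
                   [f"snp{j}" for j in range(m)],
                   n_samples=trait_sample.n_samples, n_covariates=0)


def add_signal(zvec: np.ndarray, r_assoc: int, effect_size: float,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Mean-shift exactly r_assoc uniformly chosen entries by effect_size."""
    z = np.array(zvec, dtype=float, copy=True)
    if r_assoc < 0 or r_assoc > z.shape[0]:
        raise ValueError("r_assoc out of range")
    idx = rng.choice(z.shape[0], size=r_assoc, replace=False)
    z[idx] += effect_size
    return z, np.sort(idx)


@dataclass
class StudyContext:
    """One simulated study: truth, sample, estimate and precomputed grid."""

    config: SimulationConfig
    omega_true: LowRankCorrelation
    trait_sample: TraitSample
    omega_hat: CorrelationEstimate
    grid: LValueGrid
    calibration: dict[str, np.ndarray] = field(default_factory=dict)

    def calibrate(self, methods: tuple[str, ...], n_reps: int,
                  seed: int | np.random.SeedSequence) -> dict[str, np.ndarray]:
        missing = tuple(m for m in methods if m not in self.calibration)
        if missing:
            self.calibration.update(sample_null_statistics(
                self.omega_hat, self.grid, n_reps, seed, methods=missing))
        return {m: self.calibration[m] for m in methods}


def build_study(config: SimulationConfig, grid_kwargs: dict | None = None) -> StudyContext:
    """Generate Ω → Y → ĈY → Z study → Ω̂ → l-value grid.

    The Z study enters Ω̂ estimation through its factored form: with
    Z = G Eᵀ (ĈY = G Gᵀ, E the M×r SNP coefficients) only the r×r Gram
    matrix of the centered coefficients is needed, so the M SNP columns are
    never materialised and M can match a genome-scale pruned SNP panel.
    """
    from .covariance import estimate_omega_from_factor

    ss = np.random.SeedSequence(config.seed)
    s_y, s_z, _ = ss.spawn(3)
    omega_true = make_omega_true(config.omega_spec, config.d)
    ts = simulate_cy(config.n_samples, omega_true, s_y)
    logger.info("study: D=%d N=%d M=%d", config.d, config.n_samples, config.m_snps)
    rng_z = np.random.default_rng(s_z)
    e = rng_z.standard_normal((config.m_snps, ts.cy.rank_factor))
    ec = e - e.mean(axis=0, keepdims=True)
    omega_hat = estimate_omega_from_factor(ts.cy.factor, ec.T @ ec,
                                           rank=config.n_samples - 1)
    grid = precompute_lvalue_grid(omega_hat, q=config.q, **(grid_kwargs or {}))
    return StudyContext(config=config, omega_true=omega_true, trait_sample=ts,
                        omega_hat=omega_hat, grid=grid)


def _evaluation_rates(ctx: StudyContext, methods: tuple[str, ...],
                      n_reps: int, alpha: float,
                      seed_eval: np.random.SeedSequence,
                      source, signal: tuple[int, float] | None,
                      calibration: dict[str, np.ndarray],
                      block: int = 2048) -> dict[str, float]:
    """Fraction of evaluation replicates each method rejects at level alpha."""
    from .competitors import ORIENTATION

    n_blocks = (n_reps + block - 1) // block
    children = seed_eval.spawn(n_blocks)
    reject = {m: 0 for m in methods}
    done = 0
    for b in range(n_blocks):
        nb = min(block, n_reps - done)
        rng = np.random.default_rng(children[b])
        zb = source.rvs(nb, rng).T
        if signal is not None:
            r_assoc, c_r = signal
            for col in range(nb):
                idx = rng.choice(zb.shape[0], size=r_assoc, replace=False)
                zb[idx, col] += c_r
        stats = study_statistics_batch(zb, ctx.grid, tuple(methods))
        for m in methods:
            pv = empirical_pvalue(stats[m], calibration[m],
                                  small_is_extreme=ORIENTATION[m])
            reject[m] += int(np.sum(pv <= alpha))
        done += nb
    return {m: reject[m] / n_reps for m in methods}


def _rate_table(rates: dict[str, float], n: int, **extra) -> pd.DataFrame:
    rows = []
    for m, r in rates.items():
        rows.append({"method": m, "rate": r,
                     "se": float(np.sqrt(r * (1 - r) / n)), "n_reps": n, **extra})
    return pd.DataFrame(rows)


def estimate_type1(config: SimulationConfig, ctx: StudyContext | None = None,
                   eval_from: str = "cy") -> pd.DataFrame:
    """Empirical type-I error of each method at the nominal level.

    ``eval_from``: "cy" draws evaluation replicates from the conditional
    truth ĈY (the study scheme); "omega" from Ω̂; "shared" evaluates the
    calibration set against itself (diagnostic: rate ≈ alpha by construction).
    """
    if ctx is None:
        ctx = build_study(config)
    ss = np.random.SeedSequence(config.seed + 1)
    s_cal, s_eval = ss.spawn(2)
    cal = ctx.calibrate(config.methods, config.n_null_reps, s_cal)
    if eval_from == "shared":
        from .competitors import ORIENTATION

        rates = {}
        for m in config.methods:
            pv = empirical_pvalue(cal[m], cal[m], small_is_extreme=ORIENTATION[m])
            rates[m] = float(np.mean(pv <= config.alpha))
        return _rate_table(rates, config.n_null_reps, eval_from=eval_from)
    source = {"cy": ctx.trait_sample.cy, "omega": ctx.omega_hat}[eval_from]
    rates = _evaluation_rates(ctx, config.methods, config.n_null_reps,
                              config.alpha, s_eval, source, None, cal)
    return _rate_table(rates, config.n_null_reps, eval_from=eval_from)


def estimate_power(config: SimulationConfig, ctx: StudyContext | None = None,
                   eval_seed_offset: int = 2) -> pd.DataFrame:
    """Per-method power: rejection fraction over alternative replicates with
    exactly r_assoc mean-shifted traits per replicate."""
    if config.r_assoc <= 0:
        raise ValueError("set r_assoc > 0 for a power experiment")
    if ctx is None:
        ctx = build_study(config)
    ss = np.random.SeedSequence(config.seed + 1)
    s_cal, _ = ss.spawn(2)
    cal = ctx.calibrate(config.methods, config.n_null_reps, s_cal)
    s_eval = np.random.SeedSequence(config.seed + eval_seed_offset).spawn(1)[0]
    rates = _evaluation_rates(ctx, config.methods, config.n_alt_reps,
                              config.alpha, s_eval, ctx.trait_sample.cy,
                              (config.r_assoc, config.effect_size), cal)
    return _rate_table(rates, config.n_alt_reps, r_assoc=config.r_assoc,
                       effect_size=config.effect_size)


def calibrate_effect(config: SimulationConfig, ctx: StudyContext | None = None,
                     target_range: tuple[float, float] = (0.5, 0.9),
                     n_search_reps: int = 400, max_iter: int = 14,
                     c_init: float = 1.0, c_bound: float = 32.0):
    """Bisection on the effect size c_R until the maximum power across
    methods falls inside ``target_range``.

    Returns (c_R, achieved powers at c_R, search trace).
    """
    lo_t, hi_t = target_range
    if not 0 < lo_t < hi_t <= 1:
        raise ValueError("invalid target range")
    if ctx is None:
        ctx = build_study(config)
    trace = []

    def max_power(c: float) -> float:
        cfg = replace(config, effect_size=c, n_alt_reps=n_search_reps)
        tab = estimate_power(cfg, ctx=ctx, eval_seed_offset=3)
        p = float(tab["rate"].max())
        trace.append((c, p))
        return p

    lo, hi = 0.0, c_init
    p_hi = max_power(hi)
    while p_hi < lo_t:
        lo, hi = hi, hi * 2.0
        if hi > c_bound:
            raise RuntimeError("target power range unreachable within bounds")
        p_hi = max_power(hi)
    if p_hi <= hi_t:
        c_r = hi
    else:
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            p_mid = max_power(mid)
            if p_mid < lo_t:
                lo = mid
            elif p_mid > hi_t:
                hi = mid
            else:
                c_r = mid
                break
        else:
            c_r = 0.5 * (lo + hi)
    cfg = replace(config, effect_size=c_r)
    powers = estimate_power(cfg, ctx=ctx)
    return c_r, powers, trace
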