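"""Null distribution of the exceedance count S(c) under trait dependence.

For a threshold c ≥ 0, S(c) counts traits with |Z| ≥ c.  The key identity
{π(d) ≤ h} = {S(−Φ⁻¹(h/2)) ≥ d} turns order-statistic cdfs into upper tails
of S.  Under a correlated multivariate-normal null, S(c) keeps the
Binomial(D, 2Φ(−c)) mean but is over-dispersed; it is approximated by a
beta-binomial whose first two moments match those of S(c).

The second moment needs Σ_{i≠j} P(|Z_i| ≥ c, |Z_j| ≥ c).  Each pairwise term
is evaluated by a one-dimensional quadrature of the bivariate-normal density
along the correlation path (the tetrachoric/Plackett identity
∂Φ₂(−c,−c;t)/∂t = φ₂(−c,−c;t) = exp(−c²/(1+t)) / (2π√(1−t²)), made smooth
by t = sin θ), and the pair sum is accumulated from either the explicit
off-diagonal correlations (small D) or a blockwise histogram of |Ω_ij|
computed from the low-rank factor (large D) — the D×D matrix is never
materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import special

from .covariance import CorrelationEstimate, LowRankCorrelation
from .ell_core import DEFAULT_Q, n_lvalues

__all__ = [
    "CountMoments",
    "BetaBinomialFit",
    "PairCorrelationSummary",
    "LValueGrid",
    "tail_prob",
    "pair_exceedance_prob",
    "pair_summary",
    "s_moments",
    "fit_beta_binomial",
    "precompute_lvalue_grid",
    "lvalue_lookup",
]

_THETA_NODES = 4001
_PROB_FLOOR = 1e-300
_ONE_MINUS = 1.0 - 1e-16
_HIST_THRESHOLD = 3000  # dense pair enumeration below this dimension


def tail_prob(c) -> np.ndarray | float:
    """p = 2Φ(−c), the two-sided tail mass at threshold c (erfc path)."""
    return special.erfc(np.asarray(c, dtype=float) / np.sqrt(2.0))


class _PsiCurve:
    """ψ_c(ω) = P(|Z_i|≥c, |Z_j|≥c) − p² as a function of |ω|, precomputed
    as a cumulative integral on a θ = arcsin t grid."""

    def __init__(self, c: float, n_nodes: int = _THETA_NODES):
        self.c = float(c)
        theta = np.linspace(0.0, np.pi / 2, n_nodes)
        s = np.sin(theta)
        c2 = self.c * self.c
        up = np.exp(-c2 / (1.0 + s))
        with np.errstate(divide="ignore"):
            lo = np.where(s < 1.0, np.exp(-c2 / np.maximum(1.0 - s, 1e-300)), 0.0)
        integrand = up - lo
        cum = np.concatenate([[0.0], np.cumsum((integrand[1:] + integrand[:-1]) / 2.0)])
        self._theta = theta
        self._cum = cum * (theta[1] - theta[0]) / np.pi

    def __call__(self, abs_omega: np.ndarray) -> np.ndarray:
        a = np.arcsin(np.clip(np.abs(abs_omega), 0.0, 1.0))
        return np.interp(a, self._theta, self._cum)


def pair_exceedance_prob(c: float, omega_ij: float) -> float:
    """P(|Z_i| ≥ c, |Z_j| ≥ c) for a standard bivariate normal pair."""
    if c < 0:
        raise ValueError("threshold c must be nonnegative")
    w = float(omega_ij)
    if abs(w) > 1 + 1e-12:
        raise ValueError("correlation must lie in [-1, 1]")
    p = float(tail_prob(c))
    return float(p * p + _PsiCurve(c)(np.abs(np.clip(w, -1, 1)))[()])


@dataclass
class PairCorrelationSummary:
    """Off-diagonal correlations of Ω reduced to what the moment match needs:
    either explicit values (with multiplicity) or a histogram of |Ω_ij|."""

    d: int
    values: np.ndarray | None = None       # upper-triangle values (weight 2 each)
    counts: np.ndarray | None = None       # ordered-pair counts per bin
    bin_abs: np.ndarray | None = None      # mean |omega| per bin

    def pair_sum(self, psi: _PsiCurve) -> float:
        """Σ_{i≠j} ψ(ω_ij)."""
        if self.values is not None:
            return 2.0 * float(psi(np.abs(self.values)).sum())
        nz = self.counts > 0
        return float(self.counts[nz] @ psi(self.bin_abs[nz]))


def _values_to_summary(d: int, vals: np.ndarray,
                       max_explicit: int = 20_000) -> PairCorrelationSummary:
    """Keep explicit pair values when few; otherwise reduce to a fine
    histogram of |ω| (4096 bins, per-bin mean) so the per-threshold pair sum
    is O(bins) instead of O(D²)."""
    if vals.shape[0] <= max_explicit:
        return PairCorrelationSummary(d=d, values=vals)
    n_bins = 4096
    a = np.clip(np.abs(vals), 0.0, 1.0)
    ib = np.minimum((a * n_bins).astype(np.int64), n_bins - 1)
    counts = 2 * np.bincount(ib, minlength=n_bins)  # ordered pairs
    sums = 2 * np.bincount(ib, weights=a, minlength=n_bins)
    mean_abs = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return PairCorrelationSummary(d=d, counts=counts, bin_abs=mean_abs)


def pair_summary(omega) -> PairCorrelationSummary:
    if isinstance(omega, PairCorrelationSummary):
        return omega
    if isinstance(omega, CorrelationEstimate):
        omega = omega.structure
    if isinstance(omega, LowRankCorrelation):
        if omega.d <= _HIST_THRESHOLD:
            return _values_to_summary(omega.d, omega.offdiag_values())
        counts, mean_abs = omega.offdiag_abs_histogram()
        return PairCorrelationSummary(d=omega.d, counts=counts, bin_abs=mean_abs)
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("omega must be square")
    if np.max(np.abs(np.diag(omega) - 1.0)) > 1e-8 or np.max(np.abs(omega)) > 1 + 1e-8:
        raise ValueError("omega is not a correlation matrix")
    vals = omega[np.triu_indices(omega.shape[0], k=1)]
    return _values_to_summary(omega.shape[0], vals)


@dataclass
class CountMoments:
    c: float
    p: float
    mean: float
    variance: float


def s_moments(c: float, omega) -> CountMoments:
    """Null mean and variance of S(c) = Σ_d I{|Z_d| ≥ c} under Z ~ N(0, Ω).

    mean = D·p;  variance = D·p(1−p) + Σ_{i≠j} [P(|Z_i|≥c,|Z_j|≥c) − p²].
    """
    summ = pair_summary(omega)
    p = float(tail_prob(c))
    d = summ.d
    psi = _PsiCurve(c)
    var = d * p * (1.0 - p) + summ.pair_sum(psi)
    return CountMoments(c=float(c), p=p, mean=d * p, variance=var)


@dataclass
class BetaBinomialFit:
    """Moment-matched beta-binomial (or binomial fallback) for S(c)."""

    d: int
    p: float
    alpha_bb: float
    beta_bb: float
    fallback_binomial: bool

    def moments(self) -> tuple[float, float]:
        if self.fallback_binomial:
            return self.d * self.p, self.d * self.p * (1.0 - self.p)
        a, b = self.alpha_bb, self.beta_bb
        s = a + b
        mean = self.d * a / s
        var = self.d * a * b * (s + self.d) / (s * s * (s + 1.0))
        return mean, var

    def _log_pmf_all(self, gammaln_cache=None) -> np.ndarray:
        k = np.arange(self.d + 1, dtype=float)
        if gammaln_cache is None:
            log_choose = (special.gammaln(self.d + 1.0) - special.gammaln(k + 1.0)
                          - special.gammaln(self.d - k + 1.0))
        else:
            log_choose = gammaln_cache
        if self.fallback_binomial:
            with np.errstate(divide="ignore", invalid="ignore"):
                lp = log_choose + k * np.log(self.p) + (self.d - k) * np.log1p(-self.p)
            if self.p >= 1.0:
                lp = np.where(k == self.d, 0.0, -np.inf)
            return lp
        a, b = self.alpha_bb, self.beta_bb
        return (log_choose + special.gammaln(k + a) + special.gammaln(self.d - k + b)
                - special.gammaln(self.d + a + b) - special.betaln(a, b))

    def upper_tail(self, d_max: int, gammaln_cache=None) -> np.ndarray:
        """P(S ≥ d) for d = 1..d_max, summed from the top in linear space."""
        pmf = np.exp(self._log_pmf_all(gammaln_cache))
        tail = np.cumsum(pmf[::-1])[::-1]
        return np.clip(tail[1:d_max + 1], 0.0, 1.0)


def fit_beta_binomial(d: int, mean: float, variance: float,
                      rel_tol: float = 1e-9) -> BetaBinomialFit:
    """Match the first two moments of S(c); binomial fallback when the target
    variance does not exceed the binomial one (the model cannot be
    under-dispersed)."""
    if not 0 < mean < d:
        raise ValueError("mean must lie strictly between 0 and D")
    if variance <= 0:
        raise ValueError("variance must be positive")
    p = mean / d
    binom_var = d * p * (1.0 - p)
    if d == 1 or variance <= binom_var * (1.0 + rel_tol):
        if variance < binom_var * (1.0 - 1e-6):
            import warnings
            warnings.warn("target variance below binomial; using binomial fallback")
        return BetaBinomialFit(d=d, p=p, alpha_bb=np.inf, beta_bb=np.inf,
                               fallback_binomial=True)
    rho = (variance / binom_var - 1.0) / (d - 1.0)
    if rho >= 1.0:
        import warnings
        warnings.warn("over-dispersion at the degenerate limit; clamping")
        rho = 1.0 - 1e-12
    s = 1.0 / rho - 1.0
    return BetaBinomialFit(d=d, p=p, alpha_bb=p * s, beta_bb=(1.0 - p) * s,
                           fallback_binomial=False)


def _probit(x: np.ndarray) -> np.ndarray:
    return special.ndtri(np.clip(x, _PROB_FLOOR, _ONE_MINUS))


def _signed_probit(lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Φ⁻¹ of a probability given both its lower and upper tail, so that
    values within ~1e-300 of either end keep full probit resolution."""
    lo = np.clip(lower, _PROB_FLOOR, _ONE_MINUS)
    up = np.clip(upper, _PROB_FLOOR, _ONE_MINUS)
    return np.where(lower <= 0.5, special.ndtri(lo), -special.ndtri(up))


def _beta_probit(dd: np.ndarray, d: int, p: np.ndarray) -> np.ndarray:
    """Probit of Beta(d, D−d+1) cdf at p, accurate in both tails."""
    p = np.clip(p, 0.0, 1.0)
    u = special.betainc(dd, d - dd + 1.0, p)
    uc = special.betainc(d - dd + 1.0, dd, 1.0 - p)
    return _signed_probit(u, uc)


@dataclass
class LValueGrid:
    """Precomputed F̂(d)(h) over thresholds h ∈ ℋ for d = 1..floor(qD).

    Lookup interpolates in probit-transformed coordinates: the abscissa is
    Φ⁻¹ of the independence-case order-statistic cdf Beta(d, D−d+1)(h) and
    the ordinate Φ⁻¹(F̂(d)(h)), so the curve is the Gaussian Q-Q map between
    the dependent and independent null laws of π(d) — near-linear, and the
    exact identity when Ω = I.
    """

    h_grid: np.ndarray
    table: np.ndarray          # (m, n_h) F̂ values
    u_grid: np.ndarray         # (m, n_h) independence Beta cdf at the nodes
    d: int
    q: float
    pair: PairCorrelationSummary
    fit_alpha: np.ndarray
    fit_beta: np.ndarray
    fit_fallback: np.ndarray
    omega_fingerprint: str = ""
    x_grid: np.ndarray = field(default=None, repr=False)
    y_grid: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        dd = np.arange(1, self.table.shape[0] + 1, dtype=float)[:, None]
        if self.x_grid is None:
            self.x_grid = _beta_probit(dd, self.d, self.h_grid[None, :])
        if self.y_grid is None:
            self.y_grid = _signed_probit(self.table, 1.0 - self.table)

    @property
    def m(self) -> int:
        return self.table.shape[0]

    def batch_min_lvalue(self, sorted_top: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Min l-value and its argmin d for each column of a (m, n) matrix of
        the m smallest sorted p-values per replicate."""
        m, n = sorted_top.shape
        if m != self.m:
            raise ValueError("row count must equal floor(qD)")
        dd = np.arange(1, m + 1, dtype=float)[:, None]
        x = _beta_probit(dd, self.d, sorted_top)
        y = np.empty_like(x)
        for row in range(m):
            y[row] = np.interp(x[row], self.x_grid[row], self.y_grid[row])
        arg = np.argmin(y, axis=0)
        ymin = y[arg, np.arange(n)]
        return special.ndtr(ymin), arg + 1

    def direct_lvalue(self, d: int, p_observed: float) -> float:
        """Gridless evaluation: refit the beta-binomial at the exact
        c = −Φ⁻¹(p/2) and return P(S ≥ d)."""
        if not 1 <= d <= self.m:
            raise ValueError("d out of range")
        p_observed = float(p_observed)
        if not 0 < p_observed <= 1:
            raise ValueError("p must lie in (0, 1]")
        c = float(-special.ndtri(p_observed / 2.0)) if p_observed < 1 else 0.0
        c = max(c, 0.0)
        mom = s_moments(c, self.pair)
        fit = fit_beta_binomial(self.d, mom.mean, mom.variance)
        return float(fit.upper_tail(d)[d - 1])

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("h_grid", data=self.h_grid)
            f.create_dataset("table", data=self.table)
            f.create_dataset("u_grid", data=self.u_grid)
            f.create_dataset("fit_alpha", data=self.fit_alpha)
            f.create_dataset("fit_beta", data=self.fit_beta)
            f.create_dataset("fit_fallback", data=self.fit_fallback.astype(np.int8))
            if self.pair.values is not None:
                f.create_dataset("pair_values", data=self.pair.values)
            else:
                f.create_dataset("pair_counts", data=self.pair.counts)
                f.create_dataset("pair_bin_abs", data=self.pair.bin_abs)
            f.attrs.update(d=self.d, q=self.q, fingerprint=self.omega_fingerprint)

    @classmethod
    def load(cls, path) -> "LValueGrid":
        with h5py.File(path, "r") as f:
            d = int(f.attrs["d"])
            if "pair_values" in f:
                pair = PairCorrelationSummary(d=d, values=f["pair_values"][:])
            else:
                pair = PairCorrelationSummary(d=d, counts=f["pair_counts"][:],
                                              bin_abs=f["pair_bin_abs"][:])
            return cls(
                h_grid=f["h_grid"][:], table=f["table"][:], u_grid=f["u_grid"][:],
                d=d, q=float(f.attrs["q"]), pair=pair,
                fit_alpha=f["fit_alpha"][:], fit_beta=f["fit_beta"][:],
                fit_fallback=f["fit_fallback"][:].astype(bool),
                omega_fingerprint=str(f.attrs["fingerprint"]),
            )


def precompute_lvalue_grid(
    omega,
    q: float = DEFAULT_Q,
    h_grid: np.ndarray | None = None,
    n_h: int = 1500,
    h_min: float = 1e-25,
) -> LValueGrid:
    """Build the F̂(d)(h) table for d = 1..floor(qD), h ∈ ℋ.

    ℋ defaults to ``n_h`` log-spaced points on [h_min, q] plus a linear
    refinement reaching h = 0.995, so l-values are represented over the full
    range observed order statistics can take; below h_min (|Z| ≈ 10.5)
    lookups clamp to the edge.
    """
    summ = pair_summary(omega)
    d = summ.d
    m = n_lvalues(d, q)
    if m < 1:
        raise ValueError("floor(qD) must be at least 1")
    if h_grid is None:
        # log-spaced backbone plus a linearly-spaced refinement of the upper
        # range, where the order statistics of large d concentrate and the
        # log grid would be locally coarse; the top extends well past q so
        # large observed p-values map to their true (large) l-values instead
        # of an endpoint clamp
        h_max = 0.995
        base = np.geomspace(h_min, q, n_h)
        top = np.linspace(q / 50.0, h_max, 800)
        h_grid = np.unique(np.concatenate([base, top]))
    else:
        h_grid = np.asarray(h_grid, dtype=float)
        if np.any((h_grid <= 0) | (h_grid >= 1)):
            raise ValueError("h thresholds must lie in (0, 1)")
        if np.any(np.diff(h_grid) <= 0):
            raise ValueError("h_grid must be strictly ascending")
    n = h_grid.shape[0]

    k = np.arange(d + 1, dtype=float)
    log_choose = (special.gammaln(d + 1.0) - special.gammaln(k + 1.0)
                  - special.gammaln(d - k + 1.0))

    table = np.empty((m, n))
    fa = np.empty(n)
    fb = np.empty(n)
    fallback = np.zeros(n, dtype=bool)
    cs = -special.ndtri(h_grid / 2.0)
    for j in range(n):
        mom = s_moments(cs[j], summ)
        fit = fit_beta_binomial(d, mom.mean, mom.variance)
        fa[j], fb[j] = fit.alpha_bb, fit.beta_bb
        fallback[j] = fit.fallback_binomial
        table[:, j] = fit.upper_tail(m, gammaln_cache=log_choose)

    # Enforce the structural monotonicities (tiny per-h fit wiggle only):
    np.maximum.accumulate(table, axis=1, out=table)      # nondecreasing in h
    np.minimum.accumulate(table, axis=0, out=table)      # nonincreasing in d

    dd = np.arange(1, m + 1, dtype=float)[:, None]
    u_grid = special.betainc(dd, d - dd + 1.0, h_grid[None, :])

    fp = ""
    if isinstance(omega, CorrelationEstimate):
        fp = omega.fingerprint()
    elif isinstance(omega, LowRankCorrelation):
        fp = omega.fingerprint()
    return LValueGrid(h_grid=h_grid, table=table, u_grid=u_grid, d=d, q=q,
                      pair=summ, fit_alpha=fa, fit_beta=fb, fit_fallback=fallback,
                      omega_fingerprint=fp)


def lvalue_lookup(grid: LValueGrid, d: int, p_observed) -> np.ndarray | float:
    """Evaluate F̂(d) at observed π(d) value(s) by monotone interpolation."""
    if not 1 <= d <= grid.m:
        raise ValueError("d exceeds floor(qD)")
    p = np.asarray(p_observed, dtype=float)
    x = _beta_probit(np.asarray(float(d)), grid.d, p)
    y = np.interp(x, grid.x_grid[d - 1], grid.y_grid[d - 1])
    out = special.ndtr(y)
    return float(out) if np.isscalar(p_observed) else out
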