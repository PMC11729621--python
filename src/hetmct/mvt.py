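"""Central multivariate t probabilities, equicoordinate quantiles, adjusted p.

One-sided multiple contrast tests need P(T_1 <= u_1, ..., T_L <= u_L) for a
central L-variate t with a given correlation matrix and (possibly
non-integer) degrees of freedom.  The rectangle probability is computed by
the separation-of-variables quasi-Monte-Carlo method of Genz and Bretz:

* Cholesky-factor the correlation matrix (with diagonal pivoting, so
  singular but positive-semidefinite matrices -- e.g. all-pairs contrast
  correlations of rank k-1 < L -- are handled via degenerate indicator
  steps);
* integrate the sequentially conditioned normal recursion over scrambled
  Sobol points, with one extra coordinate for the chi-scale mixing variable
  that turns the normal into a t probability;
* repeat over independently scrambled replicates: the mean is the estimate
  and ~3.5 standard errors of the replicate spread is the reported error
  bound, with automatic doubling of the point budget until the requested
  tolerance is met.

Everything is deterministic for a fixed seed.  Degrees of freedom above
1e4 switch to the multivariate normal limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import lapack
from scipy.special import chdtri, ndtr, ndtri
from scipy.stats import norm, qmc
from scipy.stats import t as t_dist

__all__ = ["MvtSpec", "mvt_cdf", "equicoordinate_quantile", "adjusted_p"]

NORMAL_DF_CUTOFF = 1e4
_ERR_MULT = 3.5  # replicate-spread multiplier for the reported error bound
_PIV_TOL = 1e-10


def _pivoted_cholesky(R: np.ndarray):
    """Lower Cholesky factor with diagonal pivoting; supports PSD rank deficiency."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(np.abs(np.diag(R) - 1.0) > 1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    c, piv, rank, _ = lapack.dpstrf(R, lower=1)
    C = np.tril(c)
    C[rank:, rank:] = 0.0
    perm = piv - 1
    resid = np.max(np.abs(R[np.ix_(perm, perm)] - C @ C.T))
    if resid > 1e-7:
        raise ValueError("correlation matrix is not positive semidefinite")
    return C, perm, int(rank)


@lru_cache(maxsize=128)
def _chi_scale_interp(df: float):
    """Interpolation nodes for s(w) = sqrt(chi2_ppf(w, df) / df).

    Parameterized on the normal-quantile scale z = ndtri(w), where the
    function is smooth; 8193 nodes keep the interpolation error in s below
    ~1e-7 over the mass of the distribution.
    """
    z = np.linspace(-8.5, 8.5, 8193)
    w = ndtr(z)
    x = chdtri(df, 1.0 - w)  # chi2 quantile at probability w
    return z, np.sqrt(x / df)


def _chi_scale(w: np.ndarray, df: float) -> np.ndarray:
    z_grid, s_grid = _chi_scale_interp(float(df))
    return np.interp(ndtri(np.clip(w, 1e-16, 1.0 - 1e-16)), z_grid, s_grid)


def _needs_draw(C: np.ndarray) -> np.ndarray:
    """Coordinates whose conditional normal must actually be sampled.

    A (non-degenerate) coordinate needs a uniform draw only if a later row
    of the Cholesky factor references it; in particular the last coordinate
    never does.
    """
    L = C.shape[0]
    need = np.zeros(L, dtype=bool)
    for j in range(L):
        need[j] = C[j, j] > _PIV_TOL and bool(np.any(C[j + 1 :, j] != 0.0))
    return need


def _recursion(u, C, need, s, w: np.ndarray, col0: int):
    """Genz conditioned-normal recursion; returns per-point products."""
    L = u.size
    npts = w.shape[0]
    prod = np.ones(npts)
    ys = np.zeros((L, npts))
    col = col0
    for j in range(L):
        num = s * u[j] - C[j, :j] @ ys[:j] if j else s * u[j] * np.ones(npts)
        if C[j, j] > _PIV_TOL:
            e = ndtr(num / C[j, j])
            if need[j]:
                ys[j] = ndtri(np.clip(w[:, col] * e, 1e-300, 1.0 - 1e-16))
                col += 1
        else:
            # rank-deficient coordinate: fully determined by earlier ones
            e = (num >= 0).astype(float)
        prod *= e
    return prod


def mvt_cdf(
    upper,
    corr,
    df,
    *,
    eps: float = 1e-5,
    seed: int = 0,
    n_start: int = 2**11,
    n_max: int = 2**17,
    n_reps: int = 10,
):
    """P(T_1 <= u_1, ..., T_L <= u_L) for the central multivariate t.

    Returns ``(probability, error_bound)``.  ``df=inf`` (or above 1e4)
    gives the multivariate normal probability.  Deterministic for a fixed
    ``seed`` and point budget.
    """
    u = np.atleast_1d(np.asarray(upper, dtype=float))
    if not np.isscalar(df) and np.ndim(df) != 0:
        raise ValueError("df must be scalar")
    df = float(df)
    if not (df > 0):
        raise ValueError("df must be positive")
    if np.any(np.isnan(u)):
        raise ValueError("NaN upper limit")
    if u.size == 1:
        p = float(t_dist.cdf(u[0], df)) if df <= NORMAL_DF_CUTOFF else float(ndtr(u[0]))
        return p, 0.0
    if np.any(u == -np.inf):
        return 0.0, 0.0
    C, perm, rank = _pivoted_cholesky(corr)
    u = u[perm]
    use_t = df <= NORMAL_DF_CUTOFF
    need = _needs_draw(C)
    dim = max(int(need.sum()), 1) + (1 if use_t else 0)
    rng = np.random.default_rng(seed)
    n = n_start
    while True:
        ests = np.empty(n_reps)
        for r in range(n_reps):
            # independent Owen scramblings; the replicate spread estimates the error
            eng = qmc.Sobol(d=dim, scramble=True, seed=int(rng.integers(2**31)))
            w = eng.random(n)
            if use_t:
                s = _chi_scale(w[:, 0], df)
                ests[r] = _recursion(u, C, need, s, w, 1).mean()
            else:
                ests[r] = _recursion(u, C, need, 1.0, w, 0).mean()
        p = float(ests.mean())
        err = float(_ERR_MULT * ests.std(ddof=1) / np.sqrt(n_reps))
        if err <= eps or n >= n_max:
            return min(max(p, 0.0), 1.0), err
        n *= 2


def equicoordinate_quantile(
    level: float,
    corr,
    df,
    L: int = None,
    *,
    eps: float = 1e-5,
    seed: int = 0,
    xtol: float = 1e-6,
    n_max: int = 2**17,
) -> float:
    """q with P(T_1 <= q, ..., T_L <= q) = level (the simultaneous critical value).

    Solved by bracketed root search on the QMC probability; the bracket
    [marginal quantile, Bonferroni quantile] always contains the root.
    """
    from scipy.optimize import brentq

    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    L = corr.shape[0] if L is None else int(L)
    df = float(df)
    use_t = df <= NORMAL_DF_CUTOFF
    marg = t_dist.ppf if use_t else (lambda p, *_: norm.ppf(p))
    if L == 1:
        return float(marg(level, df))
    lo = float(marg(level, df))
    hi = float(marg(1.0 - (1.0 - level) / L, df))

    def f(q):
        return mvt_cdf(np.full(L, q), corr, df, eps=eps, seed=seed, n_max=n_max)[0] - level

    flo, fhi = f(lo), f(hi)
    # widen for QMC wobble at the bracket edges
    tries = 0
    while flo > 0 and tries < 5:
        lo -= 0.5
        flo = f(lo)
        tries += 1
    while fhi < 0 and tries < 10:
        hi += 0.5
        fhi = f(hi)
        tries += 1
    if flo > 0 or fhi < 0:
        raise RuntimeError(f"quantile bracket [{lo}, {hi}] failed: f={flo}, {fhi}")
    return float(brentq(f, lo, hi, xtol=xtol))


def adjusted_p(
    t_stats,
    df,
    corr,
    *,
    eps: float = 1e-5,
    seed: int = 0,
    n_max: int = 2**17,
) -> np.ndarray:
    """One-sided multiplicity-adjusted p-values.

    Each statistic is referred to its *own* L-variate t distribution:
    p_l = 1 - P(T <= t_l 1) with degrees of freedom df_l and the common
    correlation matrix, so contrasts with different df get different
    critical values.
    """
    t_stats = np.atleast_1d(np.asarray(t_stats, dtype=float))
    dfv = np.broadcast_to(np.asarray(df, dtype=float), t_stats.shape)
    out = np.empty(t_stats.size)
    cache = {}
    for l, (t_l, df_l) in enumerate(zip(t_stats, dfv)):
        if t_l == np.inf:
            out[l] = 0.0
            continue
        if t_l == -np.inf:
            out[l] = 1.0
            continue
        key = (float(t_l), float(df_l))
        if key not in cache:
            p, _ = mvt_cdf(
                np.full(t_stats.size, t_l), corr, df_l,
                eps=eps, seed=seed + l, n_max=n_max,
            )
            cache[key] = 1.0 - p
        out[l] = cache[key]
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class MvtSpec:
    """Bundle of a multivariate-t reference distribution and QMC settings."""

    corr: np.ndarray
    df: float
    eps: float = 1e-5
    seed: int = 0

    @property
    def dimension(self) -> int:
        return np.atleast_2d(self.corr).shape[0]

    def cdf(self, upper):
        return mvt_cdf(upper, self.corr, self.df, eps=self.eps, seed=self.seed)

    def quantile(self, level: float) -> float:
        return equicoordinate_quantile(
            level, self.corr, self.df, eps=self.eps, seed=self.seed
        )
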