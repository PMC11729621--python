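"""Monte-Carlo familywise-error and power study for the MCT procedures.

The study design: six normal treatments with a common mean of 100,
partitioned into three prespecified variance groups {1,2}, {3,4}, {5,6}
(the grouping is held fixed in every setting, including the homoskedastic
one -- the procedures always estimate three group variances, mirroring a
variance model fixed before the data are seen).  Four allocations, each
with total N = 60:

(a) balanced, n = 10 each, sigma = (10, 10, 30, 30, 50, 50)
(b) control smallest, n = (5, 11, 11, 11, 11, 11), same sigma
(c) last group smallest, n = (11, 11, 11, 11, 11, 5), same sigma
(d) balanced homoskedastic, n = 10 each, sigma = 30 each

Families: many-to-one (dunnett), all-pairs (tukey), trend (williams),
each-vs-rest (average), and a two-factor user-defined set of nine rows.
All tests are one-sided at familywise level alpha.

The familywise error is the fraction of replicates with at least one
rejection; the complete (all-pairs) power is the fraction in which *all*
designated false hypotheses are rejected simultaneously.  Every method
sees identical replicate data.  Rejections are taken from adjusted
p-values (equivalent to critical-value comparison by duality); for
procedures whose critical value does not depend on the data (HOM: fixed
correlation and df) the single equicoordinate quantile is computed once
and reused, which is decision-identical to the generic path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .contrasts import ContrastMatrix, build_contrasts
from .mct import METHODS, _CANON
from .mvt import equicoordinate_quantile, mvt_cdf

__all__ = [
    "SimulationSetting",
    "make_setting",
    "two_factor_matrix",
    "family_matrix",
    "simulate_fwe",
    "simulate_power",
    "FAMILIES",
]

FAMILIES = ("dunnett", "tukey", "williams", "average", "userdef")

_SIGMA_HET = (10.0, 10.0, 30.0, 30.0, 50.0, 50.0)

# default QMC settings inside the replicate loop: decisions only need the
# adjusted p to ~1e-3 around alpha, so a small fixed budget suffices
_SIM_QMC = dict(eps=2e-3, n_start=2**10, n_max=2**11, n_reps=4)


@dataclass(frozen=True)
class SimulationSetting:
    """One allocation of sample sizes and standard deviations."""

    label: str
    n: np.ndarray
    sigma: np.ndarray
    mu: np.ndarray = None
    variance_groups: tuple = ((0, 1), (2, 3), (4, 5))

    def __post_init__(self):
        n = np.asarray(self.n, dtype=int)
        sigma = np.asarray(self.sigma, dtype=float)
        mu = np.full(n.size, 100.0) if self.mu is None else np.asarray(self.mu, float)
        if not (n.size == sigma.size == mu.size):
            raise ValueError("n, sigma and mu must have equal length")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "mu", mu)
        codes = np.full(n.size, -1, dtype=int)
        for h, members in enumerate(self.variance_groups):
            for j in members:
                if codes[j] != -1:
                    raise ValueError("treatment assigned to two variance groups")
                codes[j] = h
        if np.any(codes < 0):
            raise ValueError("every treatment needs a variance group")
        object.__setattr__(self, "_codes", codes)

    @property
    def k(self) -> int:
        return self.n.size

    @property
    def group_codes(self) -> np.ndarray:
        return self._codes

    @property
    def H(self) -> int:
        return len(self.variance_groups)

    @property
    def N_h(self) -> np.ndarray:
        return np.bincount(self._codes, weights=self.n).astype(int)

    @property
    def I_h(self) -> np.ndarray:
        return np.bincount(self._codes)

    def shifted(self, delta: float, treatments=(2, 4)) -> "SimulationSetting":
        """Copy with the mean of the given treatments raised by ``delta``."""
        mu = self.mu.copy()
        mu[list(treatments)] += delta
        return SimulationSetting(self.label, self.n, self.sigma, mu,
                                 self.variance_groups)


def make_setting(label: str) -> SimulationSetting:
    """The four study allocations (total N = 60 each)."""
    label = str(label).lower()
    if label == "a":
        return SimulationSetting("a", [10] * 6, _SIGMA_HET)
    if label == "b":
        return SimulationSetting("b", [5, 11, 11, 11, 11, 11], _SIGMA_HET)
    if label == "c":
        return SimulationSetting("c", [11, 11, 11, 11, 11, 5], _SIGMA_HET)
    if label == "d":
        return SimulationSetting("d", [10] * 6, [30.0] * 6)
    raise ValueError(f"unknown setting label {label!r}")


def two_factor_matrix() -> ContrastMatrix:
    """Nine user-defined rows for a flattened 3x2 two-factor layout.

    The first six rows compare the levels of a three-level factor, the
    last three the levels of a two-level factor, each split for the
    other factor's levels.
    """
    m = np.array(
        [
            [-1, 0, 1, 0, 0, 0],
            [0, -1, 0, 1, 0, 0],
            [-1, 0, 0, 0, 1, 0],
            [0, -1, 0, 0, 0, 1],
            [0, 0, -1, 0, 1, 0],
            [0, 0, 0, -1, 0, 1],
            [-1, 1, 0, 0, 0, 0],
            [0, 0, -1, 1, 0, 0],
            [0, 0, 0, 0, -1, 1],
        ],
        dtype=float,
    )
    return ContrastMatrix(m, tuple(f"u{j + 1}" for j in range(9)))


def family_matrix(family: str, n) -> ContrastMatrix:
    family = str(family).lower()
    if family == "userdef":
        return two_factor_matrix()
    return build_contrasts(family, len(n), n=n)


# designated false hypotheses of the power study (treatments 3 and 5 raised)
_POWER_SET = {"dunnett": (1, 3), "tukey": (1, 3, 5, 7, 12)}


def _draw_replicates(setting: SimulationSetting, reps: int, rng):
    """Vectorized per-treatment sample means and variances."""
    k = setting.k
    means = np.empty((reps, k))
    svars = np.empty((reps, k))
    for j in range(k):
        x = rng.normal(setting.mu[j], setting.sigma[j], size=(reps, setting.n[j]))
        means[:, j] = x.mean(axis=1)
        svars[:, j] = x.var(axis=1, ddof=1)
    return means, svars


class _MethodEngine:
    """Per-method vectorized statistics plus lazy per-replicate adjusted p.

    Degrees of freedom are truncated to integers for the multivariate-t
    evaluation, the same convention the procedures use by default.
    """

    def __init__(self, method, setting, C, means, svars, alpha, seed, qmc):
        self.method = method
        self.alpha = alpha
        self.qmc = dict(_SIM_QMC, **(qmc or {}))
        self.seed = seed
        n = setting.n
        codes = setting.group_codes
        w = n - 1.0
        reps = means.shape[0]
        s2g = np.empty((reps, setting.H))
        for h, members in enumerate(setting.variance_groups):
            members = list(members)
            s2g[:, h] = (w[members] * svars[:, members]).sum(axis=1) / w[members].sum()
        pooled = (w * svars).sum(axis=1) / (n.sum() - n.size)
        self.Cm = C.matrix
        C2, C4 = self.Cm**2, self.Cm**4
        if method == "HOM":
            W = pooled[:, None] / n  # (reps, k)
        elif method in ("SDF", "PIa", "PH", "PHmax"):
            W = s2g[:, codes] / n
        elif method == "PI":
            W = svars / n
        elif method == "SW":
            W = svars / (n - 1.0)
        else:
            raise ValueError(f"unknown method {method!r}")
        self.W = W
        self.v = W @ C2.T
        self.T = (means @ self.Cm.T - 0.0) / np.sqrt(self.v)
        N, k = int(n.sum()), n.size
        if method in ("HOM", "SDF", "SW"):
            self.df = np.full_like(self.T, float(N - k))
        elif method == "PI":
            self.df = self.v**2 / ((svars / n) ** 2 / w @ C4.T)
        elif method == "PIa":
            self.df = self.v**2 / ((s2g[:, codes] / n) ** 2 / w @ C4.T)
        else:  # PH / PHmax
            absC = np.abs(self.Cm)
            a = np.zeros((C.L, setting.H))
            np.add.at(a.T, codes, absC.T)
            a = a**2
            N_h, I_h = setting.N_h, setting.I_h
            num = (s2g / N_h @ a.T) ** 2
            den = s2g**2 / (N_h**2 * (N_h - I_h)) @ (a**2).T
            df_ph = num / den
            if method == "PHmax":
                df_pia = self.v**2 / ((s2g[:, codes] / n) ** 2 / w @ C4.T)
                self.df = np.maximum(df_ph, df_pia)
            else:
                self.df = df_ph
        self.df = np.maximum(np.floor(self.df), 1.0)
        self.L = C.L
        self.p_single = t_dist.sf(self.T, self.df)
        self.fixed_critical = method == "HOM"
        self._q_fixed = None

    def _fixed_quantile(self):
        if self._q_fixed is None:
            self._q_fixed = equicoordinate_quantile(
                1.0 - self.alpha, self._corr(0), float(self.df[0, 0]),
                eps=1e-4, seed=self.seed, n_max=2**15,
            )
        return self._q_fixed

    def _corr(self, r: int) -> np.ndarray:
        cov = self.Cm @ (self.W[r][:, None] * self.Cm.T)
        d = np.sqrt(np.diag(cov))
        R = cov / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        return R

    def _adj_p(self, r: int, l: int, corr=None) -> float:
        corr = self._corr(r) if corr is None else corr
        qmc_seed = (self.seed * 2654435761 + r * 1009 + l) % 2**31
        p, _ = mvt_cdf(
            np.full(self.L, self.T[r, l]), corr, float(self.df[r, l]),
            seed=qmc_seed, **self.qmc,
        )
        return 1.0 - p

    def any_rejection(self) -> np.ndarray:
        """Per-replicate indicator of at least one rejection."""
        alpha = self.alpha
        if alpha <= 0.0:
            return np.zeros(self.T.shape[0], dtype=bool)
        if self.fixed_critical:
            return np.any(self.T > self._fixed_quantile(), axis=1)
        out = np.zeros(self.T.shape[0], dtype=bool)
        # adjusted p is bracketed by the marginal tail and its Bonferroni
        # multiple, so most replicates never need the multivariate integral
        sure = np.any(self.L * self.p_single < alpha, axis=1)
        out[sure] = True
        maybe = np.nonzero(~sure & np.any(self.p_single < alpha, axis=1))[0]
        for r in maybe:
            corr = self._corr(r)
            for l in np.argsort(self.p_single[r]):
                if self.p_single[r, l] >= alpha:
                    break
                if self._adj_p(r, l, corr) < alpha:
                    out[r] = True
                    break
        return out

    def all_rejected(self, subset) -> np.ndarray:
        """Per-replicate indicator that every contrast in ``subset`` rejects."""
        alpha = self.alpha
        subset = np.asarray(subset, dtype=int)
        if alpha <= 0.0:
            return np.zeros(self.T.shape[0], dtype=bool)
        if self.fixed_critical:
            return np.all(self.T[:, subset] > self._fixed_quantile(), axis=1)
        ps = self.p_single[:, subset]
        out = np.all(self.L * ps < alpha, axis=1)
        maybe = np.nonzero(~out & np.all(ps < alpha, axis=1))[0]
        for r in maybe:
            corr = self._corr(r)
            ok = True
            # check the least significant candidates first
            for l in subset[np.argsort(-self.p_single[r, subset])]:
                if self.L * self.p_single[r, l] < alpha:
                    continue
                if self._adj_p(r, l, corr) >= alpha:
                    ok = False
                    break
            out[r] = ok
        return out


def _as_methods(methods):
    if methods is None:
        return METHODS
    if isinstance(methods, str):
        methods = [m for m in methods.replace(",", " ").split() if m]
    return tuple(_CANON[str(m).lower()] for m in methods)


def simulate_fwe(
    setting,
    family: str,
    methods=None,
    reps: int = 10000,
    alpha: float = 0.05,
    seed: int = 1,
    qmc: dict = None,
) -> pd.DataFrame:
    """Estimate the familywise error rate under the global null.

    Returns a tidy frame (setting, family, method, reps, estimate, mc_se,
    seed); the estimate is the fraction of replicates with at least one
    one-sided rejection at level ``alpha``.  All methods are evaluated on
    identical replicate data; deterministic for a fixed seed.
    """
    if isinstance(setting, str):
        setting = make_setting(setting)
    methods = _as_methods(methods)
    C = family_matrix(family, setting.n)
    rng = np.random.default_rng(seed)
    means, svars = _draw_replicates(setting, int(reps), rng)
    rows = []
    for m in methods:
        eng = _MethodEngine(m, setting, C, means, svars, alpha, seed, qmc)
        hits = eng.any_rejection()
        p_hat = hits.mean()
        rows.append(
            dict(
                setting=setting.label, family=str(family).lower(), method=m,
                reps=int(reps), estimate=float(p_hat),
                mc_se=float(np.sqrt(p_hat * (1 - p_hat) / reps)), seed=seed,
            )
        )
    return pd.DataFrame(rows)


def simulate_power(
    setting,
    family: str,
    effect_grid,
    methods=None,
    reps: int = 10000,
    alpha: float = 0.05,
    seed: int = 1,
    qmc: dict = None,
) -> pd.DataFrame:
    """Complete (all-pairs) power over a grid of mean shifts.

    Treatments 3 and 5 have their means raised by each ``delta`` in
    ``effect_grid``; the estimate is the fraction of replicates in which
    *all* designated false hypotheses of the family reject simultaneously
    (many-to-one: contrasts 2 and 4; all-pairs: contrasts 2, 4, 6, 8, 13 in
    lexicographic order).  At delta = 0 there are no false hypotheses under
    the strict one-sided reading and the reported number is degenerate
    (bounded by the familywise error).
    """
    if isinstance(setting, str):
        setting = make_setting(setting)
    family = str(family).lower()
    if family not in _POWER_SET:
        raise ValueError("power study supports families 'dunnett' and 'tukey'")
    subset = _POWER_SET[family]
    methods = _as_methods(methods)
    C = family_matrix(family, setting.n)
    rows = []
    for delta in np.atleast_1d(np.asarray(effect_grid, dtype=float)):
        shifted = setting.shifted(delta)
        rng = np.random.default_rng(seed)
        means, svars = _draw_replicates(shifted, int(reps), rng)
        for m in methods:
            eng = _MethodEngine(m, shifted, C, means, svars, alpha, seed, qmc)
            hits = eng.all_rejected(subset)
            p_hat = hits.mean()
            rows.append(
                dict(
                    setting=setting.label, family=family, method=m,
                    delta=float(delta), reps=int(reps), estimate=float(p_hat),
                    mc_se=float(np.sqrt(p_hat * (1 - p_hat) / reps)), seed=seed,
                )
            )
    return pd.DataFrame(rows)
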