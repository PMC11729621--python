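"""Contrast estimates, degrees-of-freedom rules and correlation matrices.

Given summary statistics and a contrast matrix, every procedure reduces to
choosing (i) a variance source for the plug-in variance of each treatment
mean and (ii) a degrees-of-freedom rule:

* ``treatment`` -- per-treatment sample variances S_hi^2 (complete
  heteroskedasticity),
* ``group`` -- pooled variance-group estimates S_h^2 (partial
  heteroskedasticity),
* ``pooled_all`` -- the single homoskedastic pool with divisor N - k,
* ``hc3`` -- the HC3 sandwich variance of each cell mean, which for a
  cell-means fit collapses to S_hi^2 / (n_hi - 1).

Degrees of freedom: the Satterthwaite moment-matching rule applied with
either variance source, and the partial-heteroskedasticity extension that
pools information over whole variance groups (divisors N_h and
N_h^2 (N_h - I_h)), which collapses to Satterthwaite when every group
contains a single treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contrasts import ContrastMatrix
from .data import Dataset, SummaryStats

__all__ = [
    "DfVector",
    "mean_variances",
    "contrast_estimates",
    "df_satterthwaite",
    "df_partial",
    "df_phmax",
    "correlation_matrix",
    "hc3_mean_variances",
]

VARIANCE_SOURCES = ("treatment", "group", "pooled_all", "hc3")


@dataclass(frozen=True)
class DfVector:
    """Per-contrast degrees of freedom with the rule that produced them."""

    values: np.ndarray
    method: str  # satt | pia | ph | phmax | single

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("degrees of freedom must be positive and finite")
        if self.method == "single" and np.ptp(v) != 0:
            raise ValueError("method 'single' requires all entries equal")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self):
        return self.values.size


def mean_variances(stats: SummaryStats, variance_source: str) -> np.ndarray:
    """Plug-in variance of each treatment mean, Var(Xbar_hi) = V_hi / n_hi."""
    lay = stats.layout
    if variance_source == "treatment":
        return stats.var_treatment / lay.n
    if variance_source == "group":
        return stats.var_group_per_treatment / lay.n
    if variance_source == "pooled_all":
        return np.full(lay.k, stats.var_pooled_all) / lay.n
    if variance_source == "hc3":
        return stats.var_treatment / (lay.n - 1)
    raise ValueError(f"unknown variance source {variance_source!r}")


def contrast_estimates(stats: SummaryStats, C: ContrastMatrix, variance_source: str):
    """Contrast estimates eta_hat_l and their squared standard errors v_l."""
    _check_aligned(stats, C)
    eta = C.matrix @ stats.mean
    v = (C.matrix**2) @ mean_variances(stats, variance_source)
    if np.any(v <= 0):
        bad = [C.names[i] for i in np.nonzero(v <= 0)[0]]
        raise ValueError(f"zero variance for contrast(s) {bad}")
    return eta, v


def df_satterthwaite(
    stats: SummaryStats, C: ContrastMatrix, variance_source: str = "treatment"
) -> DfVector:
    """Moment-matching degrees of freedom for each contrast.

    df_l = (sum c^2 V/n)^2 / sum c^4 V^2 / (n^2 (n-1)) with V the
    per-treatment (``treatment``) or group-pooled (``group``) variance.
    The two-sample case with per-treatment variances is Welch's df.
    """
    if variance_source not in ("treatment", "group"):
        raise ValueError("variance_source must be 'treatment' or 'group'")
    _check_aligned(stats, C)
    w = mean_variances(stats, variance_source)  # V_hi / n_hi
    num = ((C.matrix**2) @ w) ** 2
    den = (C.matrix**4) @ (w**2 / (stats.layout.n - 1))
    if np.any(den <= 0):
        raise ValueError("zero Satterthwaite denominator (all involved variances zero)")
    return DfVector(num / den, "satt" if variance_source == "treatment" else "pia")


def df_partial(stats: SummaryStats, C: ContrastMatrix, variant: str = "group") -> DfVector:
    """Partial-heteroskedasticity degrees of freedom.

    With a_lh = (sum_i |c_lhi|)^2,

        df_l = (sum_h a_lh S_h^2 / N_h)^2
               / sum_h a_lh^2 S_h^4 / (N_h^2 (N_h - I_h)).

    A contrast supported on a single variance group h gets exactly the
    group's residual df N_h - I_h.  When every group holds one treatment
    this reduces to the Satterthwaite rule with group variances.

    ``variant='per-term'`` keeps, for sensitivity checks only, the rejected
    per-(h,i)-term reading (inner sums taken before squaring per term); it
    is inconsistent with the single-group reduction and is not used by any
    procedure.
    """
    _check_aligned(stats, C)
    lay = stats.layout
    H = lay.H
    codes = lay.group_codes
    absC = np.abs(C.matrix)
    s2 = stats.var_group
    NI = lay.N_h - lay.I_h
    if variant == "group":
        a = np.zeros((C.L, H))
        np.add.at(a.T, codes, absC.T)
        a = a**2  # a_lh = (sum_i |c_lhi|)^2
        num = (a @ (s2 / lay.N_h)) ** 2
        den = (a**2) @ (s2**2 / (lay.N_h**2 * NI))
    elif variant == "per-term":
        # rejected per-(h,i)-term reading: treatment-wise sums throughout
        wt = s2[codes] / lay.N_h[codes]
        num = ((absC**2) @ wt) ** 2
        den = (absC**4) @ (s2[codes] ** 2 / (lay.N_h[codes] ** 2 * NI[codes]))
    else:
        raise ValueError("variant must be 'group' or 'per-term'")
    if np.any(den <= 0):
        raise ValueError("zero denominator in partial-heteroskedasticity df")
    return DfVector(num / den, "ph")


def df_phmax(stats: SummaryStats, C: ContrastMatrix) -> DfVector:
    """Elementwise maximum of the group-Satterthwaite and partial-het df."""
    pia = df_satterthwaite(stats, C, "group").values
    ph = df_partial(stats, C).values
    return DfVector(np.maximum(pia, ph), "phmax")


def correlation_matrix(
    stats: SummaryStats, C: ContrastMatrix, variance_source: str
) -> np.ndarray:
    """Estimated correlation matrix of the contrast test statistics.

    rho_ll' = sum c_l c_l' V/n / sqrt(v_l v_l'), with the chosen plug-in
    variance source; the diagonal is set to exactly one.
    """
    _check_aligned(stats, C)
    w = mean_variances(stats, variance_source)
    cov = C.matrix @ (w[:, None] * C.matrix.T)
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        raise ValueError("zero contrast variance")
    R = cov / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def hc3_mean_variances(data: Dataset) -> np.ndarray:
    """HC3 sandwich variance of each treatment mean, from residuals.

    In the cell-means model every observation has leverage 1/n_hi, so

        Var_HC3(Xbar_hi) = n_hi^{-2} sum_j r_hij^2 / (1 - 1/n_hi)^2,

    which simplifies algebraically to S_hi^2 / (n_hi - 1).  The residual
    form is computed here; the closed form is what ``mean_variances(...,
    'hc3')`` uses, and the two must agree.
    """
    out = np.empty(data.layout.k)
    for j, (x, m) in enumerate(zip(data.observations, data.layout.n)):
        r = x - x.mean()
        out[j] = np.sum((r / (1.0 - 1.0 / m)) ** 2) / m**2
    return out


def _check_aligned(stats: SummaryStats, C: ContrastMatrix) -> None:
    if C.k != stats.layout.k:
        raise ValueError(
            f"contrast matrix has {C.k} columns but layout has {stats.layout.k} treatments"
        )
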