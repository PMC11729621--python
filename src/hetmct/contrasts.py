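"""Contrast-matrix construction for multiple contrast tests.

A contrast matrix C has one row per comparison; each row c_l sums to zero,
so that eta_l = c_l' mu is a linear contrast of the treatment means.  The
built-in families are the classical one-way ones (many-to-one, all-pairs,
trend, each-vs-average) plus a stratified many-to-one family for flattened
two-factor (cell-means) layouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["ContrastMatrix", "build_contrasts", "dunnett_by_stratum"]

_ROWSUM_TOL = 1e-12


@dataclass(frozen=True)
class ContrastMatrix:
    """L x k matrix of named contrast rows aligned to a treatment order."""

    matrix: np.ndarray
    names: tuple

    def __post_init__(self):
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", m)
        names = tuple(str(x) for x in self.names) if self.names is not None else tuple(
            f"c{l + 1}" for l in range(m.shape[0])
        )
        object.__setattr__(self, "names", names)
        if len(names) != m.shape[0]:
            raise ValueError("one name per contrast row required")
        if not np.all(np.isfinite(m)):
            raise ValueError("contrast coefficients must be finite")
        rowsum = np.abs(m.sum(axis=1))
        if np.any(rowsum > _ROWSUM_TOL * np.maximum(1.0, np.abs(m).sum(axis=1))):
            bad = [names[i] for i in np.nonzero(rowsum > _ROWSUM_TOL)[0]]
            raise ValueError(f"contrast rows must sum to zero, violated by {bad}")
        if np.any(np.all(m == 0, axis=1)):
            raise ValueError("all-zero contrast row")

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def __neg__(self) -> "ContrastMatrix":
        """Sign-flipped matrix (turns a 'greater' family into 'less')."""
        return ContrastMatrix(-self.matrix, self.names)

    def to_frame(self, treatments=None) -> pd.DataFrame:
        cols = list(treatments) if treatments is not None else [
            f"t{j + 1}" for j in range(self.k)
        ]
        return pd.DataFrame(self.matrix, index=list(self.names), columns=cols)

    def to_csv(self, path, treatments=None) -> None:
        self.to_frame(treatments).to_csv(path, index_label="contrast")

    @classmethod
    def from_csv(cls, path) -> "ContrastMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), tuple(df.index.astype(str)))


def build_contrasts(
    family: str,
    k: int,
    n=None,
    user_matrix=None,
    names=None,
    *,
    weighted_average: bool = True,
) -> ContrastMatrix:
    """Build a named contrast family for ``k`` treatments.

    Families
    --------
    dunnett : k-1 comparisons of treatments 2..k vs treatment 1 (control).
    tukey : all k(k-1)/2 pairwise comparisons, later minus earlier, in
        lexicographic order (1,2), (1,3), ..., (k-1,k).
    williams : k-1 trend rows; row l compares the sample-size-weighted mean
        of the l highest treatments against the control (requires ``n``).
    average : k rows, each treatment vs the sample-size-weighted average
        of the remaining treatments (the standard many-one construction;
        unweighted complements via ``weighted_average=False`` or when no
        ``n`` is given).
    user : ``user_matrix`` validated and wrapped.
    """
    if k < 2:
        raise ValueError("need at least two treatments")
    family = family.lower()
    if family == "dunnett":
        m = np.zeros((k - 1, k))
        m[:, 0] = -1.0
        m[np.arange(k - 1), np.arange(1, k)] = 1.0
        labels = [f"mu{j + 2}-mu1" for j in range(k - 1)]
    elif family == "tukey":
        pairs = list(combinations(range(k), 2))
        m = np.zeros((len(pairs), k))
        for l, (i, j) in enumerate(pairs):
            m[l, i], m[l, j] = -1.0, 1.0
        labels = [f"mu{j + 1}-mu{i + 1}" for i, j in pairs]
    elif family == "williams":
        if n is None:
            raise ValueError("williams contrasts need per-treatment sample sizes")
        n = np.asarray(n, dtype=float)
        if n.size != k:
            raise ValueError("n must have one entry per treatment")
        m = np.zeros((k - 1, k))
        for l in range(1, k):
            top = np.arange(k - l, k)
            m[l - 1, 0] = -1.0
            m[l - 1, top] = n[top] / n[top].sum()
        labels = [f"williams{l + 1}" for l in range(k - 1)]
    elif family == "average":
        if n is None or not weighted_average:
            n = np.ones(k)
        n = np.asarray(n, float)
        m = np.zeros((k, k))
        for i in range(k):
            rest = np.arange(k) != i
            m[i, i] = 1.0
            m[i, rest] = -n[rest] / n[rest].sum()
        labels = [f"mu{i + 1}-rest" for i in range(k)]
    elif family == "user":
        if user_matrix is None:
            raise ValueError("family 'user' needs user_matrix")
        m = np.atleast_2d(np.asarray(user_matrix, dtype=float))
        if m.shape[1] != k:
            raise ValueError(f"user matrix has {m.shape[1]} columns, expected {k}")
        labels = None
    else:
        raise ValueError(f"unknown contrast family {family!r}")
    if names is not None:
        labels = list(names)
    return ContrastMatrix(m, tuple(labels) if labels is not None else None)


def dunnett_by_stratum(
    n_strata: int,
    n_levels: int,
    control_level: int = 1,
    level_names=None,
    stratum_names=None,
) -> ContrastMatrix:
    """Many-to-one comparisons of factor levels, split per stratum.

    Assumes a flattened two-factor cell-means order that is level-major and
    stratum-minor (level 1 stratum 1, level 1 stratum 2, ..., level 2
    stratum 1, ...).  For each non-control level and each stratum one row
    compares that cell against the control level's cell in the same
    stratum, giving L = (n_levels - 1) * n_strata contrasts.  With a single
    stratum this is exactly the many-to-one (Dunnett) family.
    """
    if not 1 <= control_level <= n_levels:
        raise ValueError("control level out of range")
    lev = list(level_names) if level_names is not None else [
        f"L{j + 1}" for j in range(n_levels)
    ]
    strat = list(stratum_names) if stratum_names is not None else [
        f"s{j + 1}" for j in range(n_strata)
    ]
    c0 = control_level - 1
    k = n_strata * n_levels
    rows, labels = [], []
    for j in range(n_levels):
        if j == c0:
            continue
        for s in range(n_strata):
            row = np.zeros(k)
            row[j * n_strata + s] = 1.0
            row[c0 * n_strata + s] = -1.0
            rows.append(row)
            labels.append(f"{lev[j]}-{lev[c0]}:{strat[s]}")
    return ContrastMatrix(np.array(rows), tuple(labels))
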