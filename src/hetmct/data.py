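"""Data containers for one-way layouts with variance groups.

The sampling model is a (pseudo) one-way layout in which every treatment
belongs to exactly one *variance group*: observations X_hij ~ N(mu_hi, sigma_h^2)
for group h = 1..H, treatment i = 1..I_h within the group, and replicate
j = 1..n_hi.  Treatments inside a group are homoskedastic, treatments from
different groups may have different variances ("partial heteroskedasticity").

Everything downstream (contrast estimates, degrees of freedom, correlation
matrices) depends on the data only through :class:`SummaryStats`, so summary
tables of (mean, variance, n) are a first-class input alongside raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VarianceLayout",
    "Dataset",
    "SummaryStats",
    "load_dataset",
    "load_summary_stats",
    "summarize",
    "exact_moment_sample",
    "mycotoxin_summary",
    "mycotoxin_dataset",
    "MYCOTOXIN_TABLE",
]


@dataclass(frozen=True)
class VarianceLayout:
    """Treatment/variance-group structure of a partially heteroskedastic layout.

    Parameters
    ----------
    treatments : tuple of str
        Treatment labels in canonical order (group-major, first appearance).
    groups : tuple of str
        Variance-group label of each treatment, aligned with ``treatments``.
    n : ndarray of int
        Per-treatment sample sizes n_hi (each >= 2).
    """

    treatments: tuple
    groups: tuple
    n: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "treatments", tuple(str(t) for t in self.treatments))
        object.__setattr__(self, "groups", tuple(str(g) for g in self.groups))
        object.__setattr__(self, "n", np.asarray(self.n, dtype=int))
        if len(self.treatments) != len(self.groups) or len(self.treatments) != self.n.size:
            raise ValueError("treatments, groups and n must have equal length")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("treatment labels must be unique")
        if np.any(self.n < 2):
            bad = [t for t, m in zip(self.treatments, self.n) if m < 2]
            raise ValueError(f"every treatment needs n >= 2, violated by {bad}")
        # group labels in first-appearance order
        seen = {}
        for g in self.groups:
            seen.setdefault(g, len(seen))
        object.__setattr__(self, "_group_labels", tuple(seen))
        codes = np.array([seen[g] for g in self.groups], dtype=int)
        object.__setattr__(self, "_group_codes", codes)
        if np.any(np.diff(codes) < 0):
            # canonical order is group-major: all of group 1, then group 2, ...
            raise ValueError("treatments must be ordered group-major (contiguous groups)")
        N_h = np.bincount(codes, weights=self.n).astype(int)
        I_h = np.bincount(codes).astype(int)
        if np.any(N_h - I_h < 1):
            raise ValueError("each variance group needs N_h - I_h >= 1 residual df")
        object.__setattr__(self, "_N_h", N_h)
        object.__setattr__(self, "_I_h", I_h)

    # -- derived structure ------------------------------------------------
    @property
    def group_labels(self) -> tuple:
        """Variance-group labels in first-appearance order."""
        return self._group_labels

    @property
    def group_codes(self) -> np.ndarray:
        """Integer group index (0-based) per treatment."""
        return self._group_codes

    @property
    def H(self) -> int:
        return len(self._group_labels)

    @property
    def I_h(self) -> np.ndarray:
        """Number of treatments per variance group."""
        return self._I_h

    @property
    def N_h(self) -> np.ndarray:
        """Total observations per variance group."""
        return self._N_h

    @property
    def k(self) -> int:
        """Total number of treatments."""
        return len(self.treatments)

    @property
    def N(self) -> int:
        """Total number of observations."""
        return int(self.n.sum())


@dataclass(frozen=True)
class Dataset:
    """Raw observations aligned to a :class:`VarianceLayout`."""

    layout: VarianceLayout
    observations: tuple  # tuple of 1-d float arrays, one per treatment

    def __post_init__(self):
        obs = tuple(np.asarray(x, dtype=float) for x in self.observations)
        object.__setattr__(self, "observations", obs)
        if len(obs) != self.layout.k:
            raise ValueError("need one observation vector per treatment")
        for t, x, m in zip(self.layout.treatments, obs, self.layout.n):
            if x.ndim != 1 or x.size != m:
                raise ValueError(f"treatment {t}: expected {m} observations, got {x.size}")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"treatment {t}: non-finite observation")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns treatment, variance_group, value."""
        rows = []
        for t, g, x in zip(self.layout.treatments, self.layout.groups, self.observations):
            rows.extend((t, g, v) for v in x)
        return pd.DataFrame(rows, columns=["treatment", "variance_group", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SummaryStats:
    """Per-treatment means/variances and pooled group variances.

    ``var_group`` pools the within-treatment sums of squares over each
    variance group:

        S_h^2 = sum_i sum_j (X_hij - Xbar_hi)^2 / sum_i (n_hi - 1),

    i.e. the (n_hi - 1)-weighted average of the per-treatment sample
    variances S_hi^2.  ``var_pooled_all`` pools across *all* treatments with
    divisor N - k (the homoskedastic residual variance).
    """

    layout: VarianceLayout
    mean: np.ndarray
    var_treatment: np.ndarray
    var_group: np.ndarray = field(default=None)
    var_pooled_all: float = field(default=None)

    def __post_init__(self):
        lay = self.layout
        mean = np.asarray(self.mean, dtype=float)
        vt = np.asarray(self.var_treatment, dtype=float)
        if mean.size != lay.k or vt.size != lay.k:
            raise ValueError("mean and var_treatment must have one entry per treatment")
        if np.any(vt < 0) or not np.all(np.isfinite(vt)) or not np.all(np.isfinite(mean)):
            raise ValueError("means must be finite and variances finite nonnegative")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "var_treatment", vt)
        w = lay.n - 1
        if self.var_group is None:
            vg = np.bincount(lay.group_codes, weights=w * vt) / np.bincount(
                lay.group_codes, weights=w
            )
            object.__setattr__(self, "var_group", vg)
        else:
            vg = np.asarray(self.var_group, dtype=float)
            if vg.size != lay.H or np.any(vg < 0):
                raise ValueError("var_group must hold one nonnegative value per group")
            object.__setattr__(self, "var_group", vg)
        if self.var_pooled_all is None:
            object.__setattr__(
                self, "var_pooled_all", float(np.sum(w * vt) / (lay.N - lay.k))
            )

    @property
    def var_group_per_treatment(self) -> np.ndarray:
        """Group variance S_h^2 broadcast to treatment order."""
        return self.var_group[self.layout.group_codes]

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        *,
        treatment_col: str = "treatment",
        group_col: str = "variance_group",
        mean_col: str = "mean",
        var_col: str = "variance",
        n_col: str = "n",
        variance: str = "treatment",
    ) -> "SummaryStats":
        """Build summary statistics from a (mean, variance, n) table.

        ``variance='treatment'`` reads per-treatment sample variances and
        pools them per group; ``variance='group'`` reads the column as the
        group variance S_h^2 directly (must be constant within a group).
        """
        for col in (treatment_col, group_col, mean_col, var_col, n_col):
            if col not in table.columns:
                raise ValueError(f"missing column {col!r}")
        layout = VarianceLayout(
            treatments=tuple(table[treatment_col].astype(str)),
            groups=tuple(table[group_col].astype(str)),
            n=table[n_col].to_numpy(),
        )
        mean = table[mean_col].to_numpy(dtype=float)
        var = table[var_col].to_numpy(dtype=float)
        if variance == "treatment":
            return cls(layout=layout, mean=mean, var_treatment=var)
        if variance == "group":
            vg = np.empty(layout.H)
            for h in range(layout.H):
                vals = var[layout.group_codes == h]
                if np.ptp(vals) > 1e-8 * max(1.0, abs(vals[0])):
                    raise ValueError("group variance column not constant within a group")
                vg[h] = vals[0]
            # per-treatment variances unknown; carry the group value so that
            # sources requiring S_hi^2 degrade gracefully rather than silently
            return cls(layout=layout, mean=mean, var_treatment=vg[layout.group_codes],
                       var_group=vg)
        raise ValueError("variance must be 'treatment' or 'group'")

    def to_frame(self) -> pd.DataFrame:
        lay = self.layout
        return pd.DataFrame(
            {
                "treatment": lay.treatments,
                "variance_group": lay.groups,
                "mean": self.mean,
                "variance": self.var_treatment,
                "group_variance": self.var_group_per_treatment,
                "n": lay.n,
            }
        )


def load_dataset(
    path,
    *,
    treatment_col: str = "treatment",
    group_col: str = "variance_group",
    value_col: str = "value",
) -> Dataset:
    """Read a long-format CSV (one row per observation) into a :class:`Dataset`.

    The layout is inferred from the distinct (group, treatment) labels in
    first-appearance order of the groups; a treatment listed under two
    different group labels is an error.
    """
    df = pd.read_csv(path)
    for col in (treatment_col, group_col, value_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    vals = pd.to_numeric(df[value_col], errors="coerce")
    if vals.isna().any():
        raise ValueError("non-numeric or missing response value")
    df = df.assign(**{value_col: vals})
    mapping = df.groupby(treatment_col, sort=False)[group_col].nunique()
    if (mapping > 1).any():
        bad = mapping[mapping > 1].index.tolist()
        raise ValueError(f"treatment(s) {bad} appear under more than one variance group")
    # group-major canonical order, groups by first appearance
    group_order = list(dict.fromkeys(df[group_col].astype(str)))
    treatments, groups, obs = [], [], []
    for g in group_order:
        sub = df[df[group_col].astype(str) == g]
        for t in dict.fromkeys(sub[treatment_col].astype(str)):
            x = sub[sub[treatment_col].astype(str) == t][value_col].to_numpy(float)
            treatments.append(t)
            groups.append(g)
            obs.append(x)
    layout = VarianceLayout(treatments=treatments, groups=groups, n=[len(x) for x in obs])
    return Dataset(layout=layout, observations=tuple(obs))


def load_summary_stats(path, *, variance: str = "treatment", **cols) -> SummaryStats:
    """Read a summary-statistics CSV (mean, variance, n per treatment)."""
    return SummaryStats.from_table(pd.read_csv(path), variance=variance, **cols)


def summarize(data: Dataset) -> SummaryStats:
    """Compute per-treatment means/variances and pooled group variances."""
    mean = np.array([x.mean() for x in data.observations])
    var = np.array(
        [x.var(ddof=1) for x in data.observations]
    )
    return SummaryStats(layout=data.layout, mean=mean, var_treatment=var)


def exact_moment_sample(mean: float, variance: float, n: int, seed) -> np.ndarray:
    """Vector of length ``n`` with *exactly* the requested sample moments.

    Draws a seeded standard-normal base vector, centers and rescales it so
    that the sample mean equals ``mean`` and the sample variance (divisor
    n - 1) equals ``variance``.  With ``variance == 0`` the constant vector
    is returned.  Used to reconstruct raw-data fixtures from printed summary
    tables.
    """
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    if n < 2:
        raise ValueError("need n >= 2")
    if variance == 0:
        return np.full(n, float(mean))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    while True:
        z = rng.standard_normal(n)
        z = z - z.mean()
        s = z.std(ddof=1)
        if s > 0:
            break
    return mean + z * (np.sqrt(variance) / s)


# Zearalenone (ZEN, ug/kg) summary statistics from a fungicide spraying-technique
# field trial in forage maize: five techniques V1..V5 (the variance groups) at
# three locations (Ba, He, Ho), four observations per cell.  Columns:
# technique, location, sample mean, sample variance.
MYCOTOXIN_TABLE = (
    ("V1", "Ba", 497.52, 84635.05),
    ("V1", "He", 585.28, 49174.28),
    ("V1", "Ho", 478.32, 52283.96),
    ("V2", "Ba", 1965.56, 256303.16),
    ("V2", "He", 2260.34, 834927.58),
    ("V2", "Ho", 2253.57, 1019235.99),
    ("V3", "Ba", 991.48, 18453.55),
    ("V3", "He", 648.84, 42016.15),
    ("V3", "Ho", 1424.02, 115393.80),
    ("V4", "Ba", 657.07, 125209.92),
    ("V4", "He", 296.00, 8175.27),
    ("V4", "Ho", 591.76, 19782.83),
    ("V5", "Ba", 556.12, 74933.46),
    ("V5", "He", 260.68, 13950.44),
    ("V5", "Ho", 585.82, 22691.60),
)

_MYCOTOXIN_N = 4


def mycotoxin_summary() -> SummaryStats:
    """Summary statistics of the mycotoxin spraying-technique trial.

    15 treatments (technique x location cells, group-major order V1Ba, V1He,
    V1Ho, V2Ba, ...), variance groups = spraying techniques (H = 5, I_h = 3,
    n = 4 everywhere).  Group variances are pooled from the per-cell sample
    variances.
    """
    df = pd.DataFrame(
        {
            "treatment": [f"{v}{loc}" for v, loc, _, _ in MYCOTOXIN_TABLE],
            "variance_group": [v for v, _, _, _ in MYCOTOXIN_TABLE],
            "mean": [m for _, _, m, _ in MYCOTOXIN_TABLE],
            "variance": [s2 for _, _, _, s2 in MYCOTOXIN_TABLE],
            "n": _MYCOTOXIN_N,
        }
    )
    return SummaryStats.from_table(df)


def mycotoxin_dataset(seed=0) -> Dataset:
    """Raw-data reconstruction of the mycotoxin trial by exact moment matching.

    Different seeds give different raw values but identical summary
    statistics (and therefore identical test results).
    """
    rng = np.random.default_rng(seed)
    stats = mycotoxin_summary()
    obs = tuple(
        exact_moment_sample(m, v, _MYCOTOXIN_N, rng)
        for m, v in zip(stats.mean, stats.var_treatment)
    )
    return Dataset(layout=stats.layout, observations=obs)
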