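"""Multiple contrast test procedures for partially heteroskedastic layouts.

The model object :class:`MultipleContrastTest` holds the data (raw or
summary form) and a contrast matrix; :meth:`~MultipleContrastTest.fit`
evaluates one of seven procedures and returns an :class:`MCTResults` with
per-contrast estimates, standard errors, test statistics, degrees of
freedom, one-sided adjusted p-values and simultaneous lower confidence
bounds.

Procedures
----------
HOM
    Classical homoskedastic MCT: single pooled variance, df = N - k.
SDF
    Group variances in the statistics/correlations but a single manually
    set residual df = N - k.
SW
    HC3 sandwich variances of the cell means (requires raw data), single
    df = N - k.
PI
    Plug-in procedure under complete heteroskedasticity: per-treatment
    variances, per-contrast Satterthwaite df.
PIa
    PI with group-pooled variances everywhere (statistics, correlations,
    Satterthwaite df).
PH
    Group-pooled variances with the partial-heteroskedasticity df rule,
    which borrows the whole variance group's replication.
PHmax
    PH with the elementwise maximum of the PIa and PH degrees of freedom.

All hypotheses are one-sided, H0l: eta_l <= delta_l against greater, with
rejection for large positive statistics; test the 'less' direction by
negating the contrast matrix.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .contrasts import ContrastMatrix, build_contrasts
from .data import Dataset, SummaryStats, summarize
from .inference import (
    DfVector,
    contrast_estimates,
    correlation_matrix,
    df_partial,
    df_phmax,
    df_satterthwaite,
    hc3_mean_variances,
)
from .mvt import adjusted_p, equicoordinate_quantile

__all__ = ["MultipleContrastTest", "MCTResults", "run_mct", "lower_bounds", "METHODS"]

METHODS = ("HOM", "SDF", "SW", "PI", "PIa", "PH", "PHmax")
_CANON = {m.lower(): m for m in METHODS}

_SOURCE = {
    "HOM": "pooled_all",
    "SDF": "group",
    "SW": "hc3",
    "PI": "treatment",
    "PIa": "group",
    "PH": "group",
    "PHmax": "group",
}


def _eval_df(df: np.ndarray, df_mode: str) -> np.ndarray:
    """Degrees of freedom as passed to the multivariate t."""
    if df_mode == "floor":
        return np.maximum(np.floor(df), 1.0)
    if df_mode == "round":
        return np.maximum(np.round(df), 1.0)
    if df_mode == "exact":
        return np.asarray(df, float)
    raise ValueError("df_mode must be 'floor', 'round' or 'exact'")


def lower_bounds(eta, v, df, corr, alpha, *, eps=1e-5, seed=0, n_max=2**17):
    """Simultaneous one-sided lower confidence bounds.

    lower_l = eta_hat_l - t_{L, df_l, R, 1-alpha} * sqrt(v_l), with the
    equicoordinate (1-alpha) quantile of the L-variate t; each contrast
    uses its own degrees of freedom.
    """
    eta = np.asarray(eta, float)
    v = np.asarray(v, float)
    dfv = np.broadcast_to(np.asarray(df, float), eta.shape)
    qs = {}
    for d in np.unique(dfv):
        qs[d] = equicoordinate_quantile(
            1.0 - alpha, corr, d, L=eta.size, eps=eps, seed=seed, n_max=n_max
        )
    q = np.array([qs[d] for d in dfv])
    return eta - q * np.sqrt(v)


class MultipleContrastTest:
    """Multiple contrast test model for a variance-grouped one-way layout.

    Parameters
    ----------
    data : Dataset or SummaryStats
        Raw observations or summary statistics.  The SW procedure needs
        raw data (it is residual-based); everything else works from
        summaries alone.
    contrasts : ContrastMatrix or str
        A contrast matrix aligned to the layout's treatment order, or a
        family name passed to :func:`hetmct.contrasts.build_contrasts`.
    delta : float or array, optional
        Per-contrast thresholds delta_l of H0l: eta_l <= delta_l (default 0).
    """

    def __init__(self, data, contrasts, *, delta=0.0):
        if isinstance(data, Dataset):
            self.data = data
            self.stats = summarize(data)
        elif isinstance(data, SummaryStats):
            self.data = None
            self.stats = data
        else:
            raise TypeError("data must be a Dataset or SummaryStats")
        lay = self.stats.layout
        if isinstance(contrasts, str):
            contrasts = build_contrasts(contrasts, lay.k, n=lay.n)
        if not isinstance(contrasts, ContrastMatrix):
            contrasts = ContrastMatrix(np.asarray(contrasts, float), None)
        if contrasts.k != lay.k:
            raise ValueError("contrast matrix does not match the treatment count")
        self.contrasts = contrasts
        self.delta = np.broadcast_to(np.asarray(delta, float), (contrasts.L,)).copy()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, contrasts, *, summary=False,
                       variance="treatment", delta=0.0, **cols):
        """Build the model from a long-format or summary-statistics table."""
        if summary:
            data = SummaryStats.from_table(frame, variance=variance, **cols)
        else:
            import io

            buf = io.StringIO()
            frame.to_csv(buf, index=False)
            buf.seek(0)
            from .data import load_dataset

            data = load_dataset(buf, **cols)
        return cls(data, contrasts, delta=delta)

    def _degrees(self, method: str, df_variant: str) -> DfVector:
        lay = self.stats.layout
        if method in ("HOM", "SDF", "SW"):
            return DfVector(np.full(self.contrasts.L, float(lay.N - lay.k)), "single")
        if method == "PI":
            return df_satterthwaite(self.stats, self.contrasts, "treatment")
        if method == "PIa":
            return df_satterthwaite(self.stats, self.contrasts, "group")
        if method == "PH":
            return df_partial(self.stats, self.contrasts, variant=df_variant)
        if method == "PHmax":
            return df_phmax(self.stats, self.contrasts)
        raise ValueError(f"unknown method {method!r}")

    def fit(
        self,
        method: str = "PH",
        *,
        alpha: float = 0.05,
        qmc_eps: float = 1e-5,
        seed: int = 0,
        df_variant: str = "group",
        df_mode: str = "floor",
        compute_bounds: bool = True,
    ) -> "MCTResults":
        """Run one procedure and return its results object.

        ``df_mode`` controls how the (generally non-integer) per-contrast
        degrees of freedom enter the multivariate-t evaluation: ``'floor'``
        (default) truncates to integers, matching the behaviour of the
        standard multivariate-t software used in multiple-comparison
        practice (and hence published reference tables); ``'exact'`` uses
        the continuous df directly; ``'round'`` rounds.  Reported df are
        always the exact values.
        """
        try:
            method = _CANON[str(method).lower()]
        except KeyError:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        source = _SOURCE[method]
        C = self.contrasts
        if method == "SW":
            if self.data is None:
                raise ValueError("SW requires raw data (residual-based HC3 estimator)")
            w = hc3_mean_variances(self.data)
            eta = C.matrix @ self.stats.mean
            v = (C.matrix**2) @ w
            cov = C.matrix @ (w[:, None] * C.matrix.T)
            d = np.sqrt(np.diag(cov))
            corr = cov / np.outer(d, d)
            np.fill_diagonal(corr, 1.0)
        else:
            eta, v = contrast_estimates(self.stats, C, source)
            corr = correlation_matrix(self.stats, C, source)
        dfv = self._degrees(method, df_variant)
        df_eval = _eval_df(dfv.values, df_mode)
        tstat = (eta - self.delta) / np.sqrt(v)
        pvals = adjusted_p(tstat, df_eval, corr, eps=qmc_eps, seed=seed)
        lower = None
        if compute_bounds:
            lower = self.delta + lower_bounds(
                eta - self.delta, v, df_eval, corr, alpha, eps=qmc_eps, seed=seed
            )
        return MCTResults(
            model=self,
            method=method,
            alpha=alpha,
            names=C.names,
            estimate=eta,
            se=np.sqrt(v),
            statistic=tstat,
            df=dfv,
            pvalues=pvals,
            lower=lower,
            corr=corr,
            delta=self.delta,
            metadata={
                "variance_source": source,
                "df_method": dfv.method,
                "df_mode": df_mode,
                "qmc_eps": qmc_eps,
                "seed": seed,
            },
        )

    def fit_all(self, methods=None, **kwargs) -> dict:
        """Fit several procedures on identical inputs; dict keyed by method."""
        methods = METHODS if methods is None else methods
        return {m: self.fit(m, **kwargs) for m in methods}


class MCTResults:
    """Results of one multiple contrast test procedure."""

    def __init__(self, *, model, method, alpha, names, estimate, se, statistic,
                 df, pvalues, lower, corr, delta, metadata):
        self.model = model
        self.method = method
        self.alpha = alpha
        self.names = names
        self.estimate = estimate
        self.se = se
        self.statistic = statistic
        self.df = df
        self.pvalues = pvalues
        self.lower = lower
        self.corr = corr
        self.delta = delta
        self.metadata = metadata

    @property
    def reject(self) -> np.ndarray:
        """One-sided rejections at the familywise level alpha."""
        return self.pvalues < self.alpha

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "contrast": list(self.names),
                "estimate": self.estimate,
                "se": self.se,
                "statistic": self.statistic,
                "df": self.df.values,
                "adj_pvalue": self.pvalues,
                "delta": self.delta,
                "reject": self.reject,
            }
        )
        if self.lower is not None:
            df.insert(6, "lower_bound", self.lower)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "method": self.method,
            "alpha": self.alpha,
            **{k: v for k, v in self.metadata.items()},
            "results": self.to_frame().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)

    def summary(self, sig_marker: bool = True) -> str:
        """Report table: p-values to 4 decimals, df to 2 (as printed reports do)."""
        lines = [
            f"Multiple contrast test: {self.method} "
            f"(variance source: {self.metadata['variance_source']})",
            f"One-sided greater, familywise alpha = {self.alpha:g}, "
            f"L = {len(self.names)} contrasts",
            "",
        ]
        head = f"{'contrast':<16}{'estimate':>12}{'se':>10}{'stat':>8}{'df':>9}{'adj p':>9}"
        if self.lower is not None:
            head += f"{'lower':>12}"
        lines.append(head)
        lines.append("-" * len(head))
        for l, name in enumerate(self.names):
            row = (
                f"{name:<16}{self.estimate[l]:>12.2f}{self.se[l]:>10.2f}"
                f"{self.statistic[l]:>8.2f}{self.df.values[l]:>9.2f}"
                f"{self.pvalues[l]:>9.4f}"
            )
            if self.lower is not None:
                row += f"{self.lower[l]:>12.2f}"
            if sig_marker and self.pvalues[l] < self.alpha:
                row += "  *"
            lines.append(row)
        lines.append("")
        lines.append(f"* adjusted p < {self.alpha:g}")
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<MCTResults {self.method}: {int(self.reject.sum())}/{len(self.names)} "
            f"rejections at alpha={self.alpha:g}>"
        )


def run_mct(data, contrasts, method="PH", *, alpha=0.05, delta=0.0, **fit_kwargs):
    """One-call interface: build the model and fit a single procedure."""
    return MultipleContrastTest(data, contrasts, delta=delta).fit(
        method, alpha=alpha, **fit_kwargs
    )
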