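import numpy as np
import pytest

import hetmct as hm
from hetmct.inference import (
    contrast_estimates,
    correlation_matrix,
    df_partial,
    df_phmax,
    df_satterthwaite,
    hc3_mean_variances,
    mean_variances,
)

from conftest import random_layout

# degrees of freedom of the mycotoxin example, per contrast (printed report)
DF_PI = [4.79, 3.35, 3.31, 4.25, 5.96, 5.26, 5.78, 3.97, 4.99, 5.98, 4.58, 5.19]
DF_PIA = [3.52] * 3 + [6.00] * 3 + [5.94] * 3 + [5.65] * 3
DF_PH = [10.57] * 3 + [17.99] * 3 + [17.83] * 3 + [16.94] * 3


class TestEstimates:
    def test_printed_first_contrast(self, myco_stats, C12):
        eta, v = contrast_estimates(myco_stats, C12, "group")
        assert eta[0] == pytest.approx(1468.04, abs=0.005)
        assert v[0] == pytest.approx((62031.10 + 703488.91) / 4, rel=1e-6)

    def test_null_case_equal_means(self):
        lay = hm.VarianceLayout(["a", "b"], ["g", "g"], [4, 4])
        stats = hm.SummaryStats(layout=lay, mean=[5.0, 5.0], var_treatment=[1.0, 2.0])
        eta, _ = contrast_estimates(stats, hm.build_contrasts("dunnett", 2), "group")
        assert eta[0] == 0.0

    def test_treatment_source_matches_elementwise_formula(self, myco_stats, C12):
        eta, v = contrast_estimates(myco_stats, C12, "treatment")
        lay = myco_stats.layout
        for l in range(C12.L):
            brute = sum(
                C12.matrix[l, j] ** 2 * myco_stats.var_treatment[j] / lay.n[j]
                for j in range(lay.k)
            )
            assert v[l] == pytest.approx(brute, rel=1e-12)

    def test_zero_variance_error(self):
        lay = hm.VarianceLayout(["a", "b"], ["g", "g"], [4, 4])
        stats = hm.SummaryStats(layout=lay, mean=[0.0, 1.0], var_treatment=[0.0, 0.0])
        with pytest.raises(ValueError, match="zero variance"):
            contrast_estimates(stats, hm.build_contrasts("dunnett", 2), "group")


class TestDegreesOfFreedom:
    def test_satterthwaite_against_printed_table(self, myco_stats, C12):
        np.testing.assert_allclose(
            np.round(df_satterthwaite(myco_stats, C12, "treatment").values, 2), DF_PI
        )
        np.testing.assert_allclose(
            np.round(df_satterthwaite(myco_stats, C12, "group").values, 2), DF_PIA
        )

    def test_partial_against_printed_table(self, myco_stats, C12):
        np.testing.assert_allclose(np.round(df_partial(myco_stats, C12).values, 2), DF_PH)

    def test_phmax_is_elementwise_max(self, myco_stats, C12):
        mx = df_phmax(myco_stats, C12).values
        pia = df_satterthwaite(myco_stats, C12, "group").values
        ph = df_partial(myco_stats, C12).values
        np.testing.assert_allclose(mx, np.maximum(pia, ph))
        assert mx[0] == pytest.approx(10.57, abs=0.005)

    def test_balanced_homoskedastic_pair_is_welch_limit(self):
        # equal variances, equal n: Welch df equals the pooled 2(n-1)
        lay = hm.VarianceLayout(["a", "b"], ["g1", "g2"], [6, 6])
        stats = hm.SummaryStats(layout=lay, mean=[0.0, 1.0], var_treatment=[3.0, 3.0])
        df = df_satterthwaite(stats, hm.build_contrasts("dunnett", 2), "treatment")
        assert df.values[0] == pytest.approx(10.0, rel=1e-12)

    def test_within_group_contrast_gets_residual_df(self, myco_stats):
        # a contrast supported on one variance group: df = N_h - I_h exactly
        row = np.zeros(15)
        row[0], row[1] = 1, -1  # V1Ba - V1He, both in group V1
        C = hm.ContrastMatrix(row, ("within-V1",))
        df = df_partial(myco_stats, C)
        assert df.values[0] == pytest.approx(12 - 3, rel=1e-12)

    def test_per_term_variant_doubles_within_group_df(self, myco_stats):
        row = np.zeros(15)
        row[0], row[1] = 1, -1
        C = hm.ContrastMatrix(row, ("within-V1",))
        df = df_partial(myco_stats, C, variant="per-term")
        assert df.values[0] == pytest.approx(2 * (12 - 3), rel=1e-12)

    def test_single_treatment_groups_reduce_to_satterthwaite(self):
        rng = np.random.default_rng(3)
        data = random_layout(rng, H=3, max_treatments=1)
        stats = hm.summarize(data)
        C = hm.build_contrasts("tukey", stats.layout.k)
        np.testing.assert_allclose(
            df_partial(stats, C).values,
            df_satterthwaite(stats, C, "group").values,
            rtol=1e-10,
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_df_bracketing(self, seed):
        data = random_layout(np.random.default_rng(seed))
        stats = hm.summarize(data)
        if stats.layout.k < 2 or np.any(stats.var_treatment <= 0):
            pytest.skip("degenerate draw")
        C = hm.build_contrasts("tukey", stats.layout.k)
        lay = stats.layout
        satt = df_satterthwaite(stats, C, "treatment").values
        ph = df_partial(stats, C).values
        for l in range(C.L):
            trts = np.nonzero(C.matrix[l])[0]
            lo = np.min(lay.n[trts] - 1)
            hi = np.sum(lay.n[trts] - 1)
            assert lo - 1e-9 <= satt[l] <= hi + 1e-9
            grps = np.unique(lay.group_codes[trts])
            lo_g = np.min((lay.N_h - lay.I_h)[grps])
            hi_g = np.sum((lay.N_h - lay.I_h)[grps])
            assert lo_g - 1e-9 <= ph[l] <= hi_g + 1e-9


class TestCorrelation:
    def test_dunnett_balanced_half(self):
        lay = hm.VarianceLayout(list("abcd"), ["g"] * 4, [5] * 4)
        stats = hm.SummaryStats(layout=lay, mean=np.zeros(4), var_treatment=np.full(4, 2.0))
        R = correlation_matrix(stats, hm.build_contrasts("dunnett", 4), "pooled_all")
        off = R[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, rtol=1e-12)

    def test_disjoint_support_uncorrelated(self):
        lay = hm.VarianceLayout(list("abcd"), ["g"] * 4, [5] * 4)
        stats = hm.SummaryStats(layout=lay, mean=np.zeros(4), var_treatment=np.full(4, 2.0))
        C = hm.ContrastMatrix([[1, -1, 0, 0], [0, 0, 1, -1]], ("p1", "p2"))
        R = correlation_matrix(stats, C, "group")
        assert R[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_against_brute_force_formula(self, myco_stats, C12):
        R = correlation_matrix(myco_stats, C12, "group")
        lay = myco_stats.layout
        w = myco_stats.var_group_per_treatment / lay.n
        for l in range(3):
            for m in range(C12.L):
                num = np.sum(C12.matrix[l] * C12.matrix[m] * w)
                den = np.sqrt(np.sum(C12.matrix[l] ** 2 * w) * np.sum(C12.matrix[m] ** 2 * w))
                assert R[l, m] == pytest.approx(num / den, rel=1e-10)

    @pytest.mark.parametrize("source", ["treatment", "group", "pooled_all", "hc3"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_psd_property(self, source, seed):
        data = random_layout(np.random.default_rng(seed + 10))
        stats = hm.summarize(data)
        if stats.layout.k < 2 or np.any(stats.var_treatment <= 0):
            pytest.skip("degenerate draw")
        R = correlation_matrix(stats, hm.build_contrasts("tukey", stats.layout.k), source)
        assert np.min(np.linalg.eigvalsh(R)) >= -1e-10
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(R), 1.0)


class TestInvariances:
    def test_scale_invariance(self, myco_data, C12):
        stats = hm.summarize(myco_data)
        scaled = hm.summarize(
            hm.Dataset(
                layout=myco_data.layout,
                observations=tuple(7.0 * x for x in myco_data.observations),
            )
        )
        def tstat(s):
            eta, v = contrast_estimates(s, C12, "group")
            return eta / np.sqrt(v)

        np.testing.assert_allclose(tstat(stats), tstat(scaled), rtol=1e-9)
        np.testing.assert_allclose(
            df_partial(stats, C12).values, df_partial(scaled, C12).values, rtol=1e-9
        )
        np.testing.assert_allclose(
            correlation_matrix(stats, C12, "group"),
            correlation_matrix(scaled, C12, "group"),
            rtol=1e-9,
        )

    def test_contrast_row_scaling_invariance(self, myco_stats, C12):
        scale = np.linspace(1, 4, C12.L)
        C2 = hm.ContrastMatrix(C12.matrix * scale[:, None], C12.names)
        eta1, v1 = contrast_estimates(myco_stats, C12, "group")
        eta2, v2 = contrast_estimates(myco_stats, C2, "group")
        np.testing.assert_allclose(eta2 / np.sqrt(v2), eta1 / np.sqrt(v1), rtol=1e-12)
        np.testing.assert_allclose(
            df_partial(myco_stats, C2).values, df_partial(myco_stats, C12).values, rtol=1e-12
        )
        np.testing.assert_allclose(
            correlation_matrix(myco_stats, C2, "group"),
            correlation_matrix(myco_stats, C12, "group"),
            rtol=1e-12,
        )


class TestHC3:
    def test_residual_form_equals_closed_form(self, myco_data):
        resid = hc3_mean_variances(myco_data)
        stats = hm.summarize(myco_data)
        closed = stats.var_treatment / (stats.layout.n - 1)
        np.testing.assert_allclose(resid, closed, rtol=1e-10)
        np.testing.assert_allclose(mean_variances(stats, "hc3"), closed, rtol=1e-12)

    def test_zero_residuals(self):
        lay = hm.VarianceLayout(["a"], ["g"], [4])
        with pytest.raises(ValueError):
            # single treatment cannot form a contrast layout with k >= 2,
            # but HC3 itself still works on the dataset
            hm.build_contrasts("dunnett", 1)
        data = hm.Dataset(layout=lay, observations=(np.full(4, 3.0),))
        assert hc3_mean_variances(data)[0] == 0.0
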