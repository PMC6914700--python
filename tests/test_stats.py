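import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from braineff import (
    adjusted_regression,
    anova_three_group,
    chi_square,
    composite_z,
    fdr_bh,
    kruskal_wallis,
    normalize_log_wmh,
)


class TestNormalizeLogWmh:
    def test_closed_form(self):
        assert normalize_log_wmh(1000.0, 1_000_000.0) == pytest.approx(-3.0)
        assert normalize_log_wmh(5.0, 5.0) == pytest.approx(0.0)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            normalize_log_wmh(0.0, 1e6)
        with pytest.raises(ValueError):
            normalize_log_wmh(10.0, -1.0)


class TestCompositeZ:
    def test_single_instrument_z(self):
        scores = pd.DataFrame({"test1": [8.0, 10.0, 12.0]})
        z = composite_z(scores, {"dom": [("test1", False)]})
        # x=12 with sample mean 10, population sd: z = 2/sd
        sd = np.std([8, 10, 12])
        assert z.dom.iloc[2] == pytest.approx(2.0 / sd)
        assert z.dom.mean() == pytest.approx(0.0, abs=1e-10)

    def test_opposed_instruments_cancel(self):
        scores = pd.DataFrame({"u": [1.0, 2.0, 3.0], "v": [3.0, 2.0, 1.0]})
        z = composite_z(scores, {"dom": [("u", False), ("v", False)]})
        np.testing.assert_allclose(z.dom, 0.0, atol=1e-12)

    def test_timed_scores_enter_as_reciprocal(self):
        secs = pd.DataFrame({"tmt_a_seconds": [40.0, 50.0, 80.0]})
        z = composite_z(secs, {"speed": [("tmt_a_seconds", True)]})
        inv = 1.0 / secs.tmt_a_seconds  # 40 s -> 0.025 before z-scoring
        expected = (inv - inv.mean()) / inv.std(ddof=0)
        np.testing.assert_allclose(z.speed, expected, atol=1e-12)

    def test_zero_variance_instrument_named(self):
        scores = pd.DataFrame({"flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            composite_z(scores, {"dom": [("flat", False)]})

    def test_instrument_zscores_have_unit_moments(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame({"a": rng.normal(10, 2, 50)})
        z = composite_z(scores, {"dom": [("a", False)]})
        assert z.dom.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.dom.std(ddof=0) == pytest.approx(1.0, abs=1e-10)


class TestAnova:
    def test_hand_computed_f(self):
        r = anova_three_group({"HC": [1, 2, 3], "WMH-NC": [2, 3, 4], "WMH-CIND": [3, 4, 5]})
        assert r.f == pytest.approx(3.0)

    def test_flat_groups_not_significant(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1e-6, 10)
        r = anova_three_group({g: 5.0 + base + rng.normal(0, 1e-6, 10) for g in ("HC", "WMH-NC", "WMH-CIND")})
        assert not r.significant

    def test_shifted_group_flagged_in_posthocs(self):
        rng = np.random.default_rng(2)
        vals = {
            "HC": rng.normal(0, 1, 30),
            "WMH-NC": rng.normal(0, 1, 30),
            "WMH-CIND": rng.normal(5, 1, 30),
        }
        r = anova_three_group(vals)
        assert r.significant
        assert r.posthoc_p["HC vs WMH-CIND"] < 0.05 / 3
        assert r.posthoc_p["WMH-NC vs WMH-CIND"] < 0.05 / 3
        assert r.posthoc_significant["HC vs WMH-CIND"]

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_three_group({"HC": [1.0], "WMH-NC": [1, 2], "WMH-CIND": [1, 2]})

    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        r = anova_three_group({"HC": a, "WMH-NC": b})
        t = sps.ttest_ind(a, b, equal_var=True).statistic
        assert r.f == pytest.approx(t**2)


class TestFdr:
    def test_all_small_p_rejected(self):
        reject, adj = fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_retained(self):
        reject, adj = fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_single_p_reduces_to_raw_threshold(self):
        reject, _ = fdr_bh([0.04], q=0.05)
        assert reject.all()

    def test_empty_input(self):
        reject, adj = fdr_bh([])
        assert reject.size == 0 and adj.size == 0

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50), st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None)
    def test_bh_monotone_and_superset_of_bonferroni(self, pvals, _seed):
        q = 0.05
        reject, adj = fdr_bh(pvals, q)
        order = np.argsort(pvals)
        assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()
        bonf = np.asarray(pvals) < q / len(pvals)
        assert (bonf <= reject).all()


class TestOtherTests:
    def test_kruskal_identical_distributions(self):
        rng = np.random.default_rng(4)
        vals = {g: rng.normal(0, 1, 30) for g in ("HC", "WMH-NC", "WMH-CIND")}
        h, p = kruskal_wallis(vals)
        assert p > 0.01

    def test_kruskal_separated_ranks(self):
        vals = {
            "HC": np.arange(30, dtype=float),
            "WMH-NC": np.arange(30, dtype=float) + 100,
            "WMH-CIND": np.arange(30, dtype=float) + 200,
        }
        _, p = kruskal_wallis(vals)
        assert p < 0.001

    def test_chi_square_balanced_counts(self):
        chi2, p = chi_square([[10, 10, 10], [10, 10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi_square_degenerate_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0, 0], [0, 0, 0]])


class TestAdjustedRegression:
    @staticmethod
    def _frame(rng, n, beta_x=0.0):
        x = rng.standard_normal(n)
        return pd.DataFrame(
            {
                "x": x,
                "age": rng.normal(60, 8, n),
                "gender": rng.integers(0, 2, n),
                "education": rng.normal(11, 3, n),
                "y": beta_x * x + rng.standard_normal(n),
            }
        )

    def test_exact_linear_relation(self):
        rng = np.random.default_rng(5)
        df = self._frame(rng, 100)
        df["y"] = df["x"]
        res = adjusted_regression(df, "y", "x")
        assert res.loc["x", "beta"] == pytest.approx(1.0, abs=1e-8)
        assert res.loc["x", "p"] < 1e-10

    def test_null_association_near_zero(self):
        rng = np.random.default_rng(60)
        res = adjusted_regression(self._frame(rng, 2000), "y", "x")
        assert abs(res.loc["x", "beta"]) < 0.05

    def test_effect_recovery(self):
        rng = np.random.default_rng(7)
        res = adjusted_regression(self._frame(rng, 2000, beta_x=0.5), "y", "x")
        # y has variance 1.25, so the standardized slope is 0.5/sqrt(1.25)
        assert res.loc["x", "beta"] == pytest.approx(0.5 / np.sqrt(1.25), abs=0.06)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(8)
        df = self._frame(rng, 50)
        df["age"] = df["x"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            adjusted_regression(df, "y", "x")
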