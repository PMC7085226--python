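import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mpmquant import (
    GroupSummary,
    compare_groups,
    summarize,
    t_test_from_summary,
    t_test_from_values,
)
from mpmquant.stats import p_value_bin
from mpmquant.errors import InsufficientDataError

# Published two-group summaries (nuclear area px^2 and collagen %):
PRE_AREA = GroupSummary("pre", "nuclear_area_px2", 30, 596.56, 208.69)
POST_AREA = GroupSummary("post", "nuclear_area_px2", 30, 856.22, 255.74)
PRE_COLL = GroupSummary("pre", "collagen_content_pct", 30, 22.81, 10.23)
POST_COLL = GroupSummary("post", "collagen_content_pct", 30, 36.10, 12.42)


class TestSummarize:
    @pytest.mark.parametrize(
        "values, mean, sd",
        [([1, 3], 2.0, math.sqrt(2)), ([5, 5, 5], 5.0, 0.0)],
    )
    def test_closed_forms(self, values, mean, sd):
        s = summarize(values)
        assert s.mean == pytest.approx(mean)
        assert s.sd == pytest.approx(sd)
        assert s.n == len(values)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize([1.0])


class TestTTest:
    def test_identical_summaries_null(self):
        s = GroupSummary("a", "m", 10, 5.0, 2.0)
        res = t_test_from_summary(s, s)
        assert res.t_statistic == 0.0 and res.p_value == 1.0 and not res.significant

    @pytest.mark.parametrize(
        "a, b, t_expected",
        [
            # frozen from an independent evaluation of the pooled closed form
            (PRE_AREA, POST_AREA, 4.308669341224651),
            (PRE_COLL, POST_COLL, 4.523887361238085),
        ],
    )
    def test_published_summaries_match_independent_oracle(self, a, b, t_expected):
        res = t_test_from_summary(a, b, variant="pooled")
        assert res.t_statistic == pytest.approx(t_expected, rel=1e-6)
        assert res.degrees_of_freedom == 58
        assert res.p_value < 0.001
        oracle = sps.ttest_ind_from_stats(
            b.mean, b.sd, b.n, a.mean, a.sd, a.n, equal_var=True
        )
        assert res.t_statistic == pytest.approx(oracle.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(oracle.pvalue, rel=1e-12)

    def test_welch_equals_pooled_t_for_equal_n(self):
        pooled = t_test_from_summary(PRE_AREA, POST_AREA, "pooled")
        welch = t_test_from_summary(PRE_AREA, POST_AREA, "welch")
        assert pooled.t_statistic == pytest.approx(welch.t_statistic, rel=1e-12)
        assert welch.degrees_of_freedom < pooled.degrees_of_freedom

    def test_antisymmetric_t_and_invariant_p_under_swap(self):
        fwd = t_test_from_summary(PRE_COLL, POST_COLL)
        rev = t_test_from_summary(POST_COLL, PRE_COLL)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_zero_variance_conventions(self):
        same = t_test_from_values([3.0] * 4, [3.0] * 4)
        assert same.t_statistic == 0.0 and same.p_value == 1.0 and same.zero_variance
        diff = t_test_from_values([0.0] * 4, [1.0] * 4)
        assert math.isinf(diff.t_statistic) and diff.p_value == 0.0
        assert diff.zero_variance and diff.significant

    def test_values_and_summary_paths_agree(self, rng):
        a = rng.normal(10, 3, 25)
        b = rng.normal(12, 4, 30)
        via_values = t_test_from_values(a, b)
        via_summary = t_test_from_summary(summarize(a), summarize(b))
        assert via_values.t_statistic == pytest.approx(
            via_summary.t_statistic, rel=1e-13
        )
        scipy_res = sps.ttest_ind(b, a, equal_var=True)
        assert via_values.t_statistic == pytest.approx(scipy_res.statistic, rel=1e-12)
        assert via_values.p_value == pytest.approx(scipy_res.pvalue, rel=1e-12)

    def test_p_value_bins(self):
        assert p_value_bin(0.0005) == "<0.001"
        assert p_value_bin(0.005) == "<0.01"
        assert p_value_bin(0.03) == "<0.05"
        assert p_value_bin(0.2) == "ns"


class TestCompareGroups:
    @staticmethod
    def _tables(rng, n=30):
        pre = pd.DataFrame(
            dict(
                nuclear_area_px2=rng.normal(596.56, 208.69, n),
                collagen_content_pct=rng.normal(22.81, 10.23, n),
            )
        )
        post = pd.DataFrame(
            dict(
                nuclear_area_px2=rng.normal(856.22, 255.74, n),
                collagen_content_pct=rng.normal(36.10, 12.42, n),
            )
        )
        return pre, post

    def test_structure_and_significance_at_published_effects(self, rng):
        pre, post = self._tables(rng)
        table = compare_groups(pre, post)
        assert list(table.metric) == ["nuclear_area_px2", "collagen_content_pct"]
        assert (table.n_pre == 30).all() and (table.n_post == 30).all()
        assert table.significant.all()
        assert {"welch_t", "p_bin", "degrees_of_freedom"} <= set(table.columns)

    def test_single_sample_group_rejected(self, rng):
        pre, post = self._tables(rng)
        with pytest.raises(InsufficientDataError):
            compare_groups(pre.iloc[:1], post)

    def test_type_i_error_near_alpha(self):
        # equal-variance normal null: rejection rate at alpha=0.05 must sit
        # in [0.03, 0.07] over 1000 seeded replicates
        rng = np.random.default_rng(1234)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0, 1, 30)
            b = rng.normal(0, 1, 30)
            if t_test_from_values(a, b).significant:
                hits += 1
        assert 0.03 <= hits / n_rep <= 0.07


class TestPropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(finite, min_size=2, max_size=40),
        st.lists(finite, min_size=2, max_size=40),
    )
    def test_pooled_t_and_p_match_scipy_for_arbitrary_samples(self, a, b):
        res = t_test_from_values(a, b, variant="pooled")
        if res.zero_variance:
            assert res.p_value in (0.0, 1.0)
            return
        oracle = sps.ttest_ind(np.asarray(b), np.asarray(a), equal_var=True)
        assert res.t_statistic == pytest.approx(oracle.statistic, rel=1e-9, abs=1e-12)
        assert res.p_value == pytest.approx(oracle.pvalue, rel=1e-9, abs=1e-12)
        assert 0.0 <= res.p_value <= 1.0
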