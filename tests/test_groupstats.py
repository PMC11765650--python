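"""Nonparametric comparisons: descriptives, rank tests, report tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forasym import (
    BilateralPair,
    Cohort,
    Group,
    HorizontalTrait,
    Sex,
    cohort_fa_table,
    kruskal_wallis,
    mann_whitney,
    posthoc_pairwise,
    summarize,
)
from forasym.groupstats import (
    VARIABLE_ORDER,
    group_comparison_report,
    sex_comparison_report,
)

from conftest import make_record


class TestSummarize:
    def test_closed_form(self):
        s = summarize([1, 2, 3])
        assert (s.mean, s.median, s.sd, s.n) == (2.0, 2.0, 1.0, 3)

    def test_even_n_median_midpoint(self):
        assert summarize([1, 3]).median == 2.0

    def test_single_value(self):
        s = summarize([5])
        assert s.mean == 5.0 and s.sd == 0.0
        with pytest.raises(ValueError):
            summarize([5], strict=True)

    def test_empty_is_domain_error(self):
        with pytest.raises(ValueError):
            summarize([])


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        # enumeration over all C(6,3) = 20 equally likely rank splits
        # gives P(U = 0) = 1/20 per tail, two-sided p = 0.1
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u_statistic == 0.0
        assert r.p_value == pytest.approx(0.1)

    def test_identical_multisets(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.u_statistic == 4.5  # n^2 / 2
        assert r.p_value >= 0.99

    def test_single_observations(self):
        assert mann_whitney([1], [2]).u_statistic == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=20),
        b=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=20),
    )
    def test_u_and_mirror_sum_to_n1n2(self, a, b):
        u_ab = mann_whitney(a, b).u_statistic
        u_ba = mann_whitney(b, a).u_statistic
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert 0.0 <= u_ab <= len(a) * len(b)


class TestKruskalWallis:
    def test_hand_oracle(self):
        # ranks 1..6, rank sums 3/7/11:
        # H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 32/7
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert r.chi2 == pytest.approx(32.0 / 7.0)
        assert r.df == 2

    def test_identical_groups_degenerate(self):
        r = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert r.chi2 == 0.0 and r.p_value == 1.0 and r.df == 2

    def test_df_always_k_minus_1(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            groups = [rng.normal(size=rng.integers(2, 9)) for _ in range(3)]
            assert kruskal_wallis(groups).df == 2

    def test_two_group_case_monotone_in_mann_whitney_distance(self):
        """For two groups, H grows with |U - n1 n2 / 2|."""
        rng = np.random.default_rng(1)
        a = rng.normal(size=12)
        hs, dists = [], []
        for shift in (0.0, 0.5, 1.5, 4.0):
            b = rng.normal(size=12) + shift
            u = mann_whitney(a, b).u_statistic
            dists.append(abs(u - 72.0))
            hs.append(kruskal_wallis([a, b]).chi2)
        order = np.argsort(dists)
        assert list(np.argsort(hs)) == list(order)


class TestPosthoc:
    def test_identical_groups_all_near_one(self):
        ph = posthoc_pairwise([[1, 2, 3]] * 3, labels=["a", "b", "c"])
        assert len(ph) == 3
        assert all(p >= 0.99 for p in ph.values())

    @pytest.mark.parametrize("method", ["dscf", "dunn"])
    def test_shifted_group_has_smallest_pairwise_ps(self, method):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=15), rng.normal(size=15)
        c = rng.normal(size=15) + 8.0
        ph = posthoc_pairwise([a, b, c], labels=["a", "b", "c"], method=method)
        assert len(ph) == 3
        assert ph[("a", "c")] < ph[("a", "b")]
        assert ph[("b", "c")] < ph[("a", "b")]
        assert all(0.0 <= p <= 1.0 for p in ph.values())

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="post-hoc"):
            posthoc_pairwise([[1], [2], [3]], method="tukey")


def test_null_type_one_error_both_tests():
    """Identically distributed groups reject at ~alpha: empirical rate
    within [0.03, 0.07] over 1,000 seeded replicates for both tests."""
    rng = np.random.default_rng(42)
    rej_mw = rej_kw = 0
    n_rep = 1000
    for _ in range(n_rep):
        if mann_whitney(rng.normal(size=15), rng.normal(size=15)).p_value <= 0.05:
            rej_mw += 1
        if kruskal_wallis([rng.normal(size=10) for _ in range(3)]).p_value <= 0.05:
            rej_kw += 1
    assert 0.03 <= rej_mw / n_rep <= 0.07
    assert 0.03 <= rej_kw / n_rep <= 0.07


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _twin_cohort(mfo_mfo_male_offset=0.0):
    """Cohort where each female has a male twin with identical
    measurements, optionally offset on the MFO-MFO distance only."""
    rng = np.random.default_rng(7)
    records = []
    groups = [Group.CONTROL, Group.HE, Group.CH]
    for i in range(12):
        pairs = tuple((5 + rng.normal(0, 0.3), 5 + rng.normal(0, 0.3)) for _ in range(3))
        horiz = tuple(5 + rng.normal(0, 0.3) for _ in range(3))
        g = groups[i % 3]
        records.append(make_record(f"F{i}", Sex.F, g, pairs, horiz))
        horiz_m = (horiz[0], horiz[1], horiz[2] + mfo_mfo_male_offset)
        records.append(make_record(f"M{i}", Sex.M, g, pairs, horiz_m))
    return Cohort(records=records)


def test_sex_report_shape_and_identical_sexes():
    cohort = _twin_cohort()
    rep = sex_comparison_report(cohort, cohort_fa_table(cohort))
    assert len(rep) == 15 * 2
    assert list(rep["variable"].unique()) == VARIABLE_ORDER
    assert (rep["p_value"] >= 0.99).all()


def test_sex_report_detects_targeted_male_offset():
    cohort = _twin_cohort(mfo_mfo_male_offset=3.0)
    rep = sex_comparison_report(cohort, cohort_fa_table(cohort))
    per_var = rep.drop_duplicates("variable").set_index("variable")["p_value"]
    assert per_var.idxmin() == HorizontalTrait.MFO_MFO.value
    assert per_var[HorizontalTrait.MFO_MFO.value] < 0.001


def test_sex_report_requires_both_sexes():
    cohort = Cohort(records=[make_record("A", Sex.F), make_record("B", Sex.F, Group.CH)])
    with pytest.raises(ValueError, match="both sexes"):
        sex_comparison_report(cohort, cohort_fa_table(cohort))


def test_group_report_shape(study_like_cohort, study_like_fa):
    rep = group_comparison_report(study_like_cohort, study_like_fa)
    assert len(rep) == 15
    assert (rep["df"] == 2).all()
    assert rep["p_value"].between(0, 1).all()
    posthoc_cols = [c for c in rep.columns if c.startswith("p_")]
    assert len(posthoc_cols) == 4  # p_value + 3 pairwise columns

def test_group_report_elevated_ch_fa_signal(study_like_cohort, study_like_fa):
    """With the 5x CH asymmetry scale, the SOF-MFO FA rows carry the
    strongest group signal while raw side measurements need not."""
    rep = group_comparison_report(study_like_cohort, study_like_fa).set_index("variable")
    assert rep.loc["SOF-MFO FA1", "p_value"] <= 0.05
    assert rep.loc["SOF-MFO FA2", "p_value"] <= 0.05
    fa_p = rep.loc[["SOF-MFO FA1", "SOF-MFO FA2"], "p_value"].max()
    raw_p = rep.loc[["SOF-MFO right", "SOF-MFO left"], "p_value"].min()
    assert fa_p < raw_p


def test_group_report_requires_all_groups():
    records = [make_record(f"S{i}", Sex.F if i % 2 else Sex.M, Group.CONTROL)
               for i in range(4)]
    cohort = Cohort(records=records)
    with pytest.raises(ValueError, match="missing"):
        group_comparison_report(cohort, cohort_fa_table(cohort))
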