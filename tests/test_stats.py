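"""Repeatability and comparison statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtcine.errors import ConfigError, DataError, ZeroVarianceError
from rtcine.phantom import generate_repeatability_cohort
from rtcine.stats import (
    bh_adjust,
    bland_altman,
    compare_conditions,
    cr_from_summary,
    icc_a1,
    repeatability_coefficient,
    repeatability_table,
    rm_anova,
)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


def test_identical_vectors_have_zero_bias_and_loa():
    r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0


def test_two_point_differences():
    r = bland_altman([0.0, 12.0], [22.0, 0.0])  # d = {-22, 12}
    assert r.bias == pytest.approx(-5.0)
    assert r.sd_diff == pytest.approx(24.04, abs=0.005)


def test_bland_altman_matches_definition_oracle(rng):
    for _ in range(10):
        v1 = rng.normal(100, 15, 12)
        v2 = v1 + rng.normal(-5, 10, 12)
        r = bland_altman(v1, v2)
        d = v1 - v2
        sd = np.sqrt(np.sum((d - d.mean()) ** 2) / (len(d) - 1))  # oracle from scratch
        assert r.bias == pytest.approx(d.mean())
        assert r.sd_diff == pytest.approx(sd)
        assert r.loa_low == pytest.approx(d.mean() - 1.96 * sd)
        assert r.loa_high == pytest.approx(d.mean() + 1.96 * sd)
        assert r.group_mean == pytest.approx((v1.sum() + v2.sum()) / (2 * len(v1)))


def test_fewer_than_two_pairs_rejected():
    with pytest.raises(ConfigError):
        bland_altman([1.0], [2.0])


# ---------------------------------------------------------------------------
# repeatability coefficient
# ---------------------------------------------------------------------------


def test_cr_reproduces_cohort_summary_values():
    """SD(d)=17 mL at a 90 mL mean gives 37%; SD(d)=23 at 109 mL gives 41%."""
    assert cr_from_summary(17.0, 90.0) == pytest.approx(37.0, abs=0.05)
    assert round(cr_from_summary(17.0, 90.0)) == 37
    assert cr_from_summary(23.0, 109.0) == pytest.approx(41.4, abs=0.05)
    assert round(cr_from_summary(23.0, 109.0)) == 41


def test_zero_differences_give_zero_cr():
    assert repeatability_coefficient([5.0, 7.0, 9.0], [5.0, 7.0, 9.0]) == 0.0


def test_nonpositive_group_mean_rejected():
    with pytest.raises(DataError):
        repeatability_coefficient([1.0, -1.0], [-1.0, 1.0])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=0.01, max_value=1e4))
def test_cr_is_scale_invariant(scale):
    v1 = np.array([80.0, 95.0, 102.0, 88.0, 110.0, 91.0])
    v2 = np.array([85.0, 90.0, 99.0, 95.0, 100.0, 96.0])
    base = repeatability_coefficient(v1, v2)
    scaled = repeatability_coefficient(scale * v1, scale * v2)
    assert scaled == pytest.approx(base, rel=1e-9)


# ---------------------------------------------------------------------------
# ICC(A,1)
# ---------------------------------------------------------------------------


def test_identical_sessions_give_perfect_icc():
    x = np.column_stack([[1.0, 5.0, 9.0, 2.0], [1.0, 5.0, 9.0, 2.0]])
    assert icc_a1(x) == pytest.approx(1.0)


def test_constant_matrix_is_undefined():
    with pytest.raises(ZeroVarianceError):
        icc_a1(np.full((5, 2), 3.0))


def test_icc_recovers_simulated_reliability():
    cohort = generate_repeatability_cohort(10_000, sigma_between=3.0, sigma_within=1.0,
                                           grand_mean=90.0, seed=42)
    assert cohort.theoretical_icc == pytest.approx(0.9)
    assert icc_a1(cohort.matrix) == pytest.approx(0.9, abs=0.02)


def test_icc_matches_pingouin_cross_check(rng):
    """Independent route: pingouin's single-rater absolute-agreement ICC."""
    import pingouin as pg

    x = rng.normal(50, 8, (15, 2)) + rng.normal(0, 3, (15, 1))
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile([1, 2], 15),
            "value": x.ravel(),
        }
    )
    table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="value")
    expected = float(table.set_index("Type").loc["ICC(A,1)", "ICC"])
    assert icc_a1(x) == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def _bh_oracle(p):
    """Brute-force step-up: adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[rank_j - 1]] * m / rank_j for rank_j in range(rank_i, m + 1)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


def test_bh_equal_spaced_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def test_bh_single_value_unchanged():
    assert bh_adjust([0.37])[0] == pytest.approx(0.37)


def test_bh_matches_brute_force_oracle(rng):
    for size in (1, 2, 5, 8, 20):
        p = rng.uniform(0, 1, size)
        assert np.allclose(bh_adjust(p), _bh_oracle(p))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
def test_bh_is_monotone_and_dominates_raw(p):
    adj = bh_adjust(np.array(p))
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # preserves the raw ordering


def test_bh_rejects_out_of_range():
    with pytest.raises(ConfigError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# condition comparisons
# ---------------------------------------------------------------------------


def test_identical_conditions_give_null_t():
    table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    out = compare_conditions(table, design="paired")
    assert out.loc[0, "t"] == 0.0 and out.loc[0, "p_raw"] == 1.0


def test_perfectly_linear_methods_correlate_fully():
    table = pd.DataFrame({"m1": [1.0, 2.0, 3.0, 4.0], "m2": [2.0, 4.0, 6.0, 8.0]})
    out = compare_conditions(table, design="paired")
    assert out.loc[0, "r"] == pytest.approx(1.0)


def test_paired_family_is_bh_adjusted(rng):
    table = pd.DataFrame(rng.normal(0, 1, (10, 3)), columns=["rest", "mod", "vig"])
    out = compare_conditions(table, design="paired")
    assert len(out) == 3
    assert np.allclose(out["p_adj"], _bh_oracle(out["p_raw"].to_numpy()))


def test_rm_anova_matches_hand_computed_sums_of_squares():
    table = pd.DataFrame(
        {
            "rest": [90.0, 85.0, 100.0, 95.0],
            "moderate": [102.0, 98.0, 111.0, 105.0],
            "vigorous": [115.0, 108.0, 120.0, 118.0],
        }
    )
    x = table.to_numpy()
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((x - grand) ** 2).sum() - ss_cond - ss_subj
    f_oracle = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    res = rm_anova(table)
    assert res.f == pytest.approx(f_oracle)
    assert (res.df_effect, res.df_error) == (2, 6)

    # independent route: statsmodels AnovaRM on the same data
    from statsmodels.stats.anova import AnovaRM

    long = table.reset_index().melt(id_vars="index", var_name="stage", value_name="value")
    sm = AnovaRM(long, depvar="value", subject="index", within=["stage"]).fit()
    assert res.f == pytest.approx(float(sm.anova_table["F Value"].iloc[0]))
    assert res.p == pytest.approx(float(sm.anova_table["Pr > F"].iloc[0]))


def test_rm_anova_drops_incomplete_subjects():
    table = pd.DataFrame(
        {
            "rest": [90.0, 85.0, 100.0, 95.0, 88.0],
            "moderate": [102.0, 98.0, 111.0, 105.0, 99.0],
            "vigorous": [115.0, 108.0, 120.0, np.nan, np.nan],
        }
    )
    res = rm_anova(table)
    assert res.n_complete == 3 and res.n_dropped == 2


def test_rm_anova_needs_three_conditions():
    with pytest.raises(ConfigError):
        rm_anova(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 3.0]}))


def test_repeatability_table_summarises_cohort():
    cohort = generate_repeatability_cohort(20, sigma_between=10.0, sigma_within=4.0,
                                           grand_mean=90.0, seed=3)
    long = cohort.long.assign(stage="rest", parameter="lv_sv")
    long["session"] = long["session"].str.replace("session_", "").astype(int)
    table = repeatability_table(long)
    assert len(table) == 1
    row = table.iloc[0]
    oracle = bland_altman(cohort.matrix[:, 0], cohort.matrix[:, 1])
    assert row["cr_percent"] == pytest.approx(oracle.cr_percent)
    assert row["bias"] == pytest.approx(oracle.bias)
    assert row["icc_a1"] == pytest.approx(icc_a1(cohort.matrix))
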