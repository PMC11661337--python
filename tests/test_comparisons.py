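"""Comparison statistics: published-cell checks, sufficiency, oracles."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from nsdcog import (build_tables, chi_square_2xk, cohens_d, two_sample_t,
                    two_sample_t_from_summaries)
from nsdcog.comparisons import ComparisonError, pooled_sd


# --- Cohen's d from the published group summary cells -----------------------

@pytest.mark.parametrize("a,b,expected", [
    ((0.07, 0.71, 58), (-0.26, 0.60, 43), 0.50),    # 2A subgroup contrast
    ((-0.13, 0.66, 234), (-0.37, 0.67, 91), 0.36),  # overall subgroup contrast
    ((-0.02, 0.61, 157), (-0.20, 0.63, 176), 0.29), # 2B hyposmia-only vs HC
    ((-0.20, 0.63, 176), (-0.47, 0.72, 48), 0.41),  # 2B subgroup contrast
])
def test_cohens_d_reproduces_published_effect_sizes(a, b, expected):
    assert cohens_d(*a, *b) == pytest.approx(expected, abs=0.01)


def test_cohens_d_identical_groups_is_zero():
    assert cohens_d(0.5, 1.0, 30, 0.5, 1.0, 30) == 0.0


def test_cohens_d_zero_pooled_sd_is_undefined():
    with pytest.raises(ComparisonError, match="undefined"):
        cohens_d(0.1, 0.0, 10, 0.2, 0.0, 10)


def test_pooled_sd_weights_by_dof():
    # closed form: sqrt((9*4 + 19*1)/28)
    assert pooled_sd(2.0, 10, 1.0, 20) == pytest.approx(np.sqrt(55 / 28))


# --- t-tests -----------------------------------------------------------------

def test_identical_samples_give_t0_p1():
    x = np.arange(10.0)
    cmp_ = two_sample_t(x, x.copy())
    assert cmp_.statistic == pytest.approx(0.0)
    assert cmp_.p_value == pytest.approx(1.0)


def test_published_p_value_from_summaries():
    cmp_ = two_sample_t_from_summaries(-0.13, 0.66, 234, -0.37, 0.67, 91)
    assert round(cmp_.p_value, 4) == 0.0036
    assert cmp_.df == 323


def test_summary_and_raw_paths_agree_to_machine_precision():
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 40), rng.normal(0.4, 1.3, 25)
    raw = two_sample_t(a, b)
    summ = two_sample_t_from_summaries(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )
    for field in ("statistic", "p_value", "df", "cohens_d", "mean_difference"):
        assert getattr(raw, field) == pytest.approx(getattr(summ, field),
                                                    abs=1e-12)


def test_antisymmetry_under_group_swap():
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 35)
    ab, ba = two_sample_t(a, b), two_sample_t(b, a)
    assert ab.statistic == pytest.approx(-ba.statistic)
    assert ab.mean_difference == pytest.approx(-ba.mean_difference)
    assert ab.p_value == pytest.approx(ba.p_value)
    assert ab.cohens_d == pytest.approx(ba.cohens_d)


_sample = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=3,
    max_size=25,
)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(a=_sample, b=_sample)
def test_swap_invariance_property(a, b):
    """|d| and p are swap-invariant; t and the mean difference flip sign."""
    a, b = np.asarray(a), np.asarray(b)
    assume(a.std(ddof=1) > 1e-6 or b.std(ddof=1) > 1e-6)
    ab = two_sample_t(a, b)
    ba = two_sample_t(b, a)
    assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)
    assert ab.cohens_d == pytest.approx(ba.cohens_d, abs=1e-12)
    assert ab.statistic == pytest.approx(-ba.statistic, abs=1e-12)
    assert ab.mean_difference == pytest.approx(-ba.mean_difference, abs=1e-12)
    assert 0.0 <= ab.p_value <= 1.0


def test_welch_matches_scipy_unequal_var():
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 20), rng.normal(0.3, 2.5, 50)
    cmp_ = two_sample_t(a, b, kind="welch")
    ref = stats.ttest_ind(a, b, equal_var=False)
    assert cmp_.statistic == pytest.approx(ref.statistic)
    assert cmp_.p_value == pytest.approx(ref.pvalue)
    assert cmp_.kind == "welch_t"


def test_t_requires_two_per_group():
    with pytest.raises(ComparisonError):
        two_sample_t([1.0], [1.0, 2.0])


def test_t_p_matches_permutation_oracle():
    """Pooled t vs a 10^5-draw permutation distribution at n=15/group."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 1.0, 15)
    b = rng.normal(0.6, 1.0, 15)
    p_t = two_sample_t(a, b).p_value
    pool = np.concatenate([a, b])
    n_perm = 100_000
    idx = np.argsort(rng.random((n_perm, 30)), axis=1)[:, :15]
    mean_a = pool[idx].mean(axis=1)
    mean_b = (pool.sum() - pool[idx].sum(axis=1)) / 15
    obs = abs(a.mean() - b.mean())
    p_perm = float((np.abs(mean_a - mean_b) >= obs - 1e-12).mean())
    assert p_t == pytest.approx(p_perm, abs=0.01)


# --- chi-square ---------------------------------------------------------------

def test_chi_square_reproduces_published_sex_p_value():
    cmp_ = chi_square_2xk([[96, 62], [63, 38]])
    assert round(cmp_.p_value, 4) == 0.7944


def test_chi_square_identical_proportions():
    cmp_ = chi_square_2xk([[40, 60], [20, 30]])
    assert cmp_.statistic == pytest.approx(0.0)
    assert cmp_.p_value == pytest.approx(1.0)


@pytest.mark.parametrize("table", [
    [[0, 0], [1, 2]],          # zero row
    [[1, 0], [2, 0]],          # zero column
    [[-1, 2], [3, 4]],         # negative count
    [[1.5, 2], [3, 4]],        # non-integer
])
def test_chi_square_invalid_tables(table):
    with pytest.raises(ComparisonError):
        chi_square_2xk(table)


def _pearson_stat(table):
    """Straight-line Pearson statistic, independent of the implementation."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - e) ** 2 / e
    return stat


def _all_tables(n):
    for a in range(n + 1):
        for b in range(n + 1 - a):
            for c in range(n + 1 - a - b):
                yield np.array([[a, b], [c, n - a - b - c]])


def test_chi_square_matches_enumeration_over_all_n12_tables():
    """Statistic and p match independent formulas on every 2×2 with n=12."""
    for table in _all_tables(12):
        if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
            continue
        cmp_ = chi_square_2xk(table)
        stat = _pearson_stat(table)
        assert cmp_.statistic == pytest.approx(stat, abs=1e-12)
        assert cmp_.p_value == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-12)


def test_chi_square_p_close_to_exact_multinomial_tail_at_n12():
    """Asymptotic p vs the exact multinomial tail under the independence null.

    At n=12 the chi-square approximation is known to deviate from the exact
    tail by several hundredths; agreement within 0.08 confirms the statistic
    is calibrated while acknowledging the small-sample approximation error.
    """
    obs = np.array([[4, 2], [2, 4]])
    n = obs.sum()
    row_p = obs.sum(axis=1) / n
    col_p = obs.sum(axis=0) / n
    null = np.outer(row_p, col_p).ravel()
    s_obs = _pearson_stat(obs)
    exact = 0.0
    for table in _all_tables(n):
        if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
            continue
        if _pearson_stat(table) >= s_obs - 1e-12:
            exact += stats.multinomial.pmf(table.ravel(), n, null)
    p_asym = chi_square_2xk(obs).p_value
    assert p_asym == pytest.approx(float(exact), abs=0.08)


# --- report tables ------------------------------------------------------------

def test_table3_panel_sizes_match_constructed_cohort(scored):
    tables = build_tables(scored)
    t3 = tables["table3"].set_index(["panel", "group"])["n"]
    # 3 stage-2B hyposmia-only and 1 HC lack an evaluable CSS
    assert t3[("overall", "hyposmia_only")] == 234
    assert t3[("overall", "hyposmia_irbd")] == 91
    assert t3[("stage2A", "hyposmia_only")] == 58
    assert t3[("stage2A", "hyposmia_irbd")] == 43
    assert t3[("stage2B", "hyposmia_only")] == 176
    assert t3[("stage2B", "hyposmia_irbd")] == 48
    assert t3[("overall", "HC")] == 157
    cmps = tables["table3_comparisons"]
    assert set(cmps["panel"]) == {"overall", "stage2A", "stage2B"}
    assert (cmps["kind"] == "pooled_t").all()


def test_single_group_yields_no_comparisons(scored):
    hc_only = scored[scored["cohort_role"] == "robust_hc"]
    with pytest.warns(UserWarning):
        tables = build_tables(hc_only)
    assert len(tables["table3_comparisons"]) == 0
    pcols = [c for c in tables["table1"].columns if c.startswith("p_")]
    assert pcols == []
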