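"""ICC, SEM/CoV, bootstrap comparison, repeated-measures ANOVA, paired t."""

import numpy as np
import pandas as pd
import pytest

from graphrely import (
    TwoWayTable,
    VarianceComponents,
    bootstrap_reliability_compare,
    categorize_icc,
    generate_two_way_table,
    icc_absolute_single,
    icc_confidence_interval,
    paired_t,
    rm_anova_2x2,
    sem_and_cov,
)
from graphrely.connectivity import ConfigurationError, InputError
from graphrely.reliability import DegenerateTableError

from oracles import brute_icc, brute_rm_anova


def _random_table(rng, n=12, k=2, subject_sd=1.5):
    vals = rng.normal(size=(n, k)) + subject_sd * rng.normal(size=(n, 1))
    return TwoWayTable(vals)


# ---------------------------------------------------------------------------
# ICC point estimate


def test_icc_hand_example():
    """[[1,2],[3,4]]: MSR=4, MSC=1, MSE=0 -> ICC = 4/(4+1) = 0.8."""
    res = icc_absolute_single(TwoWayTable(np.array([[1.0, 2.0], [3.0, 4.0]])))
    assert res.ms_rows == pytest.approx(4.0)
    assert res.ms_cols == pytest.approx(1.0)
    assert res.ms_error == pytest.approx(0.0, abs=1e-12)
    assert res.icc == pytest.approx(0.8)


def test_icc_perfect_agreement():
    vals = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
    res = icc_absolute_single(TwoWayTable(vals))
    assert res.icc == pytest.approx(1.0)
    assert res.ci_high == pytest.approx(1.0)
    assert res.category == "excellent"


def test_icc_matches_independent_enumeration():
    """The printed-formula implementation matches loop-based mean-squares
    enumeration on 200 random tables to 1e-10."""
    rng = np.random.default_rng(20)
    for trial in range(200):
        n = int(rng.integers(4, 20))
        k = int(rng.integers(2, 5))
        tab = _random_table(rng, n, k, subject_sd=rng.uniform(0.2, 3.0))
        exp_icc, exp_msr, exp_msc, exp_mse = brute_icc(tab.values)
        res = icc_absolute_single(tab)
        assert res.icc_raw == pytest.approx(exp_icc, abs=1e-10)
        assert res.ms_rows == pytest.approx(exp_msr, abs=1e-10)
        assert res.ms_cols == pytest.approx(exp_msc, abs=1e-10)
        assert res.ms_error == pytest.approx(exp_mse, abs=1e-10)


def test_icc_matches_pingouin_absolute_single():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(21)
    for trial in range(10):
        tab = _random_table(rng, n=10)
        df = pd.DataFrame({
            "subj": np.repeat(np.arange(10), 2),
            "sess": np.tile(np.arange(2), 10),
            "y": tab.values.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subj", raters="sess",
                                       ratings="y")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0]
        res = icc_absolute_single(tab)
        assert res.icc_raw == pytest.approx(row.ICC, abs=1e-8)
        lo, hi = row["CI95"]
        assert res.ci_low == pytest.approx(max(lo, 0.0), abs=0.011)
        assert res.ci_high == pytest.approx(min(hi, 1.0), abs=0.011)


def test_icc_negative_clamped_to_zero():
    # strong session effect, no subject effect -> raw ICC < 0
    vals = np.array([[0.0, 10.0], [0.1, 9.9], [-0.1, 10.1], [0.0, 10.0]])
    res = icc_absolute_single(TwoWayTable(vals))
    assert res.icc_raw < 0
    assert res.icc == 0.0
    assert res.ci_low <= res.icc <= res.ci_high


def test_icc_constant_table_raises():
    with pytest.raises(DegenerateTableError):
        icc_absolute_single(TwoWayTable(np.full((4, 2), 3.0)))


def test_icc_shift_invariance():
    rng = np.random.default_rng(22)
    tab = _random_table(rng)
    shifted = TwoWayTable(tab.values + 123.4)
    assert icc_absolute_single(shifted).icc == pytest.approx(
        icc_absolute_single(tab).icc, abs=1e-10)


# ---------------------------------------------------------------------------
# CI behaviour


def test_ci_brackets_point_estimate():
    rng = np.random.default_rng(23)
    for trial in range(20):
        tab = _random_table(rng, n=int(rng.integers(5, 15)))
        res = icc_absolute_single(tab)
        assert res.ci_low <= res.icc <= res.ci_high


def test_ci_coverage_at_icc_075():
    """95% CI contains the analytic ICC 0.75 in 93-97% of 1000 simulated
    tables (n=15, k=2)."""
    vc = VarianceComponents(mu=10.0, var_subject=3.0, var_session=0.0,
                            var_error=1.0)
    assert vc.analytic_icc == pytest.approx(0.75)
    hits = 0
    for seed in range(1000):
        tab = generate_two_way_table(15, 2, vc, seed=50_000 + seed)
        lo, hi = icc_confidence_interval(tab)
        hits += lo <= 0.75 <= hi
    assert 930 <= hits <= 970


def test_icc_parameter_recovery():
    """Mean raw estimate over 1000 replicate tables (n=15, k=2) lies within
    0.05 of the analytic ICC at four reliability levels."""
    for target, var_subject in [(0.2, 0.25), (0.5, 1.0),
                                (0.75, 3.0), (0.9, 9.0)]:
        vc = VarianceComponents(mu=10.0, var_subject=var_subject,
                                var_session=0.0, var_error=1.0)
        est = [icc_absolute_single(
            generate_two_way_table(15, 2, vc, seed=s)).icc_raw
            for s in range(1000)]
        assert np.mean(est) == pytest.approx(target, abs=0.05)
    # zero subject variance: clamped estimates stay small and >= 0
    vc0 = VarianceComponents(mu=10.0, var_subject=0.0, var_session=0.0,
                             var_error=1.0)
    clamped = [icc_absolute_single(
        generate_two_way_table(15, 2, vc0, seed=s)).icc for s in range(300)]
    assert min(clamped) >= 0.0
    assert np.mean(clamped) < 0.15


# ---------------------------------------------------------------------------
# categorisation


@pytest.mark.parametrize("icc, expected", [
    (0.38, "poor"), (0.399, "poor"), (0.4, "fair"), (0.55, "fair"),
    (0.6, "good"), (0.65, "good"), (0.749, "good"),
    (0.75, "excellent"), (0.91, "excellent"), (1.0, "excellent"),
])
def test_categorize_icc(icc, expected):
    assert categorize_icc(icc) == expected


# ---------------------------------------------------------------------------
# SEM / CoV


def test_sem_cov_arithmetic():
    # both sessions [90, 100, 110]: pooled SD 10, grand mean 100
    vals = np.array([[90.0, 90.0], [100.0, 100.0], [110.0, 110.0]])
    res = sem_and_cov(TwoWayTable(vals), icc=0.75, n_boot=100, seed=0)
    assert res.sem == pytest.approx(5.0)
    assert res.cov_percent == pytest.approx(5.0)


def test_sem_cov_perfect_reliability_is_zero():
    vals = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
    res = sem_and_cov(TwoWayTable(vals), n_boot=100, seed=0)
    assert res.sem == 0.0
    assert res.cov_percent == 0.0


def test_sem_shift_invariance_cov_not():
    rng = np.random.default_rng(24)
    tab = TwoWayTable(10.0 + rng.normal(size=(10, 2))
                      + 2 * rng.normal(size=(10, 1)))
    icc = icc_absolute_single(tab).icc
    a = sem_and_cov(tab, icc, n_boot=100, seed=1)
    shifted = TwoWayTable(tab.values + 100.0)
    b = sem_and_cov(shifted, icc, n_boot=100, seed=1)
    assert b.sem == pytest.approx(a.sem, abs=1e-10)
    assert b.cov_percent < a.cov_percent  # mean grew, SEM unchanged


def test_cov_bootstrap_ci_contains_point():
    rng = np.random.default_rng(25)
    inside = 0
    for trial in range(30):
        tab = TwoWayTable(10.0 + rng.normal(size=(15, 2))
                          + rng.normal(size=(15, 1)))
        res = sem_and_cov(tab, n_boot=400, seed=trial)
        inside += res.ci_low <= res.cov_percent <= res.ci_high
    assert inside >= 29


def test_cov_zero_mean_raises():
    vals = np.array([[-1.0, 1.0], [1.0, -1.0]])
    with pytest.raises(DegenerateTableError):
        sem_and_cov(TwoWayTable(vals), icc=0.5, n_boot=50, seed=0)


# ---------------------------------------------------------------------------
# bootstrap comparison


def test_bootstrap_identical_tables_zero_effect():
    tab = generate_two_way_table(
        15, 2, VarianceComponents(10.0, 3.0, 0.0, 1.0), seed=30)
    comp = bootstrap_reliability_compare(tab, tab, "icc", 1000, seed=1)
    assert comp.effect_size_d < 0.05


def test_bootstrap_separates_high_from_low_reliability():
    """Analytic ICC 0.9 vs 0.1 inputs give a large effect (d > 0.8)."""
    ta = generate_two_way_table(
        15, 2, VarianceComponents(10.0, 9.0, 0.0, 1.0), seed=31)
    tb = generate_two_way_table(
        15, 2, VarianceComponents(10.0, 1.0 / 9.0, 0.0, 1.0), seed=32)
    comp = bootstrap_reliability_compare(ta, tb, "icc", 1000, seed=2)
    assert comp.effect_size_d > 0.8
    assert len(comp.dist_a) == len(comp.dist_b) == 1000


def test_bootstrap_determinism():
    ta = generate_two_way_table(
        10, 2, VarianceComponents(5.0, 2.0, 0.1, 1.0), seed=33)
    tb = generate_two_way_table(
        10, 2, VarianceComponents(5.0, 1.0, 0.1, 1.0), seed=34)
    c1 = bootstrap_reliability_compare(ta, tb, "cov", 500, seed=3)
    c2 = bootstrap_reliability_compare(ta, tb, "cov", 500, seed=3)
    np.testing.assert_array_equal(c1.dist_a, c2.dist_a)
    assert c1.effect_size_d == c2.effect_size_d
    c3 = bootstrap_reliability_compare(ta, tb, "cov", 500, seed=4)
    assert not np.array_equal(c1.dist_a, c3.dist_a)


def test_bootstrap_mean_consistent_with_sample_ci():
    tab = generate_two_way_table(
        15, 2, VarianceComponents(10.0, 3.0, 0.0, 1.0), seed=35)
    res = icc_absolute_single(tab)
    comp = bootstrap_reliability_compare(tab, tab, "icc", 1000, seed=5)
    back = np.tanh(comp.dist_a.mean())
    assert res.ci_low <= back <= res.ci_high


def test_bootstrap_validation():
    tab = generate_two_way_table(
        10, 2, VarianceComponents(5.0, 2.0, 0.1, 1.0), seed=36)
    small = generate_two_way_table(
        8, 2, VarianceComponents(5.0, 2.0, 0.1, 1.0), seed=37)
    with pytest.raises(InputError):
        bootstrap_reliability_compare(tab, small, "icc", 500, seed=0)
    with pytest.raises(ConfigurationError):
        bootstrap_reliability_compare(tab, tab, "icc", 50, seed=0)
    with pytest.raises(ConfigurationError):
        bootstrap_reliability_compare(tab, tab, "median", 500, seed=0)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def test_anova_constant_condition_offset_kills_interaction():
    rng = np.random.default_rng(40)
    # dyadic-rational cells keep every mean exact in binary floating point
    pre = rng.integers(-8, 9, size=(8, 2)) / 4.0
    y = np.stack([pre, pre + 3.0], axis=1)  # POST = PRE + 3 everywhere
    res = rm_anova_2x2(y)
    assert res.effects["interaction"].F == pytest.approx(0.0, abs=1e-18)
    assert res.effects["exercise"].p < 1e-6


def test_anova_main_effect_equals_squared_paired_t():
    rng = np.random.default_rng(41)
    y = rng.normal(size=(12, 2, 2)) + rng.normal(size=(12, 1, 1))
    res = rm_anova_2x2(y)
    t, _ = paired_t(y[:, 0, :].mean(axis=1), y[:, 1, :].mean(axis=1))
    assert res.effects["exercise"].F == pytest.approx(t**2, abs=1e-10)


def test_anova_matches_brute_force_enumeration():
    rng = np.random.default_rng(42)
    for trial in range(20):
        n = int(rng.integers(3, 6))
        y = rng.normal(size=(n, 2, 2)) + 0.8 * rng.normal(size=(n, 1, 1))
        res = rm_anova_2x2(y)
        brute = brute_rm_anova(y)
        for eff, (ss_eff, ss_err) in brute.items():
            exp_f = (ss_eff / 1.0) / (ss_err / (n - 1))
            assert res.effects[eff].F == pytest.approx(exp_f, abs=1e-10)
            assert res.effects[eff].df1 == 1
            assert res.effects[eff].df2 == n - 1


def test_anova_matches_statsmodels():
    anova_rm = pytest.importorskip("statsmodels.stats.anova")
    rng = np.random.default_rng(43)
    n = 10
    y = rng.normal(size=(n, 2, 2)) + rng.normal(size=(n, 1, 1))
    df = pd.DataFrame({
        "subj": np.repeat(np.arange(n), 4),
        "A": np.tile(np.repeat([0, 1], 2), n),
        "B": np.tile([0, 1], 2 * n),
        "y": y.ravel(),
    })
    ref = anova_rm.AnovaRM(df, "y", "subj", within=["A", "B"]).fit().anova_table
    res = rm_anova_2x2(y)
    assert res.effects["exercise"].F == pytest.approx(ref.loc["A", "F Value"], abs=1e-8)
    assert res.effects["session"].F == pytest.approx(ref.loc["B", "F Value"], abs=1e-8)
    assert res.effects["interaction"].F == pytest.approx(ref.loc["A:B", "F Value"], abs=1e-8)


def test_anova_validation():
    with pytest.raises(InputError):
        rm_anova_2x2(np.zeros((2, 2, 2)))  # n < 3
    bad = np.zeros((4, 2, 2))
    bad[0, 0, 0] = np.nan
    with pytest.raises(InputError):
        rm_anova_2x2(bad)


# ---------------------------------------------------------------------------
# paired t


def test_paired_t_identical_vectors():
    assert paired_t(np.arange(5.0), np.arange(5.0)) == (0.0, 1.0)


def test_paired_t_hand_example():
    a = np.array([10.0, 12.0, 9.0, 11.0, 14.0])
    b = np.array([9.0, 11.5, 9.5, 10.0, 12.0])
    d = a - b
    exp_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
    t, p = paired_t(a, b)
    assert t == pytest.approx(exp_t, abs=1e-12)
    assert 0 < p < 1


def test_paired_t_shift_invariance():
    a = np.array([1.0, 2.0, 4.0, 8.0])
    b = np.array([1.5, 1.0, 5.0, 7.0])
    t1, _ = paired_t(a, b)
    t2, _ = paired_t(a + 50.0, b + 50.0)
    assert t1 == pytest.approx(t2, abs=1e-12)


def test_paired_t_constant_nonzero_difference_raises():
    with pytest.raises(DegenerateTableError):
        paired_t(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
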