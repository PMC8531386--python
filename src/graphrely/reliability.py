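"""Test-retest reliability statistics on subjects x sessions tables.

Relative reliability is the single-rating absolute-agreement two-way ICC

    ICC = (MSR - MSE) / (MSR + (k - 1) MSE + (k / n)(MSC - MSE))

with MSR/MSC/MSE the subject, session and error mean squares; negative
estimates are reported as 0 and rated poor / fair / good / excellent.
Absolute reliability is the standard error of measurement,
``SEM = SD_pooled * sqrt(1 - ICC)``, and the coefficient of variation,
``CoV% = 100 * SEM / |grand mean|``.  Reliability differences between
conditions are quantified by a paired participant bootstrap: the statistic
is recomputed on each resample for both conditions, ICC distributions are
Fisher-z transformed, and Cohen's d compares the two distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import ConfigurationError, InputError
from .synthetic import TwoWayTable

__all__ = [
    "ICCResult",
    "CoVResult",
    "BootstrapComparison",
    "AnovaEffect",
    "AnovaResult",
    "DegenerateTableError",
    "icc_absolute_single",
    "icc_confidence_interval",
    "categorize_icc",
    "sem_and_cov",
    "bootstrap_reliability_compare",
    "rm_anova_2x2",
    "paired_t",
]

_Z_CLAMP = 1.0 - 1e-6


class DegenerateTableError(ValueError):
    """Statistic undefined on this table (no variance, zero mean...)."""


@dataclass
class ICCResult:
    """Point estimate, 95% CI and category of the two-way absolute ICC.

    ``icc`` is clamped to [0, 1] for reporting; ``icc_raw`` keeps the
    unclamped estimate for bootstrap and CI work.
    """

    icc: float
    icc_raw: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    category: str

    @property
    def n_k(self) -> tuple[float, float]:  # pragma: no cover - debug aid
        return self.ms_rows, self.ms_error


@dataclass
class CoVResult:
    sem: float
    cov_percent: float
    ci_low: float
    ci_high: float


@dataclass
class BootstrapComparison:
    k_cycles: int
    statistic: str
    dist_a: np.ndarray
    dist_b: np.ndarray
    effect_size_d: float
    seed: int
    n_degenerate: int = 0


@dataclass
class AnovaEffect:
    F: float
    p: float
    df1: int
    df2: int


@dataclass
class AnovaResult:
    """2x2 repeated-measures ANOVA: exercise, session, interaction."""

    effects: dict[str, AnovaEffect]


# ---------------------------------------------------------------------------
# ICC


def _mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way mean squares (rows = subjects, columns = sessions)."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = values - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def _icc_point(values: np.ndarray) -> tuple[float, float, float, float]:
    n, k = values.shape
    msr, msc, mse = _mean_squares(values)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateTableError(
            "constant table: all mean squares zero, ICC undefined"
        )
    return (msr - mse) / denom, msr, msc, mse


def categorize_icc(icc: float) -> str:
    """Reliability category: poor < 0.4 <= fair < 0.6 <= good < 0.75 <= excellent.

    Boundary points are assigned to the higher category.
    """
    if icc < 0.4:
        return "poor"
    if icc < 0.6:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def icc_confidence_interval(
    table: TwoWayTable, alpha: float = 0.05
) -> tuple[float, float]:
    """95% CI for the single-rating absolute-agreement ICC.

    F-distribution construction (McGraw-Wong) with a Satterthwaite
    approximation for the denominator degrees of freedom; bounds clamped to
    [0, 1] for reporting.
    """
    values = table.values
    n, k = values.shape
    r, msr, msc, mse = _icc_point(values)
    # Satterthwaite df for the (MSC, MSE) mixture
    rr = max(min(r, _Z_CLAMP), -_Z_CLAMP)
    a = k * rr / (n * (1 - rr))
    b = 1 + k * rr * (n - 1) / (n * (1 - rr))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    v = max(v, 1.0)  # degenerate tables can drive the Satterthwaite df to 0
    f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_star2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (
        n * (msr - f_star * mse)
        / (f_star * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    upper = (
        n * (f_star2 * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_star2 * msr)
    )
    if not np.isfinite(lower):
        lower = 0.0
    if not np.isfinite(upper):
        upper = 1.0
    return float(np.clip(lower, 0.0, 1.0)), float(np.clip(upper, 0.0, 1.0))


def icc_absolute_single(table: TwoWayTable, alpha: float = 0.05) -> ICCResult:
    """Single-rating absolute-agreement two-way ICC with CI and category.

    Estimates below 0 are reported as 0 (the raw value is retained in
    ``icc_raw`` for bootstrap/CI purposes).
    """
    raw, msr, msc, mse = _icc_point(table.values)
    icc = float(max(raw, 0.0))
    ci_low, ci_high = icc_confidence_interval(table, alpha=alpha)
    # reported interval must bracket the reported (clamped) estimate
    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return ICCResult(
        icc=icc, icc_raw=float(raw), ci_low=ci_low, ci_high=ci_high,
        ms_rows=msr, ms_cols=msc, ms_error=mse,
        category=categorize_icc(icc),
    )


# ---------------------------------------------------------------------------
# SEM / CoV


def _pooled_sd(values: np.ndarray) -> float:
    """Between-subject SD pooled across sessions."""
    return float(np.sqrt(np.mean(np.var(values, axis=0, ddof=1))))


def _sem_cov_point(values: np.ndarray, icc: float) -> tuple[float, float]:
    grand = values.mean()
    if grand == 0:
        raise DegenerateTableError("zero grand mean: CoV undefined")
    sem = _pooled_sd(values) * np.sqrt(max(0.0, 1.0 - min(icc, 1.0)))
    return float(sem), float(100.0 * sem / abs(grand))


def sem_and_cov(
    table: TwoWayTable,
    icc: float | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CoVResult:
    """Standard error of measurement and CoV% with a bootstrap CI.

    ``SEM = SD_pooled x sqrt(1 - ICC)`` with the between-subject SD pooled
    across sessions; ``CoV% = 100 SEM / |grand mean|``.  The CI is a seeded
    participant-level percentile bootstrap recomputing ICC, SEM and CoV on
    each resample.
    """
    values = table.values
    if icc is None:
        icc = icc_absolute_single(table).icc
    sem, cov = _sem_cov_point(values, icc)
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    covs = np.empty(n_boot)
    got = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vb = values[idx]
        try:
            icc_b = max(_icc_point(vb)[0], 0.0)
            covs[got] = _sem_cov_point(vb, icc_b)[1]
            got += 1
        except DegenerateTableError:
            continue
    if got == 0:
        raise DegenerateTableError("all bootstrap resamples degenerate")
    lo, hi = np.percentile(covs[:got], [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return CoVResult(sem=sem, cov_percent=cov,
                     ci_low=float(lo), ci_high=float(hi))


# ---------------------------------------------------------------------------
# bootstrap comparison of reliability across conditions


def _fisher_z(r: float) -> float:
    return float(np.arctanh(np.clip(r, -_Z_CLAMP, _Z_CLAMP)))


def bootstrap_reliability_compare(
    table_a: TwoWayTable,
    table_b: TwoWayTable,
    statistic: str = "icc",
    k_cycles: int = 1000,
    seed: int = 0,
) -> BootstrapComparison:
    """Bootstrap effect size for the reliability difference between conditions.

    Each of ``k_cycles`` cycles resamples the n participants with
    replacement — the SAME resample indices for both conditions, since the
    participants are paired across conditions — and recomputes the
    statistic on each resampled table.  ICC cycles use the raw (unclamped)
    estimate and are Fisher-z transformed (clamped at +/-(1 - 1e-6) before
    atanh); CoV cycles stay on the percent scale.  Cohen's d is the
    absolute standardized difference of the two distributions with
    equal-weight pooled SD.  Degenerate resamples are recorded at the
    clamped minimum and counted.
    """
    if statistic not in ("icc", "cov"):
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    if k_cycles < 100:
        raise ConfigurationError("k_cycles must be >= 100")
    if table_a.values.shape != table_b.values.shape:
        raise InputError("condition tables must share n and k")
    n = table_a.n
    rng = np.random.default_rng(seed)
    dist_a = np.empty(k_cycles)
    dist_b = np.empty(k_cycles)
    n_degenerate = 0

    def _stat(values: np.ndarray) -> float:
        if statistic == "icc":
            return _fisher_z(_icc_point(values)[0])
        icc_b = max(_icc_point(values)[0], 0.0)
        return _sem_cov_point(values, icc_b)[1]

    floor = _fisher_z(-1.0) if statistic == "icc" else 0.0
    for c in range(k_cycles):
        idx = rng.integers(0, n, size=n)
        for dist, tab in ((dist_a, table_a), (dist_b, table_b)):
            try:
                dist[c] = _stat(tab.values[idx])
            except DegenerateTableError:
                dist[c] = floor
                n_degenerate += 1
    sd_a = dist_a.std(ddof=1)
    sd_b = dist_b.std(ddof=1)
    pooled = np.sqrt(0.5 * (sd_a**2 + sd_b**2))
    diff = abs(dist_a.mean() - dist_b.mean())
    d = 0.0 if diff == 0 else (np.inf if pooled == 0 else diff / pooled)
    return BootstrapComparison(
        k_cycles=k_cycles, statistic=statistic,
        dist_a=dist_a, dist_b=dist_b,
        effect_size_d=float(d), seed=seed, n_degenerate=n_degenerate,
    )


# ---------------------------------------------------------------------------
# ANOVA and t-tests


def rm_anova_2x2(values: np.ndarray,
                 factor_a: str = "exercise",
                 factor_b: str = "session") -> AnovaResult:
    """Two-way fully within-subject ANOVA on an (n, 2, 2) array.

    ``values[i, a, b]`` is subject ``i`` at level ``a`` of the first factor
    (exercise: PRE/POST) and level ``b`` of the second (session).  Each
    effect is tested against its own subject-by-effect error term at
    df (1, n - 1).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3 or y.shape[1] != 2 or y.shape[2] != 2:
        raise InputError("expected an (n, 2, 2) within-subject array")
    n = y.shape[0]
    if n < 3:
        raise InputError("repeated-measures ANOVA needs n >= 3")
    if not np.all(np.isfinite(y)):
        raise InputError("incomplete cells in within-subject data")
    g = y.mean()
    subj = y.mean(axis=(1, 2))           # (n,)
    A = y.mean(axis=(0, 2))              # (2,)
    B = y.mean(axis=(0, 1))              # (2,)
    AB = y.mean(axis=0)                  # (2, 2)
    SA = y.mean(axis=2)                  # (n, 2) subject x A
    SB = y.mean(axis=1)                  # (n, 2) subject x B

    ss_a = 2 * n * np.sum((A - g) ** 2)
    ss_b = 2 * n * np.sum((B - g) ** 2)
    ss_ab = n * np.sum((AB - A[:, None] - B[None, :] + g) ** 2)
    ss_as = 2 * np.sum((SA - subj[:, None] - A[None, :] + g) ** 2)
    ss_bs = 2 * np.sum((SB - subj[:, None] - B[None, :] + g) ** 2)
    resid = (y - SA[:, :, None] - SB[:, None, :] - AB[None, :, :]
             + subj[:, None, None] + A[None, :, None] + B[None, None, :] - g)
    ss_abs = np.sum(resid**2)

    df_err = n - 1
    effects = {}
    for name, ss_eff, ss_err in (
        (factor_a, ss_a, ss_as),
        (factor_b, ss_b, ss_bs),
        ("interaction", ss_ab, ss_abs),
    ):
        ms_eff = ss_eff / 1.0
        ms_err = ss_err / df_err
        if ms_err == 0:
            f = np.inf if ms_eff > 0 else 0.0
            p = 0.0 if ms_eff > 0 else 1.0
        else:
            f = ms_eff / ms_err
            p = float(stats.f.sf(f, 1, df_err))
        effects[name] = AnovaEffect(F=float(f), p=float(p), df1=1, df2=df_err)
    return AnovaResult(effects=effects)


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on matched outcome vectors.

    Identical vectors give (0, 1) — no difference at all.  A constant
    NONZERO difference (zero variance, nonzero mean) leaves t undefined and
    raises :class:`DegenerateTableError`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise InputError("need matched 1-D vectors of length >= 3")
    diff = a - b
    if np.all(diff == diff[0]):
        if diff[0] == 0:
            return 0.0, 1.0
        raise DegenerateTableError(
            "zero variance of differences with nonzero mean: t undefined"
        )
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
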