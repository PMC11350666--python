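"""Per-measurement sexual-dimorphism statistics.

Descriptive statistics, pooled-variance two-sample t-tests, variance and
normality screens, and the modified sexual dimorphism index
SDI = (male mean / female mean - 1) x 100, positive when males are larger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .synthetic_data import PopulationSample


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome: statistic, its name, df and p-value."""

    statistic: float
    name: str  # "t", "F" or "W"
    df: tuple[float, ...]
    p_value: float


def _clean(values) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    return a[~np.isnan(a)]


def coefficient_of_variation(values) -> float:
    """Sample CV: sd (n-1 denominator) over the mean, as a proportion."""
    a = _clean(values)
    if a.size < 2:
        raise InsufficientDataError(
            f"coefficient of variation needs >= 2 values, got {a.size}"
        )
    mean = a.mean()
    if mean == 0:
        raise InsufficientDataError("coefficient of variation undefined at mean 0")
    return float(a.std(ddof=1) / mean)


def sdi(mean_m: float, mean_f: float) -> float:
    """Modified sexual dimorphism index in percent.

    (male mean / female mean - 1) x 100; positive when males are larger.
    """
    if mean_f <= 0:
        raise ValueError(f"female mean must be positive, got {mean_f}")
    return (mean_m / mean_f - 1.0) * 100.0


def two_sample_t(values_m, values_f, pooled: bool = True) -> TestResult:
    """Two-sample t-test, male minus female ordering.

    Pooled-variance by default (df = n_m + n_f - 2); Welch available via
    ``pooled=False``.
    """
    a, b = _clean(values_m), _clean(values_f)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"t-test needs >= 2 values per group, got {a.size} and {b.size}"
        )
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return TestResult(float(res.statistic), "t", (float(res.df),), float(res.pvalue))


def t_from_summary(
    mean_m: float, sd_m: float, n_m: int,
    mean_f: float, sd_f: float, n_f: int,
    pooled: bool = True,
) -> TestResult:
    """Same t-test computed from summary statistics (means, SDs, ns)."""
    if sd_m < 0 or sd_f < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_m < 2 or n_f < 2:
        raise InsufficientDataError(
            f"t-test needs n >= 2 per group, got {n_m} and {n_f}"
        )
    res = stats.ttest_ind_from_stats(
        mean_m, sd_m, n_m, mean_f, sd_f, n_f, equal_var=pooled
    )
    if pooled:
        df = float(n_m + n_f - 2)
    else:
        # Welch-Satterthwaite
        va, vb = sd_m**2 / n_m, sd_f**2 / n_f
        df = (va + vb) ** 2 / (va**2 / (n_m - 1) + vb**2 / (n_f - 1))
    return TestResult(float(res.statistic), "t", (df,), float(res.pvalue))


def brown_forsythe(group_a, group_b) -> TestResult:
    """Brown-Forsythe homogeneity-of-variance test (median-centred Levene)."""
    a, b = _clean(group_a), _clean(group_b)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"Brown-Forsythe needs >= 2 values per group, got {a.size} and {b.size}"
        )
    stat, p = stats.levene(a, b, center="median")
    return TestResult(float(stat), "F", (1.0, float(a.size + b.size - 2)), float(p))


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality test; supported for 3 <= n <= 5000."""
    a = _clean(values)
    if not 3 <= a.size <= 5000:
        raise InsufficientDataError(
            f"Shapiro-Wilk supported for 3 <= n <= 5000, got {a.size}"
        )
    stat, p = stats.shapiro(a)
    return TestResult(float(stat), "W", (float(a.size),), float(p))


def dimorphism_table(
    sample: PopulationSample,
    measurements: list[str] | None = None,
    pooled: bool = True,
) -> pd.DataFrame:
    """Male-vs-female comparison, one row per measurement, ages pooled.

    Columns: measurement, mean_m, cv_m, n_m, mean_f, cv_f, n_f, t, df, p,
    sdi (percent). Uses only non-missing cells; n is the non-missing count
    per sex. Raises if a measurement lacks usable data for either sex.
    """
    measurements = measurements or sample.measurements
    males = sample.sex_subset("M")
    females = sample.sex_subset("F")
    if males.empty or females.empty:
        raise InsufficientDataError("sample must contain both sexes")

    rows = []
    for m in measurements:
        vm, vf = _clean(males[m]), _clean(females[m])
        if vm.size < 2 or vf.size < 2:
            raise InsufficientDataError(
                f"measurement {m!r} has < 2 non-missing values for one sex"
            )
        t = two_sample_t(vm, vf, pooled=pooled)
        rows.append({
            "measurement": m,
            "mean_m": vm.mean(), "cv_m": coefficient_of_variation(vm),
            "n_m": vm.size,
            "mean_f": vf.mean(), "cv_f": coefficient_of_variation(vf),
            "n_f": vf.size,
            "t": t.statistic, "df": t.df[0], "p": t.p_value,
            "sdi": sdi(vm.mean(), vf.mean()),
        })
    return pd.DataFrame(rows)


def age_comparison_table(
    sample: PopulationSample,
    measurements: list[str] | None = None,
    pooled: bool = True,
) -> pd.DataFrame:
    """Adult-vs-juvenile t-tests within each sex (pooling justification).

    Columns: sex, measurement, mean_ad, n_ad, mean_juv, n_juv, t, df, p;
    t is adult minus juvenile. Measurements with < 2 values in either age
    class are skipped rather than fatal.
    """
    measurements = measurements or sample.measurements
    rows = []
    for sex in ("F", "M"):
        sub = sample.sex_subset(sex)
        ad = sub[sub["age"] == "ad"]
        juv = sub[sub["age"] == "juv"]
        for m in measurements:
            va, vj = _clean(ad[m]), _clean(juv[m])
            if va.size < 2 or vj.size < 2:
                continue
            t = two_sample_t(va, vj, pooled=pooled)
            rows.append({
                "sex": sex, "measurement": m,
                "mean_ad": va.mean(), "n_ad": va.size,
                "mean_juv": vj.mean(), "n_juv": vj.size,
                "t": t.statistic, "df": t.df[0], "p": t.p_value,
            })
    return pd.DataFrame(rows)


def format_dimorphism_table(table: pd.DataFrame) -> pd.DataFrame:
    """Report-layer rounding: means to published precision analogues,
    V and SDI as percent with one decimal, t with two decimals."""
    out = table.copy()
    out["mean_m"] = out["mean_m"].round(2)
    out["mean_f"] = out["mean_f"].round(2)
    out["cv_m"] = (100 * out["cv_m"]).round(1)
    out["cv_f"] = (100 * out["cv_f"]).round(1)
    out["t"] = out["t"].round(2)
    out["sdi"] = out["sdi"].round(1)
    return out
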