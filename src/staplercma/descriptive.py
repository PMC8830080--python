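"""Group comparisons and publication-style summary tables.

Test dispatch follows the conventions of the underlying cost study: pooled
Student's t for continuous variables, Pearson chi-square (no continuity
correction) for categorical variables, and the Wilcoxon rank-sum test for
cost variables. Fisher's exact test replaces the chi-square automatically
when any expected cell count falls below 5, where the chi-square
approximation is invalid. Wilcoxon p-values use exact enumeration for small
untied samples and the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import (COMORBIDITIES, HISTOLOGIES, INSURANCES, MARROW_FLAGS,
                     RESIDENCES, SITES, STAGES, BMI_BANDS)


@dataclass(frozen=True)
class GroupComparison:
    """One row of a group-comparison table."""

    variable: str
    summary_a: str
    summary_b: str
    test: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def two_sample_t(x, y, variable: str = "", welch: bool = False) -> GroupComparison:
    """Two-sided two-sample t test (pooled variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t test needs at least 2 observations per sample")
    pooled = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
    if pooled <= 0:
        raise ValueError("degenerate (zero) pooled variance")
    stat, p = stats.ttest_ind(x, y, equal_var=not welch)
    return GroupComparison(
        variable, f"{x.mean():.1f}+/-{x.std(ddof=1):.1f}",
        f"{y.mean():.1f}+/-{y.std(ddof=1):.1f}",
        "welch-t" if welch else "student-t", float(stat), float(p))


def chi_square_2x2(a: int, b: int, c: int, d: int,
                   variable: str = "") -> GroupComparison:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df=1, no
    continuity correction."""
    cells = np.array([[a, b], [c, d]], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    n = cells.sum()
    rows = cells.sum(axis=1)
    cols = cells.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi-square requires nonzero margins")
    stat = n * (a * d - b * c) ** 2 / (rows[0] * rows[1] * cols[0] * cols[1])
    p = float(stats.chi2.sf(stat, df=1))
    n1, n2 = a + b, c + d
    return GroupComparison(variable, f"{100 * a / n1:.1f}%", f"{100 * c / n2:.1f}%",
                           "chi-square", float(stat), p)


def fisher_2x2(a: int, b: int, c: int, d: int,
               variable: str = "") -> GroupComparison:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]]."""
    odds, p = stats.fisher_exact([[a, b], [c, d]])
    n1, n2 = a + b, c + d
    return GroupComparison(variable, f"{100 * a / n1:.1f}%", f"{100 * c / n2:.1f}%",
                           "fisher-exact", float(odds), float(p))


def proportion_test(a: int, n1: int, c: int, n2: int, variable: str = "",
                    fisher_fallback: bool = True) -> GroupComparison:
    """Compare a/n1 vs c/n2; chi-square, falling back to Fisher's exact test
    when any expected cell count is below 5."""
    b, d = n1 - a, n2 - c
    cells = np.array([[a, b], [c, d]], dtype=float)
    n = cells.sum()
    expected = np.outer(cells.sum(axis=1), cells.sum(axis=0)) / n
    if fisher_fallback and (expected < 5).any():
        return fisher_2x2(a, b, c, d, variable)
    return chi_square_2x2(a, b, c, d, variable)


def wilcoxon_rank_sum(x, y, variable: str = "",
                      method: str = "auto") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``method='auto'`` uses exact enumeration when both samples have at most
    25 untied observations, otherwise the tie-corrected normal approximation
    with mid-ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("rank-sum test needs non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if (max(len(x), len(y)) <= 25 and not has_ties) \
            else "asymptotic"
    if method == "exact" and has_ties:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = min(1.0, float(res.pvalue))

    def _summ(v):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return f"{med:.0f} ({q1:.0f}-{q3:.0f})"

    return GroupComparison(variable, _summ(x), _summ(y), f"wilcoxon-{method}",
                           float(res.statistic), p)


_COST_LABELS = {
    "stapler_cost": "Stapler costs",
    "cartridge_cost": "Cartridge costs",
    "disposables_cost": "Disposable supplies costs",
    "drug_cost": "Drug costs",
    "operation_cost": "Operation related costs",
    "laboratory_cost": "Laboratory tests costs",
    "other_cost": "Other hospital costs",
    "total_cost": "Total hospital costs",
}


def summarize_cohort(patients: pd.DataFrame,
                     costs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build a characteristics/costs comparison table between the two groups.

    One row per variable, dispatching pooled t for continuous variables,
    chi-square (Fisher when sparse) for categorical ones, and Wilcoxon
    rank-sum for costs. Returns a DataFrame of :class:`GroupComparison` rows.
    """
    ga = patients[patients["group"] == "powered"]
    gb = patients[patients["group"] == "manual"]
    if ga.empty or gb.empty:
        raise ValueError("summarize_cohort needs both stapler groups present")
    rows: list[GroupComparison] = []

    def binary(label, mask_a, mask_b):
        rows.append(proportion_test(int(mask_a.sum()), len(ga),
                                    int(mask_b.sum()), len(gb), label))

    rows.append(two_sample_t(ga["age"], gb["age"], "Age (years)"))
    binary("Male gender", ga["sex"] == "male", gb["sex"] == "male")
    rows.append(two_sample_t(ga["bmi"], gb["bmi"], "BMI (kg/m2)"))
    for band, _, _ in BMI_BANDS:
        binary(f"BMI {band}", ga["bmi_band"] == band, gb["bmi_band"] == band)
    for block, labels in (("residence", RESIDENCES), ("insurance", INSURANCES)):
        for label in labels:
            binary(f"{block}: {label}", ga[block] == label, gb[block] == label)
    binary("Married", ga["marital"] == "married", gb["marital"] == "married")
    for name in COMORBIDITIES:
        binary(f"Comorbidity: {name}", ga[f"comorb_{name}"] == 1,
               gb[f"comorb_{name}"] == 1)
    for label in HISTOLOGIES:
        binary(f"Histology: {label}", ga["histology"] == label,
               gb["histology"] == label)
    for label in STAGES:
        binary(f"Stage: {label}", ga["stage"] == label, gb["stage"] == label)
    for name in MARROW_FLAGS:
        binary(f"Abnormal {name}", ga[f"marrow_{name}"] == 1,
               gb[f"marrow_{name}"] == 1)
    for label in SITES:
        binary(f"Site: {label}", ga["site"] == label, gb["site"] == label)
    rows.append(two_sample_t(ga["staplers_used"], gb["staplers_used"],
                             "Staplers used"))
    rows.append(two_sample_t(ga["cartridges_used"], gb["cartridges_used"],
                             "Cartridges used"))

    if costs is not None:
        merged = patients[["patient_id", "group"]].merge(costs, on="patient_id")
        ca = merged[merged["group"] == "powered"]
        cb = merged[merged["group"] == "manual"]
        for column, label in _COST_LABELS.items():
            rows.append(wilcoxon_rank_sum(ca[column], cb[column], label))

    return pd.DataFrame([r.__dict__ for r in rows])
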