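"""Group-comparison descriptive statistics (Table-1-style summaries).

Continuous variables are summarised as median (IQR) and compared with
Student's t test (or a rank test on request); categorical variables as
count (percent) and compared with the chi-squared test, falling back to
Fisher's exact test when any expected cell is below 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

VariableKind = Literal["continuous", "categorical"]


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    kind: VariableKind
    group_summaries: Mapping[str, str]
    test: str
    statistic: float
    p_value: float

    def __post_init__(self):
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def proportion(count: int, denominator: int, decimals: int = 0) -> float:
    """Percentage of a count against its group denominator.

    Table cells print integers (``decimals=0``); running text uses one
    decimal (``decimals=1``).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError(f"count {count} outside [0, {denominator}]")
    return float(round(100.0 * count / denominator, decimals))


def _summarize_continuous(values: np.ndarray) -> str:
    q1, med, q3 = np.nanpercentile(values, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _summarize_binary(values: np.ndarray) -> str:
    n = int(np.nansum(values))
    denom = int(np.sum(~np.isnan(values)))
    pct = proportion(n, denom) if denom else float("nan")
    return f"{n} ({pct:.0f})"


def chi2_2x2(table: np.ndarray, continuity: bool = False) -> tuple[float, float]:
    """Chi-squared test on a 2x2 table.

    Without continuity correction this equals the closed form
    N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); with ``continuity=True`` the Yates
    correction is applied.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("chi2_2x2 requires a 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(stat), float(p)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    variable_kind: VariableKind,
    variable: str = "",
    rank_test: bool = False,
    paired: bool = False,
    continuity: bool = False,
    fisher_threshold: float = 5.0,
) -> GroupComparison:
    """Compare one variable between two groups.

    Continuous: Student's t (pooled variance), or the Wilcoxon rank-sum
    (Mann-Whitney) test with ``rank_test=True``; ``paired=True`` additionally
    switches to the signed-rank test for paired samples.  Categorical
    (binary 0/1 vectors): chi-squared on the 2x2 table, or Fisher's exact
    test when any expected cell count falls below ``fisher_threshold``.
    Zero variance in both groups leaves the test undefined (p = NaN).
    """
    if len(values_by_group) != 2:
        raise ValueError("compare_groups requires exactly two groups")
    (name_a, raw_a), (name_b, raw_b) = values_by_group.items()
    a = np.asarray(raw_a, dtype=float)
    b = np.asarray(raw_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one observation")

    if variable_kind == "continuous":
        summaries = {name_a: _summarize_continuous(a), name_b: _summarize_continuous(b)}
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return GroupComparison(variable, variable_kind, summaries,
                                   "undefined", float("nan"), float("nan"))
        if rank_test and paired:
            stat, p = stats.wilcoxon(a, b)
            test = "wilcoxon_signed_rank"
        elif rank_test:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "wilcoxon_rank"
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=True)
            test = "t"
        return GroupComparison(variable, variable_kind, summaries,
                               test, float(stat), float(p))

    if variable_kind == "categorical":
        if not (set(np.unique(a)) <= {0.0, 1.0} and set(np.unique(b)) <= {0.0, 1.0}):
            raise ValueError("categorical comparisons expect binary 0/1 vectors")
        summaries = {name_a: _summarize_binary(a), name_b: _summarize_binary(b)}
        table = np.array([
            [a.sum(), a.size - a.sum()],
            [b.sum(), b.size - b.sum()],
        ])
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            # all-zero or all-one variable: no association testable
            return GroupComparison(variable, variable_kind, summaries,
                                   "undefined", float("nan"), float("nan"))
        expected = stats.contingency.expected_freq(table)
        if (expected < fisher_threshold).any():
            stat, p = stats.fisher_exact(table)
            test = "fisher_exact"
        else:
            stat, p = chi2_2x2(table, continuity=continuity)
            test = "chi_squared"
        return GroupComparison(variable, variable_kind, summaries,
                               test, float(stat), float(p))

    raise ValueError(f"unknown variable_kind {variable_kind!r}")


#: cohort-table rows in print order: (analysis-table column, kind, label)
TABLE1_VARIABLES: tuple[tuple[str, VariableKind, str], ...] = (
    ("age", "continuous", "Age, median (IQR), y"),
    ("sex_male", "categorical", "Male"),
    ("race_white", "categorical", "White"),
    ("race_black", "categorical", "Black"),
    ("race_hispanic", "categorical", "Hispanic"),
    ("race_asian", "categorical", "Asian"),
    ("bmi", "continuous", "BMI, median (IQR)"),
    ("vital_sbp", "continuous", "Systolic blood pressure (mm Hg)"),
    ("vital_dbp", "continuous", "Diastolic blood pressure (mm Hg)"),
    ("vital_map", "continuous", "Mean arterial pressure (mm Hg)"),
    ("vital_hr", "continuous", "Heart rate (beats/min)"),
    ("vital_rr", "continuous", "Respiratory rate (breaths/min)"),
    ("vital_temp", "continuous", "Temperature (F)"),
    ("vital_sao2", "continuous", "SaO2 (%)"),
    ("lab_sodium", "continuous", "Sodium (mEq/L)"),
    ("lab_potassium", "continuous", "Potassium (mEq/L)"),
    ("lab_bun", "continuous", "BUN (mg/dL)"),
    ("lab_scr", "continuous", "SCr (mg/dL)"),
    ("mv_duration_hours", "continuous", "Time on mechanical ventilation (h)"),
    ("los_hours", "continuous", "ICU length of stay (h)"),
    ("apache2", "continuous", "APACHE II"),
    ("saps2", "continuous", "SAPS II"),
    ("mrci_24h", "continuous", "MRCI"),
    ("mrc_icu_24h", "continuous", "MRC-ICU"),
    ("gcs", "continuous", "GCS at admission"),
    ("dx_lactic_acidosis", "categorical", "Lactic acidosis (E87.2)"),
    ("dx_hypokalemia", "categorical", "Hypokalemia (E87.6)"),
    ("dx_kidney_failure", "categorical", "Kidney failure (N17.9)"),
    ("dx_hyponatremia", "categorical", "Hypo-osmolality hyponatremia (E87.1)"),
    ("dx_ami", "categorical", "Acute myocardial infarction (I21.A)"),
    ("dx_sepsis", "categorical", "Unspecified sepsis (A41.9)"),
)


def build_table1(
    analysis_table: pd.DataFrame,
    group_col: str = "mortality",
    variables: Sequence[tuple[str, VariableKind, str]] = TABLE1_VARIABLES,
    rank_test_vars: Sequence[str] = ("mrci_24h", "mrc_icu_24h"),
) -> list[GroupComparison]:
    """One comparison row per configured variable, in print order.

    ``group_col`` must be binary (e.g. mortality for the survivor vs
    non-survivor contrast, or a high-complexity label).  Regimen-complexity
    scores are compared with the rank test; other continuous rows with the
    t test.  Missing variables produce an NA row plus a warning rather than
    aborting the table.
    """
    groups = analysis_table[group_col].astype(bool)
    rows: list[GroupComparison] = []
    label_a = f"{group_col}=0"
    label_b = f"{group_col}=1"
    for column, kind, label in variables:
        if column not in analysis_table.columns:
            warnings.warn(f"table-1 variable {column!r} missing from analysis table")
            rows.append(GroupComparison(label, kind, {label_a: "NA", label_b: "NA"},
                                        "missing", float("nan"), float("nan")))
            continue
        a = analysis_table.loc[~groups, column]
        b = analysis_table.loc[groups, column]
        if a.dropna().empty or b.dropna().empty:
            rows.append(GroupComparison(label, kind, {label_a: "NA", label_b: "NA"},
                                        "skipped", float("nan"), float("nan")))
            continue
        rows.append(compare_groups(
            {label_a: a.to_numpy(float), label_b: b.to_numpy(float)},
            kind,
            variable=label,
            rank_test=column in rank_test_vars,
        ))
    return rows


def table1_frame(rows: Sequence[GroupComparison]) -> pd.DataFrame:
    records = []
    for row in rows:
        rec = {"variable": row.variable, "kind": row.kind, "test": row.test,
               "statistic": row.statistic, "p_value": row.p_value}
        rec.update(row.group_summaries)
        records.append(rec)
    return pd.DataFrame(records)
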