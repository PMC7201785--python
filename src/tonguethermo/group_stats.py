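"""Group-comparison statistics for cohort and feature tables.

The screening study compares normal and diabetic groups variable by
variable: Shapiro-Wilk normality checks, the pooled-variance two-sample
Student's t-test (with Welch's correction behind a flag), the rank-based
Kruskal-Wallis test, and Pearson correlation (per pair and as a full matrix
with significance stars).  Computations are delegated to ``scipy.stats``;
this module supplies the study's conventions (pooled variance by default,
raw p-values with no multiplicity correction, "s"/"ns" significance tags)
and the summary-table exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "CorrelationMatrix",
    "students_t",
    "shapiro_wilk",
    "kruskal_wallis",
    "pearson_r",
    "r_squared",
    "correlation_matrix",
    "group_summary_table",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test: str
    group_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _as_sample(x, min_n: int, name: str = "sample") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations")
    return arr


def students_t(a, b, equal_var: bool = True) -> TestResult:
    """Two-sample t-test, pooled variance by default (Welch via flag)."""
    a = _as_sample(a, 2, "group a")
    b = _as_sample(b, 2, "group b")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    name = "students_t" if equal_var else "welch_t"
    return TestResult(float(t), float(p), name, (a.size, b.size))


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (n >= 3)."""
    x = _as_sample(x, 3)
    w, p = stats.shapiro(x)
    return TestResult(float(w), float(p), "shapiro_wilk", (x.size,))


def kruskal_wallis(*groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k >= 2 groups).

    With two groups this is the rank-sum comparison the study applies
    between normal and diabetic subjects.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    samples = [_as_sample(g, 1, f"group {i}") for i, g in enumerate(groups)]
    h, p = stats.kruskal(*samples)
    return TestResult(float(h), float(p), "kruskal_wallis",
                      tuple(s.size for s in samples))


def pearson_r(x, y) -> TestResult:
    """Pearson product-moment correlation with t-based two-sided p."""
    x = _as_sample(x, 3, "x")
    y = _as_sample(y, 3, "y")
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero variance")
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson_r", (x.size,))


def r_squared(x, y) -> float:
    """Coefficient of determination of the simple linear fit (= Pearson r^2)."""
    return pearson_r(x, y).statistic ** 2


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r with p-values and 0.05/0.01 significance flags."""

    names: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray

    def stars(self) -> np.ndarray:
        flags = np.full(self.r.shape, "", dtype=object)
        flags[self.p < 0.05] = "*"
        flags[self.p < 0.01] = "**"
        np.fill_diagonal(flags, "")
        return flags

    def to_frame(self) -> pd.DataFrame:
        """Lower-triangular display table with significance stars."""
        out = pd.DataFrame("", index=self.names, columns=self.names, dtype=object)
        stars = self.stars()
        for i in range(len(self.names)):
            for j in range(i + 1):
                out.iloc[i, j] = f"{self.r[i, j]:.3f}{stars[i, j]}"
        return out


def correlation_matrix(table: pd.DataFrame, variables: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlations over cohort columns.

    Zero-variance columns produce NaN entries (flagged by NaN p) rather than
    raising.
    """
    if variables is None:
        variables = [c for c in table.columns if table[c].dtype.kind == "f"]
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = table[variables[i]].to_numpy(), table[variables[j]].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
            else:
                rij, pij = stats.pearsonr(x, y)
                r[i, j] = r[j, i] = rij
                p[i, j] = p[j, i] = pij
    return CorrelationMatrix(tuple(variables), r, p)


def group_summary_table(
    table: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("normal", "diabetic"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean +/- SD per group with pooled-t p-values and "s"/"ns" tags."""
    variables = [c for c in table.columns
                 if c != group_col and table[c].dtype.kind == "f"]
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    rows = []
    for var in variables:
        res = students_t(a[var], b[var])
        rows.append({
            "variable": var,
            f"{groups[0]}_mean": a[var].mean(),
            f"{groups[0]}_sd": a[var].std(ddof=1),
            f"{groups[1]}_mean": b[var].mean(),
            f"{groups[1]}_sd": b[var].std(ddof=1),
            "p_value": res.p_value,
            "significance": "s" if res.p_value < alpha else "ns",
        })
    return pd.DataFrame(rows)
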