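"""Group-comparison statistics on published-style accuracy grids.

An accuracy grid is the 7 x 6 table of mean per-class success rates (seven
window conditions by six classes, 42 cells).  Two analyses operate on such
grids:

* an independent pooled-variance two-sample t-test between two grids
  (e.g. young vs senior subjects), treating the 42 cells of each grid as
  the observations;
* a one-way repeated-measures ANOVA across three grids (two-channel,
  corrugator-only, zygomaticus-only) with electrode configuration as the
  within factor and the 42 cells as the repeated-measures units, followed
  by the three Bonferroni-corrected paired comparisons.

The ANOVA F is reported with both the uncorrected degrees of freedom
(2, 82) and the lower-bound sphericity correction (1, 41).  Cells of the
three grids are paired positionally — in each grid's stored (printed) row
order — by default; label-matched pairing is available via
``pairing="condition"``.

The five published grids ship with the package as CSV fixtures and are
checksum-validated on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "GRID_NAMES",
    "PrintedAccuracyGrid",
    "TestResult",
    "RmAnovaResult",
    "load_printed_grid",
    "grid_values",
    "independent_t",
    "independent_t_values",
    "rm_anova",
    "rm_anova_values",
]

GRID_NAMES = (
    "table3_all",
    "table4_young",
    "table4_senior",
    "table5_female",
    "table5_male",
    "table6_corrugator",
    "table7_zygomaticus",
)

CLASSES = ("BASELINE", "0VLA", "PVHA", "NVHA", "PVLA", "NVLA")


@dataclass
class PrintedAccuracyGrid:
    """A 42-cell mean-accuracy grid (7 conditions x 6 classes) with SDs."""

    name: str
    table: pd.DataFrame  # columns: condition, class, mean_pct, sd_pct

    def __post_init__(self) -> None:
        if len(self.table) != 42:
            raise ValueError(f"grid {self.name!r} must have 42 cells")
        vals = self.table["mean_pct"]
        if not ((vals >= 0) & (vals <= 100)).all():
            raise ValueError("accuracies must lie in [0, 100]")


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    test: str
    correction: str = "none"


@dataclass
class RmAnovaResult:
    F: float
    df_uncorrected: tuple[int, int]
    df_lower_bound: tuple[int, int]
    p_uncorrected: float
    p_lower_bound: float
    pairwise: list[TestResult]


def load_printed_grid(name: str) -> PrintedAccuracyGrid:
    """Load one shipped accuracy grid, verifying its checksum."""
    if name not in GRID_NAMES:
        raise ValueError(f"unknown grid {name!r}; expected one of {GRID_NAMES}")
    pkg = resources.files("affectemg") / "data"
    text = (pkg / f"{name}.csv").read_text()
    expected = json.loads((pkg / "checksums.json").read_text())[name]
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != expected:
        raise ValueError(f"fixture {name}.csv is corrupted (checksum mismatch)")
    from io import StringIO

    table = pd.read_csv(StringIO(text))
    return PrintedAccuracyGrid(name=name, table=table)


def grid_values(grid: PrintedAccuracyGrid, pairing: str = "printed") -> np.ndarray:
    """The 42 cell means as a vector, in stored or label-sorted order."""
    if pairing == "printed":
        return grid.table["mean_pct"].to_numpy(dtype=float)
    if pairing == "condition":
        t = grid.table.copy()
        t["class"] = pd.Categorical(t["class"], categories=CLASSES, ordered=True)
        return (
            t.sort_values(["condition", "class"])["mean_pct"].to_numpy(dtype=float)
        )
    raise ValueError("pairing must be 'printed' or 'condition'")


def independent_t_values(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> TestResult:
    """Two-sample t on two cell-value vectors (A minus B), two-tailed."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    res = sstats.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else float(res.df)
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        test="independent t" + ("" if equal_var else " (Welch)"),
    )


def independent_t(
    grid_a: PrintedAccuracyGrid,
    grid_b: PrintedAccuracyGrid,
    equal_var: bool = True,
) -> TestResult:
    """Two-sample t on the 42 cells of each grid (A minus B), two-tailed.

    Pooled-variance (Student) by default; set ``equal_var=False`` for Welch.
    """
    a, b = grid_values(grid_a), grid_values(grid_b)
    if len(a) != len(b):
        raise ValueError("grids have mismatched layouts")
    return independent_t_values(a, b, equal_var=equal_var)


def rm_anova(
    grids: tuple[PrintedAccuracyGrid, PrintedAccuracyGrid, PrintedAccuracyGrid],
    pairing: str = "printed",
) -> RmAnovaResult:
    """One-way repeated-measures ANOVA over three grids plus Bonferroni pairs.

    The 42 cells are the units; the grid (electrode configuration) is the
    3-level within factor.  ``pairing`` controls how cells are matched
    across grids: ``"printed"`` pairs them in stored row order,
    ``"condition"`` matches (condition, class) labels.
    """
    if len(grids) != 3:
        raise ValueError("exactly three grids required")
    X = np.column_stack([grid_values(g, pairing) for g in grids])
    return rm_anova_values(X, names=[g.name for g in grids])


def rm_anova_values(X: np.ndarray, names: list[str] | None = None) -> RmAnovaResult:
    """Repeated-measures ANOVA on an (n units x k levels) cell matrix."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    grand = X.mean()
    ss_subjects = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_factor = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_error = ss_total - ss_subjects - ss_factor
    df_f, df_e = k - 1, (k - 1) * (n - 1)
    F = (ss_factor / df_f) / (ss_error / df_e)
    p_unc = float(sstats.f.sf(F, df_f, df_e))
    p_lb = float(sstats.f.sf(F, 1, n - 1))
    pairwise = []
    if names is None:
        names = [f"level{i}" for i in range(k)]
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            t = sstats.ttest_rel(X[:, i], X[:, j])
            pairwise.append(
                TestResult(
                    statistic=float(t.statistic),
                    df=n - 1,
                    p_value=min(1.0, n_pairs * float(t.pvalue)),
                    test=f"paired t: {names[i]} vs {names[j]}",
                    correction=f"bonferroni({n_pairs})",
                )
            )
    return RmAnovaResult(
        F=float(F),
        df_uncorrected=(df_f, df_e),
        df_lower_bound=(1, n - 1),
        p_uncorrected=p_unc,
        p_lower_bound=p_lb,
        pairwise=pairwise,
    )
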