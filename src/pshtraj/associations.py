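"""Associations between trajectory group membership and hospital outcomes.

Categorical outcomes (PSH diagnosis, survival, command-following) are tested
with the Pearson chi-squared test on the group x outcome contingency table
(no continuity correction).  Continuous outcomes (DLT, discharge GCS, length
of stay, ventilation days) are tested with one-way ANOVA, matching the
original analysis even for skewed variables; a Kruskal-Wallis alternative is
available as an option but is not the default.  Raw p-values are reported
with a 0.05 significance flag and no multiple-testing correction.

Per-group effect summaries for binary outcomes are odds with Wald 95%
confidence intervals on the log-odds scale; continuous outcomes get
per-group means with t-based intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "TestResult",
    "crosstab",
    "chi_square_test",
    "one_way_anova",
    "kruskal_wallis",
    "group_odds",
    "group_mean_ci",
    "outcome_summary",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of outcome levels (columns) within trajectory groups (rows)."""

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Percentage of each outcome level within each group row."""
        row_tot = self.counts.sum(axis=1, keepdims=True)
        return 100.0 * self.counts / row_tot


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[int, ...]
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def crosstab(labels: Sequence, outcome: Sequence) -> ContingencyTable:
    """Group x outcome contingency table (counts sum to N)."""
    lab = pd.Series(labels).reset_index(drop=True)
    out = pd.Series(outcome).reset_index(drop=True)
    if len(lab) != len(out):
        raise ValueError("labels and outcome must have equal length")
    if lab.isna().any() or out.isna().any():
        raise ValueError("labels and outcome must have no missing values")
    tab = pd.crosstab(lab, out)
    return ContingencyTable(
        row_labels=tuple(tab.index),
        col_labels=tuple(tab.columns),
        counts=tab.to_numpy(),
    )


def chi_square_test(table: ContingencyTable) -> TestResult:
    """Pearson chi-squared test of independence, no continuity correction."""
    c = table.counts
    if c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("chi-squared test needs at least a 2x2 table")
    if c.sum() == 0:
        raise ValueError("empty table")
    expected = stats.contingency.expected_freq(c)
    if (expected == 0).any():
        raise ValueError("chi-squared test undefined: an expected count is zero")
    if (expected < 5).any():
        logger.warning("chi-squared test with expected count(s) < 5; asymptotic p may be inaccurate")
    stat, p, dof, _ = stats.chi2_contingency(c, correction=False)
    return TestResult(float(stat), (int(dof),), float(p), "chi_square")


def _groups(values: Sequence[float], labels: Sequence) -> list[np.ndarray]:
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if len(v) != len(lab):
        raise ValueError("values and labels must have equal length")
    return [v[lab == g] for g in np.unique(lab)]


def one_way_anova(values: Sequence[float], labels: Sequence) -> TestResult:
    """One-way ANOVA F-test from between/within sums of squares.

    Degenerate all-constant input (zero between- and within-group variance)
    is defined as F = 0, p = 1 rather than NaN.
    """
    groups = _groups(values, labels)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups each with >= 2 observations")
    n = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = (k - 1, n - k)
    if ssw == 0:
        if ssb == 0:
            return TestResult(0.0, df, 1.0, "anova")
        return TestResult(float("inf"), df, 0.0, "anova")
    f = (ssb / df[0]) / (ssw / df[1])
    return TestResult(float(f), df, float(stats.f.sf(f, *df)), "anova")


def kruskal_wallis(values: Sequence[float], labels: Sequence) -> TestResult:
    """Rank-based alternative to the default ANOVA (config option)."""
    groups = _groups(values, labels)
    stat, p = stats.kruskal(*groups)
    return TestResult(float(stat), (len(groups) - 1,), float(p), "kruskal_wallis")


def group_odds(table: ContingencyTable, positive_level=None) -> pd.DataFrame:
    """Per-group odds of a binary outcome with a Wald 95% CI.

    Odds are ``positives / negatives``; the CI is
    ``exp(log(odds) +/- 1.96 * sqrt(1/pos + 1/neg))``.  A group with a zero
    cell still reports its odds but the CI is flagged undefined (no
    continuity correction is applied).
    """
    if len(table.col_labels) != 2:
        raise ValueError("group_odds requires a binary outcome")
    cols = list(table.col_labels)
    pos_idx = cols.index(positive_level) if positive_level is not None else 1
    neg_idx = 1 - pos_idx
    z = stats.norm.ppf(0.975)
    rows = []
    for g, row in zip(table.row_labels, table.counts):
        pos, neg = int(row[pos_idx]), int(row[neg_idx])
        odds = pos / neg if neg > 0 else np.inf
        if pos > 0 and neg > 0:
            se = np.sqrt(1 / pos + 1 / neg)
            lo, hi = np.exp(np.log(odds) - z * se), np.exp(np.log(odds) + z * se)
            ok = True
        else:
            lo = hi = np.nan
            ok = False
            logger.warning("group %r has a zero cell; odds CI undefined", g)
        rows.append({"group": g, "positives": pos, "negatives": neg,
                     "odds": odds, "ci_low": lo, "ci_high": hi, "ci_defined": ok})
    return pd.DataFrame(rows)


def group_mean_ci(values: Sequence[float], labels: Sequence, level: float = 0.95) -> pd.DataFrame:
    """Per-group mean with a t-based confidence interval.

    Half-width is ``t(n-1, 1-(1-level)/2) * sd / sqrt(n)``; singleton groups
    report an undefined CI.
    """
    rows = []
    lab = np.asarray(labels)
    v = np.asarray(values, dtype=float)
    for g in np.unique(lab):
        x = v[lab == g]
        n = len(x)
        mean = float(x.mean())
        if n >= 2:
            se = x.std(ddof=1) / np.sqrt(n)
            half = float(stats.t.ppf(1 - (1 - level) / 2, n - 1) * se)
            rows.append({"group": g, "n": n, "mean": mean,
                         "ci_low": mean - half, "ci_high": mean + half, "ci_defined": True})
        else:
            logger.warning("group %r has n=1; mean CI undefined", g)
            rows.append({"group": g, "n": n, "mean": mean,
                         "ci_low": np.nan, "ci_high": np.nan, "ci_defined": False})
    return pd.DataFrame(rows)


#: Default variable typing for the outcomes table.
CATEGORICAL_OUTCOMES = ("psh_case", "survived", "following_commands")
CONTINUOUS_OUTCOMES = (
    "dlt", "gcs_eye", "gcs_motor", "gcs_verbal", "gcs_total",
    "hospital_los", "icu_los", "vent_days",
)


def outcome_summary(
    outcomes: pd.DataFrame,
    labels: Sequence,
    alpha: float = 0.05,
    continuous_test: str = "anova",
) -> pd.DataFrame:
    """Per-variable association report between groups and outcomes.

    Categorical variables get a crosstab + chi-squared test; continuous
    variables get per-group means/medians + ANOVA (or Kruskal-Wallis when
    ``continuous_test="kruskal"``).  Returns one row per variable with the
    test statistic, p-value and an ``alpha``-level significance flag.
    Empty or missing outcome columns are skipped with a log entry.
    """
    lab = np.asarray(labels)
    rows = []
    for var in CATEGORICAL_OUTCOMES + CONTINUOUS_OUTCOMES:
        if var not in outcomes.columns or outcomes[var].dropna().empty:
            logger.info("outcome %r absent or empty; skipped", var)
            continue
        col = outcomes[var]
        if var in CATEGORICAL_OUTCOMES:
            tab = crosstab(lab, col)
            if len(tab.col_labels) < 2:
                logger.info("outcome %r has a single level; skipped", var)
                continue
            res = chi_square_test(tab)
            summary = {
                f"group_{g}": f"{cnt[1] if len(cnt) > 1 else cnt[0]}/{cnt.sum()}"
                for g, cnt in zip(tab.row_labels, tab.counts)
            }
        else:
            if continuous_test == "kruskal":
                res = kruskal_wallis(col.to_numpy(), lab)
            else:
                res = one_way_anova(col.to_numpy(), lab)
            summary = {
                f"group_{g}": f"{col.to_numpy()[lab == g].mean():.2f}"
                for g in np.unique(lab)
            }
        rows.append(
            {
                "variable": var,
                "test": res.test_name,
                "statistic": res.statistic,
                "df": "/".join(str(d) for d in res.df),
                "p_value": res.p_value,
                "significant": res.p_value < alpha,
                **summary,
            }
        )
    return pd.DataFrame(rows)
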