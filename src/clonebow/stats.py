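"""Group comparisons and counting statistics.

Mirrors the reporting conventions of quantitative developmental-biology
figure legends: two-group comparisons use a Shapiro normality gate to pick
Welch's unequal-variance t-test or the two-sided Mann–Whitney test;
multi-group designs use one-way ANOVA with Dunnett comparisons against a
reference; marker counting reports percent-positive cells within an ROI.
A summary-statistic Welch mode (means / s.d. / n in, p out) allows checks
against printed legend values.  All tests are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    median: float


@dataclass
class ComparisonResult:
    test: str  # welch | mann_whitney | anova_dunnett
    statistic: float
    p_value: float
    groups: list[GroupSummary]
    notes: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row: dict = {"test": self.test, "statistic": self.statistic,
                     "p_value": self.p_value}
        for g in self.groups:
            row[f"{g.label}_n"] = g.n
            row[f"{g.label}_mean"] = g.mean
            row[f"{g.label}_sd"] = g.sd
            row[f"{g.label}_median"] = g.median
        if self.notes:
            row["notes"] = "; ".join(self.notes)
        return row


def _summary(label: str, values: np.ndarray) -> GroupSummary:
    return GroupSummary(
        label=label, n=len(values), mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        median=float(np.median(values)),
    )


def compare_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    normality_alpha: float = 0.05,
) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Shapiro–Wilk on each group at ``normality_alpha``; both consistent
    with normality -> Welch's t-test, otherwise Mann–Whitney (exact for
    small samples without ties, as scipy decides).  Groups smaller than 3
    skip the gate and use Mann–Whitney, with a note.  Constant-valued
    groups cannot support Welch and fall back to Mann–Whitney.
    """
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if len(av) < 1 or len(bv) < 1:
        raise ValueError("each group needs at least one value")
    notes: list[str] = []
    use_welch = False
    if len(av) >= 3 and len(bv) >= 3:
        pa = sps.shapiro(av).pvalue if np.ptp(av) > 0 else 0.0
        pb = sps.shapiro(bv).pvalue if np.ptp(bv) > 0 else 0.0
        use_welch = pa > normality_alpha and pb > normality_alpha
    else:
        notes.append("group below n=3: normality gate skipped, Mann-Whitney used")
    if use_welch and (np.ptp(av) == 0 and np.ptp(bv) == 0):
        use_welch = False
        notes.append("constant-valued groups: fell back to Mann-Whitney")
    if use_welch:
        res = sps.ttest_ind(av, bv, equal_var=False)
        test, stat, p = "welch", float(res.statistic), float(res.pvalue)
        if not np.isfinite(p):
            notes.append("Welch undefined on these data: fell back to Mann-Whitney")
            use_welch = False
    if not use_welch:
        res = sps.mannwhitneyu(av, bv, alternative="two-sided")
        test, stat, p = "mann_whitney", float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        test=test, statistic=stat, p_value=p,
        groups=[_summary(labels[0], av), _summary(labels[1], bv)], notes=notes,
    )


def welch_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch's two-sided t-test from group summary statistics.

    Lets printed legend values (mean ± s.d., n) be checked without raw
    data.  Returns (t statistic, p value).
    """
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(res.statistic), float(res.pvalue)


def compare_multi_groups(
    groups: dict[str, Sequence[float]],
    reference: str,
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """One-way ANOVA followed by Dunnett comparisons to a reference group.

    Returns the omnibus ANOVA result and one result per non-reference
    group with the family-wise adjusted Dunnett p-value.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use compare_two_groups for two")
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not among groups")
    arrays = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    anova = sps.f_oneway(*arrays.values())
    omnibus = ComparisonResult(
        test="anova", statistic=float(anova.statistic),
        p_value=float(anova.pvalue),
        groups=[_summary(k, v) for k, v in arrays.items()],
    )
    others = [k for k in arrays if k != reference]
    dunnett = sps.dunnett(*[arrays[k] for k in others], control=arrays[reference])
    per_group = []
    for i, k in enumerate(others):
        per_group.append(
            ComparisonResult(
                test="anova_dunnett",
                statistic=float(dunnett.statistic[i]),
                p_value=float(dunnett.pvalue[i]),
                groups=[_summary(reference, arrays[reference]),
                        _summary(k, arrays[k])],
            )
        )
    return omnibus, per_group


def percent_positive(
    cells: pd.DataFrame,
    positive_flag: str,
    roi: Optional[Callable[[pd.DataFrame], pd.Series]] = None,
) -> dict[str, float]:
    """Percent marker-positive cells within an ROI.

    ``roi`` is a predicate over the table (defaults to everything); the
    flag column must be boolean-like.  Counts are reported with the
    fraction.
    """
    if positive_flag not in cells.columns:
        raise ValueError(f"missing flag column {positive_flag!r}")
    sub = cells[roi(cells)] if roi is not None else cells
    if len(sub) == 0:
        raise ValueError("empty ROI")
    positives = int(sub[positive_flag].astype(bool).sum())
    total = int(len(sub))
    return {"positives": positives, "total": total,
            "percent": 100.0 * positives / total}


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two partitions of the same items.

    Closed-form from the pair-counting contingency table; 1 for identical
    partitions, ~0 for independent ones.
    """
    a = pd.Categorical(list(labels_a)).codes
    b = pd.Categorical(list(labels_b)).codes
    if len(a) != len(b):
        raise ValueError("partitions label different numbers of items")
    n = len(a)
    if n == 0:
        raise ValueError("empty partitions")
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return x * (x - 1) / 2.0

    sum_cells = comb2(table).sum()
    sum_rows = comb2(table.sum(axis=1)).sum()
    sum_cols = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def comparison_report(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into a figure-legend-style table."""
    return pd.DataFrame([r.to_row() for r in results])
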