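"""Experiment statistics: R x C Pearson chi-square with pairwise post hoc
comparisons, goodness-of-fit segregation check, rate summaries, and
delta-Ct relative expression with a one-way ANOVA."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateTableError(ValueError):
    """A contingency table with an all-zero row or column marginal."""


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        r, c = self.counts.shape
        if not self.row_labels:
            self.row_labels = tuple(f"row{i + 1}" for i in range(r))
        if not self.col_labels:
            self.col_labels = tuple(f"col{j + 1}" for j in range(c))
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lengths do not match table shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square without continuity correction.

    chi2 = sum (O - E)^2 / E with E from the product of the marginals;
    df = (R-1)(C-1).
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p))


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    df: int
    p: float
    p_bonferroni: float


def posthoc_pairwise(table: ContingencyTable) -> list[PairwiseResult]:
    """All row pairs as uncorrected 2x2 (or 2xC) Pearson chi-squares.

    Raw p values are reported alongside Bonferroni-adjusted ones; the
    published values correspond to the raw column.
    """
    r = table.shape[0]
    if r < 3:
        raise ValueError("post hoc comparisons need at least 3 rows")
    n_pairs = r * (r - 1) // 2
    out = []
    for i, j in combinations(range(r), 2):
        sub = ContingencyTable(
            table.counts[[i, j], :],
            row_labels=(table.row_labels[i], table.row_labels[j]),
            col_labels=table.col_labels,
        )
        res = pearson_chi_square(sub)
        out.append(
            PairwiseResult(
                pair=(table.row_labels[i], table.row_labels[j]),
                statistic=res.statistic,
                df=res.df,
                p=res.p,
                p_bonferroni=min(1.0, res.p * n_pairs),
            )
        )
    return out


@dataclass(frozen=True)
class SegregationResult:
    statistic: float
    p: float
    consistent: bool


def segregation_test(
    n_class1: int,
    n_class2: int,
    ratio: tuple[float, float] = (1, 1),
    alpha: float = 0.05,
) -> SegregationResult:
    """1-df goodness-of-fit chi-square of two counts against a stated ratio."""
    if n_class1 < 0 or n_class2 < 0 or n_class1 + n_class2 == 0:
        raise ValueError("counts must be non-negative and not both zero")
    total = n_class1 + n_class2
    w = ratio[0] + ratio[1]
    expected = [total * ratio[0] / w, total * ratio[1] / w]
    stat, p = stats.chisquare([n_class1, n_class2], f_exp=expected)
    return SegregationResult(statistic=float(stat), p=float(p), consistent=bool(p > alpha))


def rate_summary(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (as printed in summaries)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    p: float


def relative_expression(
    matrix: pd.DataFrame,
    group_col: str = "group",
    target_col: str = "ct_target",
    reference_cols: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, AnovaResult]:
    """Per-sample 2^-dCt normalized expression plus a one-way ANOVA.

    dCt = target Ct minus the arithmetic mean of the reference-gene Cts
    (equivalent to a geometric mean on the linear scale). Requires at
    least two groups and one reference column.
    """
    if reference_cols is None:
        reference_cols = [c for c in matrix.columns if c.startswith("ct_ref")]
    if not reference_cols:
        raise ValueError("no reference-gene columns")
    for col in (group_col, target_col, *reference_cols):
        if col not in matrix.columns:
            raise ValueError(f"column {col!r} missing from matrix")
    if (matrix[[target_col, *reference_cols]] <= 0).any().any():
        raise ValueError("quantification cycles must be positive")

    out = matrix.copy()
    ref_mean = out[list(reference_cols)].mean(axis=1)
    out["delta_ct"] = out[target_col] - ref_mean
    out["rel_expr"] = 2.0 ** (-out["delta_ct"])

    groups = [g["rel_expr"].to_numpy() for _, g in out.groupby(group_col, sort=False)]
    if len(groups) < 2:
        raise ValueError("need at least two groups for ANOVA")
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.f_oneway(*groups)
    if np.isnan(stat):  # zero within-group variance with equal means
        stat, p = 0.0, 1.0
    return out, AnovaResult(statistic=float(stat), p=float(p))
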