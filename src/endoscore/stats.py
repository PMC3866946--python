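"""Two-group comparison battery: Pearson chi-square, Student's t,
Mann-Whitney, and a formatted per-variable comparison report."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .afs import ValidationError
from .roc import TwoByTwoTable

__all__ = [
    "VariableSpec",
    "pearson_chi_square",
    "students_t",
    "students_t_from_stats",
    "mann_whitney",
    "build_report",
]

logger = logging.getLogger(__name__)


def pearson_chi_square(table: TwoByTwoTable) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 table, df = 1.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); no Yates continuity
    correction (matching SPSS's "Pearson Chi-Square" row).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValidationError("chi-square requires all margins positive")
    n = table.n
    stat = n * (a * d - b * c) ** 2 / (
        margins[0] * margins[1] * margins[2] * margins[3]
    )
    return float(stat), float(_st.chi2.sf(stat, df=1))


def students_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample t-test, pooled variance by default (Welch via flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("t-test requires n >= 2 in each group")
    if equal_var and a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValidationError("zero pooled variance: t undefined")
    t, p = _st.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def students_t_from_stats(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Pooled t from summary statistics (mean, SD, n per group)."""
    t, p = _st.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var
    )
    return float(t), float(p)


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "normal",
) -> tuple[float, float]:
    """Mann-Whitney rank-sum test.

    Returns ``(z, p)``.  ``z`` is the tie-corrected normal approximation
    without continuity correction, negative when ``group_a`` is
    stochastically smaller (fixed group ordering).  With
    ``method="exact"`` the p-value comes from exact enumeration while
    ``z`` is still the normal-approximation statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValidationError("Mann-Whitney requires n >= 1 in each group")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _st.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    if method == "normal":
        p = float(min(2.0 * _st.norm.sf(abs(z)), 1.0))
    elif method == "exact":
        p = float(
            _st.mannwhitneyu(
                a, b, alternative="two-sided", method="exact"
            ).pvalue
        )
    else:
        raise ValidationError(f"unknown method {method!r}")
    return float(z), p


@dataclass(frozen=True)
class VariableSpec:
    """How one cohort variable is summarized and tested.

    ``kind``: "normal" -> mean +/- SD with pooled t; "nonnormal" ->
    median (IQR) with Mann-Whitney z; "rate" -> summed numerator over
    summed denominator with Pearson chi-square (``denominator=None``
    counts patients).  Routing is declared, not inferred from the data.
    """

    name: str
    kind: str
    column: Optional[str] = None
    numerator: Optional[str] = None
    denominator: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "nonnormal", "rate"):
            raise ValidationError(f"unknown variable kind {self.kind!r}")
        if self.kind == "rate":
            if self.numerator is None:
                raise ValidationError("rate variable needs a numerator")
        elif self.column is None:
            raise ValidationError(
                f"continuous variable {self.name!r} needs a column"
            )


def _mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f}({q1:.1f}-{q3:.1f})"


def _rate(num: float, den: float) -> str:
    # percentages are always recomputed from counts, never trusted input
    pct = 100.0 * num / den if den else float("nan")
    return f"{int(num)}/{int(den)}({pct:.1f})"


def build_report(
    df: pd.DataFrame,
    group_col: str,
    variables: Sequence[VariableSpec],
    group_order: Optional[Sequence] = None,
) -> pd.DataFrame:
    """One comparison row per variable between two groups.

    Columns: variable, total, one summary column per group, test,
    statistic, p.  Missing variables are skipped with a logged warning.
    """
    if group_col not in df.columns:
        raise ValidationError(f"grouping column {group_col!r} missing")
    groups = (
        list(group_order)
        if group_order is not None
        else sorted(df[group_col].dropna().unique().tolist())
    )
    if len(groups) != 2:
        raise ValidationError(
            f"grouping must be binary, found {len(groups)} levels"
        )
    ga = df[df[group_col] == groups[0]]
    gb = df[df[group_col] == groups[1]]
    if ga.empty or gb.empty:
        raise ValidationError("both groups must be non-empty")

    rows = []
    for spec in variables:
        needed = [
            c
            for c in (spec.column, spec.numerator, spec.denominator)
            if c is not None
        ]
        if any(c not in df.columns for c in needed):
            logger.warning(
                "variable %s skipped: missing column(s) %s",
                spec.name,
                [c for c in needed if c not in df.columns],
            )
            continue
        label = spec.label or spec.name
        if spec.kind == "rate":
            num_a = float(ga[spec.numerator].sum())
            num_b = float(gb[spec.numerator].sum())
            den_a = (
                float(ga[spec.denominator].sum())
                if spec.denominator
                else float(len(ga))
            )
            den_b = (
                float(gb[spec.denominator].sum())
                if spec.denominator
                else float(len(gb))
            )
            table = TwoByTwoTable(
                a=int(num_a),
                b=int(den_a - num_a),
                c=int(num_b),
                d=int(den_b - num_b),
            )
            stat, p = pearson_chi_square(table)
            rows.append(
                {
                    "variable": label,
                    "total": _rate(num_a + num_b, den_a + den_b),
                    f"group_{groups[0]}": _rate(num_a, den_a),
                    f"group_{groups[1]}": _rate(num_b, den_b),
                    "test": "chi2",
                    "statistic": stat,
                    "p": p,
                }
            )
        else:
            xa = ga[spec.column].dropna().to_numpy(dtype=float)
            xb = gb[spec.column].dropna().to_numpy(dtype=float)
            xt = np.concatenate([xa, xb])
            if spec.kind == "normal":
                stat, p = students_t(xa, xb)
                summ = _mean_sd
                test = "t"
            else:
                stat, p = mann_whitney(xa, xb)
                summ = _median_iqr
                test = "mann-whitney z"
            rows.append(
                {
                    "variable": label,
                    "total": summ(xt),
                    f"group_{groups[0]}": summ(xa),
                    f"group_{groups[1]}": summ(xb),
                    "test": test,
                    "statistic": stat,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
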