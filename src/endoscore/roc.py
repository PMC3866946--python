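"""Empirical ROC analysis for integer prognostic indices.

AUC is computed by the Mann-Whitney identity (concordant pairs plus half
ties), its standard error by the Hanley-McNeil formula (with a
stratified-bootstrap alternative), and the operating cut-off by
maximizing the Youden index J = sensitivity + specificity - 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _st

from .afs import ValidationError

__all__ = [
    "TwoByTwoTable",
    "ROCAnalysis",
    "sens_spec_from_table",
    "empirical_roc",
    "auc_trapezoid",
    "auc_mann_whitney",
    "auc_se_hanley_mcneil",
    "auc_se_bootstrap",
    "auc_ci_and_test",
    "youden_optimal",
    "analyze",
]

HIGHER = "higher_is_positive"
LOWER = "lower_is_positive"

_Z975 = float(_st.norm.ppf(0.975))


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts of index-positive/negative crossed with outcome.

    a = index-positive & outcome-positive, b = index-positive &
    outcome-negative, c = index-negative & outcome-positive,
    d = index-negative & outcome-negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(
                    f"cell {name} must be a non-negative integer, got {v}"
                )

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def sens_spec_from_table(table: TwoByTwoTable) -> tuple[float, float]:
    """(sensitivity, specificity) = (a/(a+c), d/(b+d))."""
    if table.a + table.c == 0:
        raise ValidationError("no outcome-positive subjects: sens undefined")
    if table.b + table.d == 0:
        raise ValidationError("no outcome-negative subjects: spec undefined")
    return table.a / (table.a + table.c), table.d / (table.b + table.d)


def _oriented(
    values: Sequence[float], outcomes: Sequence[bool], direction: str
) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("values and outcomes must be equal-length 1-d")
    if direction == LOWER:
        x = -x
    elif direction != HIGHER:
        raise ValidationError(f"unknown direction {direction!r}")
    if y.all() or not y.any():
        raise ValidationError("need at least one positive and one negative")
    return x, y


def empirical_roc(
    values: Sequence[float],
    outcomes: Sequence[bool],
    direction: str = HIGHER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Operating points of the rule "positive iff index >= t".

    Returns ``(thresholds, sens, spec)`` with one finite threshold per
    distinct observed value (ascending, on the direction-adjusted
    scale); the trivial endpoints (all positive / none positive) are
    implicit in the curve area computation.
    """
    x, y = _oriented(values, outcomes, direction)
    thresholds = np.unique(x)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        positive = x >= t
        sens[i] = (positive & y).sum() / n_pos
        spec[i] = (~positive & ~y).sum() / n_neg
    return thresholds, sens, spec


def auc_trapezoid(sens: np.ndarray, spec: np.ndarray) -> float:
    """Trapezoidal area under the (1-spec, sens) curve incl. endpoints."""
    fpr = np.concatenate(([0.0], 1.0 - np.asarray(spec)[::-1], [1.0]))
    tpr = np.concatenate(([0.0], np.asarray(sens)[::-1], [1.0]))
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def auc_mann_whitney(
    values: Sequence[float],
    outcomes: Sequence[bool],
    direction: str = HIGHER,
) -> float:
    """AUC = (concordant pairs + half ties) / (n_pos * n_neg)."""
    x, y = _oriented(values, outcomes, direction)
    n_pos = int(y.sum())
    n_neg = x.size - n_pos
    ranks = _st.rankdata(x)
    return float(
        (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def auc_se_hanley_mcneil(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC.

    Uses Q1 = A/(2-A) and Q2 = 2A^2/(1+A); ``n_pos`` is the number of
    outcome-positive subjects, ``n_neg`` outcome-negative.
    """
    if not 0.0 < auc < 1.0:
        raise ValidationError(f"AUC must be in (0, 1), got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("need at least one subject in each class")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return math.sqrt(var)


def auc_se_bootstrap(
    values: Sequence[float],
    outcomes: Sequence[bool],
    direction: str = HIGHER,
    reps: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Stratified-bootstrap SE of the Mann-Whitney AUC.

    Resamples positives and negatives separately so every resample keeps
    both classes.
    """
    if reps < 2:
        raise ValidationError("bootstrap needs at least 2 replicates")
    x, y = _oriented(values, outcomes, direction)
    rng = np.random.default_rng() if rng is None else rng
    pos = x[y]
    neg = x[~y]
    n_pos, n_neg = pos.size, neg.size
    aucs = np.empty(reps)
    for i in range(reps):
        p = pos[rng.integers(0, n_pos, n_pos)]
        q = neg[rng.integers(0, n_neg, n_neg)]
        ranks = _st.rankdata(np.concatenate([p, q]))
        aucs[i] = (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (
            n_pos * n_neg
        )
    return float(aucs.std(ddof=1))


def auc_ci_and_test(
    auc: float, se: float
) -> tuple[tuple[float, float], float]:
    """Wald 95% CI (clipped to [0, 1]) and two-sided normal p vs 0.5."""
    if not se > 0:
        raise ValidationError(f"SE must be positive, got {se}")
    lo = max(0.0, auc - _Z975 * se)
    hi = min(1.0, auc + _Z975 * se)
    z = (auc - 0.5) / se
    p = float(2.0 * _st.norm.sf(abs(z)))
    return (lo, hi), min(p, 1.0)


def youden_optimal(
    thresholds: np.ndarray, sens: np.ndarray, spec: np.ndarray
) -> tuple[float, float, float, float]:
    """(cutoff, sens, spec, J) maximizing J = sens + spec - 1.

    The cutoff is the smallest index value classified positive.  Ties
    are broken toward higher sensitivity, then toward the lower cutoff.
    """
    best = None
    for t, sn, sp in zip(thresholds, sens, spec):
        j = sn + sp - 1.0
        key = (round(j, 12), round(sn, 12), -t)
        if best is None or key > best[0]:
            best = (key, (float(t), float(sn), float(sp), float(j)))
    assert best is not None
    return best[1]


@dataclass
class ROCAnalysis:
    """Full ROC report for one index against one binary outcome."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    se: float
    ci95: tuple[float, float]
    p_vs_half: float
    youden_cutoff: float
    youden_sens: float
    youden_spec: float
    youden_j: float
    n_pos: int
    n_neg: int
    direction: str = HIGHER
    se_method: str = "hanley"

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "se": self.se,
            "ci95": list(self.ci95),
            "p_vs_half": self.p_vs_half,
            "youden_cutoff": self.youden_cutoff,
            "sensitivity": self.youden_sens,
            "specificity": self.youden_spec,
            "youden_j": self.youden_j,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "direction": self.direction,
            "se_method": self.se_method,
            "thresholds": [float(t) for t in self.thresholds],
            "sens": [float(s) for s in self.sens],
            "spec": [float(s) for s in self.spec],
        }


def analyze(
    values: Sequence[float],
    outcomes: Sequence[bool],
    direction: str = HIGHER,
    se_method: str = "hanley",
    bootstrap_reps: int = 2000,
    seed: Optional[int] = None,
) -> ROCAnalysis:
    """Run the full ROC pipeline on one index.

    A degenerate AUC of exactly 0 or 1 yields ``se = nan`` (the
    Hanley-McNeil variance collapses there) with CI and p undefined.
    """
    x, y = _oriented(values, outcomes, direction)
    thresholds, sens, spec = empirical_roc(x, y, HIGHER)
    auc = auc_mann_whitney(x, y, HIGHER)
    n_pos = int(y.sum())
    n_neg = int(x.size - n_pos)
    if 0.0 < auc < 1.0:
        if se_method == "hanley":
            se = auc_se_hanley_mcneil(auc, n_pos, n_neg)
        elif se_method == "bootstrap":
            se = auc_se_bootstrap(
                x, y, HIGHER, reps=bootstrap_reps,
                rng=np.random.default_rng(seed),
            )
        else:
            raise ValidationError(f"unknown se_method {se_method!r}")
        ci, p = auc_ci_and_test(auc, se)
    else:
        se, ci, p = float("nan"), (auc, auc), float("nan")
    cutoff, ysn, ysp, j = youden_optimal(thresholds, sens, spec)
    if direction == LOWER:
        # report thresholds and cutoff back on the original scale
        thresholds, sens, spec = -thresholds[::-1], sens[::-1], spec[::-1]
        cutoff = -cutoff
    return ROCAnalysis(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        se=se,
        ci95=ci,
        p_vs_half=p,
        youden_cutoff=cutoff,
        youden_sens=ysn,
        youden_spec=ysp,
        youden_j=j,
        n_pos=n_pos,
        n_neg=n_neg,
        direction=direction,
        se_method=se_method,
    )
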