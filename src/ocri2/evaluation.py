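"""Classifier evaluation metrics and follow-up contingency statistics.

Cancer (label ``c``) is the positive class throughout.  Metrics whose
denominator is zero are reported as ``None`` ("undefined"), never coerced
to 0.  AUC uses the rank (Mann–Whitney) formulation:
``AUC = P(score_c > score_n) + ½·P(tie)``.

The follow-up comparison is the 2×2 table of risk group (high/low) by
outcome (transformed / not transformed), tested with the two-sided
chi-square with Yates continuity correction in its safeguarded form
``Σ (max(|O−E|−0.5, 0))²/E``.  The three-category traditional-method
comparison uses the plain Pearson chi-square (df = 2): the continuity
correction is defined only for one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, Ocri2Error

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "FollowUpTable",
    "confusion_and_metrics",
    "auc_rank",
    "yates_chi_square",
    "fisher_exact",
    "multi_group_chi_square",
    "proportion_summary",
]


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 tally with cancer as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return _ratio(self.tn, self.tn + self.fn)


@dataclass
class EvaluationReport:
    """Confusion matrix, derived metrics, and (optionally) AUC."""

    confusion: ConfusionMatrix
    auc: float | None = None

    @property
    def sensitivity(self) -> float | None:
        return self.confusion.sensitivity

    @property
    def specificity(self) -> float | None:
        return self.confusion.specificity

    @property
    def ppv(self) -> float | None:
        return self.confusion.ppv

    @property
    def npv(self) -> float | None:
        return self.confusion.npv

    def to_dict(self) -> dict:
        c = self.confusion
        return {
            "confusion": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
        }


def _check_labels(labels: Sequence[str], name: str) -> None:
    bad = sorted({l for l in labels if l not in ("c", "n")})
    if bad:
        raise Ocri2Error(f"{name} labels must be 'c' or 'n'; got {bad}")


def confusion_and_metrics(truth: Sequence[str], predicted: Sequence[str]) -> EvaluationReport:
    """Tally a confusion matrix from true and predicted ``c``/``n`` labels."""
    truth = list(truth)
    predicted = list(predicted)
    if not truth:
        raise Ocri2Error("label sequences must be non-empty")
    if len(truth) != len(predicted):
        raise Ocri2Error(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted labels"
        )
    _check_labels(truth, "truth")
    _check_labels(predicted, "predicted")
    tp = sum(1 for t, p in zip(truth, predicted) if t == "c" and p == "c")
    fn = sum(1 for t, p in zip(truth, predicted) if t == "c" and p == "n")
    fp = sum(1 for t, p in zip(truth, predicted) if t == "n" and p == "c")
    tn = sum(1 for t, p in zip(truth, predicted) if t == "n" and p == "n")
    return EvaluationReport(ConfusionMatrix(tp, fp, tn, fn))


def auc_rank(scores: Sequence[float], truth: Sequence[str]) -> float:
    """Rank-based (Mann–Whitney) AUC of scores against ``c``/``n`` truth.

    Equals the probability that a random cancer case outscores a random
    normal case, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    truth = list(truth)
    if scores.size != len(truth):
        raise Ocri2Error("scores and truth must have equal length")
    _check_labels(truth, "truth")
    is_c = np.array([t == "c" for t in truth])
    n_c = int(is_c.sum())
    n_n = int((~is_c).sum())
    if n_c == 0 or n_n == 0:
        raise Ocri2Error("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks implement the half-tie rule
    return float((ranks[is_c].sum() - n_c * (n_c + 1) / 2) / (n_c * n_n))


@dataclass(frozen=True)
class FollowUpTable:
    """Risk group (rows: high, low) by outcome (cols: transformed, not)."""

    high_transformed: int
    high_not: int
    low_transformed: int
    low_not: int

    def __post_init__(self) -> None:
        if min(self.high_transformed, self.high_not, self.low_transformed, self.low_not) < 0:
            raise ValueError("counts must be non-negative")
        if self.high_total == 0 and self.low_total == 0:
            raise ValueError("at least one row total must be positive")

    @property
    def high_total(self) -> int:
        return self.high_transformed + self.high_not

    @property
    def low_total(self) -> int:
        return self.low_transformed + self.low_not

    def to_array(self) -> np.ndarray:
        return np.array(
            [[self.high_transformed, self.high_not], [self.low_transformed, self.low_not]],
            dtype=int,
        )


def _check_marginals(table: np.ndarray) -> None:
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError(
            "chi-square test undefined: table has a zero row or column marginal"
        )


def yates_chi_square(table: FollowUpTable | np.ndarray) -> tuple[float, float]:
    """Two-sided chi-square with Yates continuity correction on a 2×2 table.

    The correction subtracts ``min(0.5, |O−E|)`` from each deviation, so a
    perfectly independent table yields statistic 0 and p = 1.  Returns
    ``(statistic, p_value)`` with p from the df = 1 upper tail.
    """
    arr = table.to_array() if isinstance(table, FollowUpTable) else np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2×2 table, got shape {arr.shape}")
    _check_marginals(arr)
    res = stats.chi2_contingency(arr, correction=True)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table: FollowUpTable | np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact test — the small-sample alternative, behind its own call."""
    arr = table.to_array() if isinstance(table, FollowUpTable) else np.asarray(table, dtype=int)
    res = stats.fisher_exact(arr, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def multi_group_chi_square(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2×3 outcome table.

    Used for the three-category traditional-method comparison; df = 2.
    Columns with zero marginal contribute nothing and are dropped before
    testing (with df reduced accordingly).
    """
    arr = np.asarray(table, dtype=int)
    if arr.ndim != 2 or arr.shape[0] != 2:
        raise ValueError(f"expected a 2×k table, got shape {arr.shape}")
    keep = arr.sum(axis=0) > 0
    arr = arr[:, keep]
    if arr.shape[1] < 2:
        raise DegenerateTableError("fewer than two non-empty categories")
    _check_marginals(arr)
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)


def proportion_summary(table: FollowUpTable) -> dict[str, dict[str, float | int | None]]:
    """Per-risk-group transformation rates, as raw fractions and 1-dp percentages."""
    out: dict[str, dict[str, float | int | None]] = {}
    for name, transformed, total in (
        ("high", table.high_transformed, table.high_total),
        ("low", table.low_transformed, table.low_total),
    ):
        if total == 0:
            out[name] = {"transformed": transformed, "total": total,
                         "fraction": None, "percent": None}
        else:
            frac = transformed / total
            out[name] = {"transformed": transformed, "total": total,
                         "fraction": frac, "percent": round(100 * frac, 1)}
    return out
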