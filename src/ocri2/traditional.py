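"""The rule-based "traditional" cytology call.

An aneuploid cell is one whose DNA index is at or above 2.3 (the British
Columbia Cancer Agency criterion).  A case is then called:

* ``negative`` — no aneuploid cell,
* ``atypical`` — 1 to 5 aneuploid cells (inclusive),
* ``positive`` — more than 5 aneuploid cells.

The three rules are exhaustive and disjoint over all non-negative counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .errors import InsufficientDataError
from .io import CaseRecord

__all__ = [
    "ANEUPLOID_DI_THRESHOLD",
    "TraditionalCategory",
    "TraditionalResult",
    "count_aneuploid",
    "classify_traditional",
    "score_case",
]

#: DI at or above this value marks a cell as aneuploid.
ANEUPLOID_DI_THRESHOLD = 2.3


class TraditionalCategory(str, enum.Enum):
    NEGATIVE = "negative"
    ATYPICAL = "atypical"
    POSITIVE = "positive"


@dataclass(frozen=True)
class TraditionalResult:
    """Aneuploid-cell count and the category it implies."""

    aneuploid_count: int
    category: TraditionalCategory
    threshold: float = ANEUPLOID_DI_THRESHOLD


def count_aneuploid(di_values: Sequence[float], threshold: float = ANEUPLOID_DI_THRESHOLD) -> int:
    """Number of DI values at or above ``threshold`` (inclusive)."""
    values = list(di_values)
    if not values:
        raise InsufficientDataError("cannot count aneuploid cells of an empty DI list")
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    return sum(1 for v in values if v >= threshold)


def classify_traditional(aneuploid_count: int) -> TraditionalCategory:
    """Map an aneuploid-cell count to negative / atypical / positive."""
    if aneuploid_count < 0:
        raise ValueError(f"aneuploid count must be >= 0, got {aneuploid_count}")
    if aneuploid_count == 0:
        return TraditionalCategory.NEGATIVE
    if aneuploid_count <= 5:
        return TraditionalCategory.ATYPICAL
    return TraditionalCategory.POSITIVE


def score_case(case: CaseRecord, threshold: float = ANEUPLOID_DI_THRESHOLD) -> TraditionalResult:
    """Apply the traditional method to one case."""
    n = count_aneuploid(case.di_values, threshold)
    return TraditionalResult(n, classify_traditional(n), threshold)
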