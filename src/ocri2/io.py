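"""Data model and file I/O for DNA-index cytology cases and peak-feature tables.

A *case* is one subject's brush-biopsy sample: a list of per-cell DNA index
(DI) values — the ratio of a nucleus's integrated DNA optical density to the
diploid reference (≈1 diploid, ≈2 tetraploid/G2) — plus a clinical group
label and optional follow-up information.

Case files are long-format CSV (``case_id,group,di``; one cell per row):
variable cell counts per case make a wide layout ambiguous.  Feature tables
are the 12-column reconstruction used for classification: ten per-interval
peak counts ``V1..V10``, a single-character class label, and the case id.

Lines starting with ``#`` are ignored in every CSV the package reads; the
pipeline writes a provenance comment there.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError

__all__ = [
    "Group",
    "CaseRecord",
    "FeatureRow",
    "FeatureTable",
    "GROUP_TO_LABEL",
    "LABEL_TO_GROUP",
    "read_cases",
    "write_cases",
    "attach_followup",
    "read_feature_table",
    "write_feature_table",
]


class Group(str, enum.Enum):
    """Clinical group of a subject."""

    NORMAL = "normal"
    OLK = "olk"          # oral leukoplakia — the precancerous population
    OSCC = "oscc"        # oral squamous cell carcinoma
    UNKNOWN = "unknown"  # unlabeled sample awaiting a risk score


#: Map from clinical group to the single-character class label used in
#: feature tables (c = cancer/OSCC, k = leukoplakia, n = normal).
GROUP_TO_LABEL = {Group.OSCC: "c", Group.OLK: "k", Group.NORMAL: "n"}
LABEL_TO_GROUP = {v: k for k, v in GROUP_TO_LABEL.items()}

VALID_LABELS = frozenset("ckn")


@dataclass
class CaseRecord:
    """One subject's DI values plus group label and optional follow-up.

    Parameters
    ----------
    case_id : str
        Unique subject/sample identifier.
    group : Group
        Clinical group (``normal``, ``olk``, ``oscc`` or ``unknown``).
    di_values : list of float
        Per-cell DNA index values; all finite and > 0.
    followup_months : float, optional
        Observation time after sampling, in months.
    transformed : bool, optional
        Whether malignant transformation was confirmed during follow-up.
        May only be set together with ``followup_months``.
    """

    case_id: str
    group: Group
    di_values: list[float] = field(default_factory=list)
    followup_months: float | None = None
    transformed: bool | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        for v in self.di_values:
            if not (math.isfinite(v) and v > 0):
                raise IntegrityError(
                    f"case {self.case_id!r}: DI value {v!r} is not a finite positive number"
                )
        if self.followup_months is not None and self.followup_months < 0:
            raise IntegrityError(f"case {self.case_id!r}: negative followup_months")
        if self.transformed is not None and self.followup_months is None:
            raise IntegrityError(
                f"case {self.case_id!r}: transformed set without followup_months"
            )

    @property
    def n_cells(self) -> int:
        return len(self.di_values)


@dataclass
class FeatureRow:
    """One case's reconstructed features: 10 interval peak counts + label + id."""

    counts: list[int]
    label: str
    case_id: str

    def __post_init__(self) -> None:
        self.counts = [int(c) for c in self.counts]
        if len(self.counts) != 10:
            raise IntegrityError(
                f"case {self.case_id!r}: expected 10 interval counts, got {len(self.counts)}"
            )
        if any(c < 0 for c in self.counts):
            raise IntegrityError(f"case {self.case_id!r}: negative interval count")
        if self.label not in VALID_LABELS:
            raise IntegrityError(
                f"case {self.case_id!r}: label {self.label!r} not one of c/k/n"
            )


@dataclass
class FeatureTable:
    """Ordered collection of :class:`FeatureRow` with unique case ids."""

    rows: list[FeatureRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.case_id in seen:
                raise IntegrityError(f"duplicate case_id {row.case_id!r} in feature table")
            seen.add(row.case_id)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rows]

    @property
    def case_ids(self) -> list[str]:
        return [r.case_id for r in self.rows]

    def counts_matrix(self):
        """Return the n×10 count matrix as a numpy int array."""
        import numpy as np

        return np.array([r.counts for r in self.rows], dtype=int).reshape(len(self.rows), 10)

    def subset_labels(self, labels: Iterable[str]) -> "FeatureTable":
        """Rows whose label is in ``labels``, input order preserved."""
        keep = set(labels)
        return FeatureTable([r for r in self.rows if r.label in keep])

    def to_frame(self) -> pd.DataFrame:
        cols = {f"V{i + 1}": [r.counts[i] for r in self.rows] for i in range(10)}
        cols["label"] = self.labels
        cols["case_id"] = self.case_ids
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        expected = [f"V{i}" for i in range(1, 11)] + ["label", "case_id"]
        if list(frame.columns) != expected:
            raise FormatError(
                f"feature table must have columns {expected}, got {list(frame.columns)}"
            )
        rows = []
        for rec in frame.itertuples(index=False):
            rows.append(
                FeatureRow(
                    counts=[int(getattr(rec, f"V{i}")) for i in range(1, 11)],
                    label=str(rec.label),
                    case_id=str(rec.case_id),
                )
            )
        return cls(rows)


# ---------------------------------------------------------------------------
# case CSV


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return frame


def read_cases(path: str | Path) -> list[CaseRecord]:
    """Read a long-format case CSV into :class:`CaseRecord` objects.

    DI values are aggregated per ``case_id`` in file order; the group label
    is parsed case-insensitively.  Raises :class:`FormatError` for dialect
    problems (with the offending line number) and :class:`IntegrityError`
    for conflicting group labels within one case.
    """
    path = Path(path)
    frame = _read_csv(path, ["case_id", "group", "di"])

    order: list[str] = []
    groups: dict[str, Group] = {}
    values: dict[str, list[float]] = {}
    # +2: header line is 1, first data line is 2 (comment lines shift this,
    # so recover the true line number from the raw file when reporting)
    for idx, rec in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2
        case_id = str(rec.case_id)
        raw_group = str(rec.group).strip().lower()
        try:
            group = Group(raw_group)
        except ValueError:
            allowed = ", ".join(g.value for g in Group)
            raise FormatError(
                f"{path}:{line_no}: unknown group {rec.group!r}; allowed: {allowed}"
            ) from None
        try:
            di = float(rec.di)
        except (TypeError, ValueError):
            raise FormatError(f"{path}:{line_no}: non-numeric DI value {rec.di!r}") from None
        if not (math.isfinite(di) and di > 0):
            raise FormatError(f"{path}:{line_no}: DI value {di!r} must be finite and > 0")
        if case_id not in groups:
            order.append(case_id)
            groups[case_id] = group
            values[case_id] = []
        elif groups[case_id] is not group:
            raise IntegrityError(
                f"{path}:{line_no}: case {case_id!r} has conflicting group labels "
                f"({groups[case_id].value!r} vs {group.value!r})"
            )
        values[case_id].append(di)

    return [CaseRecord(cid, groups[cid], values[cid]) for cid in order]


def write_cases(cases: Iterable[CaseRecord], path: str | Path, *, header_comment: str | None = None) -> None:
    """Write cases as a long-format ``case_id,group,di`` CSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("case_id,group,di\n")
        for case in cases:
            for v in case.di_values:
                fh.write(f"{case.case_id},{case.group.value},{float(v)!r}\n")


def attach_followup(cases: Sequence[CaseRecord], path: str | Path) -> list[CaseRecord]:
    """Merge a follow-up CSV (``case_id,followup_months,transformed``) into cases.

    Returns new records; cases without a follow-up row are passed through
    unchanged.  ``transformed`` must be 0 or 1.
    """
    path = Path(path)
    frame = _read_csv(path, ["case_id", "followup_months", "transformed"])
    info: dict[str, tuple[float, bool]] = {}
    for idx, rec in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2
        cid = str(rec.case_id)
        try:
            months = float(rec.followup_months)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}:{line_no}: non-numeric followup_months {rec.followup_months!r}"
            ) from None
        if str(rec.transformed) not in {"0", "1"}:
            raise FormatError(
                f"{path}:{line_no}: transformed must be 0 or 1, got {rec.transformed!r}"
            )
        if cid in info:
            raise IntegrityError(f"{path}:{line_no}: duplicate follow-up for case {cid!r}")
        info[cid] = (months, str(rec.transformed) == "1")

    out = []
    for case in cases:
        if case.case_id in info:
            months, trans = info[case.case_id]
            out.append(
                CaseRecord(case.case_id, case.group, list(case.di_values), months, trans)
            )
        else:
            out.append(case)
    return out


# ---------------------------------------------------------------------------
# feature-table CSV

FEATURE_COLUMNS = [f"V{i}" for i in range(1, 11)] + ["label", "case_id"]


def write_feature_table(table: FeatureTable, path: str | Path, *, header_comment: str | None = None) -> None:
    """Write a feature table as the 12-column ``V1..V10,label,case_id`` CSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(",".join(FEATURE_COLUMNS) + "\n")
        for row in table.rows:
            fh.write(",".join(str(c) for c in row.counts) + f",{row.label},{row.case_id}\n")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a 12-column feature-table CSV, checking all table invariants."""
    path = Path(path)
    frame = _read_csv(path, FEATURE_COLUMNS)
    if list(frame.columns) != FEATURE_COLUMNS:
        raise FormatError(
            f"{path}: expected exactly columns {FEATURE_COLUMNS}, got {list(frame.columns)}"
        )
    rows = []
    for idx, rec in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2
        counts = []
        for i in range(1, 11):
            raw = getattr(rec, f"V{i}")
            try:
                c = int(raw)
            except (TypeError, ValueError):
                raise FormatError(f"{path}:{line_no}: non-integer count {raw!r}") from None
            if c < 0:
                raise IntegrityError(f"{path}:{line_no}: negative count {c}")
            counts.append(c)
        label = str(rec.label)
        if label not in VALID_LABELS:
            raise IntegrityError(f"{path}:{line_no}: label {label!r} not one of c/k/n")
        rows.append(FeatureRow(counts, label, str(rec.case_id)))
    return FeatureTable(rows)
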