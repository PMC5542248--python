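"""Peak-based reconstruction of DNA-index distributions.

The central data transformation of the pipeline: a case's per-cell DI values
are turned into a 10-dimensional feature vector in three steps.

1. **Density estimation** — a Gaussian kernel density estimate of the DI
   sample, evaluated on an equally spaced grid.  The bandwidth defaults to
   Silverman's reference rule in its ``nrd0`` form,
   ``h = 0.9 · min(sd, IQR/1.34) · n^(−1/5)``, the conventional default for
   one-dimensional density plots.
2. **Peak detection** — the lagged differences of the density mimic its
   first derivative; grid points where the density stops rising and starts
   falling (a positive-to-non-positive sign change) are recorded as peaks.
   A flat plateau preceded by a rise and followed by a fall contributes
   exactly one peak, at the first point of the plateau.
3. **Interval binning** — peak locations are tallied into ten ploidy
   intervals centred on the integers 1..10: ``[0.5,1.5), [1.5,2.5), …``;
   locations below 0.5 fall in the first interval and locations at or above
   9.5 in the last.  A diploid population peaks in interval 1, tetraploid
   in interval 2, and aneuploid populations scatter peaks across higher
   intervals.

The per-case result is a :class:`~ocri2.io.FeatureRow`; a cohort becomes an
n×12 :class:`~ocri2.io.FeatureTable` (10 counts + class label + case id).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .errors import DegenerateSampleError, InsufficientDataError, TransformError
from .io import GROUP_TO_LABEL, CaseRecord, FeatureRow, FeatureTable

__all__ = [
    "DensityConfig",
    "DensityCurve",
    "PeakSet",
    "IntervalCounts",
    "nrd0_bandwidth",
    "estimate_density",
    "detect_peaks",
    "bin_peaks",
    "transform_case",
    "reconstruct_dataset",
]


@dataclass(frozen=True)
class DensityConfig:
    """Settings for the kernel density estimate.

    Parameters
    ----------
    bandwidth : float, optional
        Fixed kernel bandwidth in DI units.  ``None`` (default) selects the
        ``nrd0`` rule-of-thumb bandwidth from the data.
    grid_points : int
        Number of equally spaced evaluation points (default 512).
    tail_extension : float
        How far past the data range the grid extends, in bandwidth units
        (default 3; smaller values clip kernel tails and may leave the
        density visibly unnormalised).
    """

    bandwidth: float | None = None
    grid_points: int = 512
    tail_extension: float = 3.0

    def __post_init__(self) -> None:
        if self.bandwidth is not None and not self.bandwidth > 0:
            raise ValueError("fixed bandwidth must be > 0")
        if self.grid_points < 8:
            raise ValueError("grid_points must be >= 8")
        if self.tail_extension < 0:
            raise ValueError("tail_extension must be >= 0")


@dataclass(frozen=True)
class DensityCurve:
    """A density estimate on a grid: ``grid_x`` strictly increasing, ``density_y >= 0``."""

    grid_x: np.ndarray
    density_y: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_x", np.asarray(self.grid_x, dtype=float))
        object.__setattr__(self, "density_y", np.asarray(self.density_y, dtype=float))
        if self.grid_x.shape != self.density_y.shape or self.grid_x.ndim != 1:
            raise ValueError("grid_x and density_y must be 1-D arrays of equal length")
        if np.any(np.diff(self.grid_x) <= 0):
            raise ValueError("grid_x must be strictly increasing")
        if np.any(self.density_y < 0):
            raise ValueError("density_y must be non-negative")

    def integral(self) -> float:
        """Trapezoid integral of the density over the grid (≈1 for a KDE)."""
        return float(np.trapezoid(self.density_y, self.grid_x))


@dataclass(frozen=True)
class PeakSet:
    """Ascending DI locations of the density's local maxima."""

    locations: np.ndarray

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=float)
        object.__setattr__(self, "locations", loc)
        if loc.ndim != 1:
            raise ValueError("locations must be 1-D")
        if loc.size > 1 and np.any(np.diff(loc) < 0):
            raise ValueError("locations must be ascending")

    def __len__(self) -> int:
        return int(self.locations.size)


@dataclass(frozen=True)
class IntervalCounts:
    """Peaks tallied into the ten ploidy intervals."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "counts", counts)
        if len(counts) != 10 or any(c < 0 for c in counts):
            raise ValueError("counts must be 10 non-negative integers")

    def total(self) -> int:
        return sum(self.counts)


def nrd0_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, ``0.9·min(sd, IQR/1.34)·n^(−1/5)``.

    Falls back to the standard deviation when the IQR is zero; raises
    :class:`DegenerateSampleError` when the sample has no spread at all.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise DegenerateSampleError(
            "sample has zero spread; pass a fixed bandwidth instead of the nrd0 rule"
        )
    q75, q25 = np.percentile(values, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread <= 0.0:
        spread = sd
    return 0.9 * spread * n ** (-1 / 5)


def estimate_density(
    di_values: Sequence[float], config: DensityConfig | None = None
) -> DensityCurve:
    """Gaussian KDE of a DI sample on an equally spaced grid.

    The grid spans ``[min − t·h, max + t·h]`` where ``h`` is the bandwidth
    and ``t`` the tail extension, so the trapezoid integral is ≈1 with the
    default ``t = 3``.
    """
    config = config or DensityConfig()
    values = np.asarray(list(di_values), dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"density estimation needs >= 2 DI values, got {values.size}"
        )
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("DI values must be finite and > 0")

    h = config.bandwidth if config.bandwidth is not None else nrd0_bandwidth(values)
    lo = values.min() - config.tail_extension * h
    hi = values.max() + config.tail_extension * h
    grid = np.linspace(lo, hi, config.grid_points)
    # mean of per-observation Gaussian kernels; 512×n is small enough to broadcast
    y = norm.pdf(grid[:, None], loc=values[None, :], scale=h).mean(axis=1)
    return DensityCurve(grid, y, h)


def detect_peaks(curve: DensityCurve) -> PeakSet:
    """Local maxima of the density via sign changes of lagged differences.

    A peak is a grid point where the curve was rising and starts falling.
    Plateau runs (consecutive zero differences) that sit between a rise and
    a fall yield one peak at the run's first point.  The first and last grid
    points are never peaks.
    """
    y = curve.density_y
    x = curve.grid_x
    d = np.diff(y)
    peaks: list[float] = []
    rising = False
    plateau_start: int | None = None
    for i, step in enumerate(d):
        if step > 0:
            rising = True
            plateau_start = None
        elif step < 0:
            if rising:
                peaks.append(float(x[plateau_start if plateau_start is not None else i]))
            rising = False
            plateau_start = None
        else:  # flat
            if rising and plateau_start is None:
                plateau_start = i
    return PeakSet(np.asarray(peaks))


def bin_peaks(peaks: PeakSet) -> IntervalCounts:
    """Tally peak locations into the ten ploidy intervals.

    Interval ``k`` (1-based) covers ``[k−0.5, k+0.5)``; locations below 0.5
    join interval 1 and locations at or above 9.5 join interval 10, so every
    real location maps to exactly one interval.
    """
    counts = np.zeros(10, dtype=int)
    if len(peaks):
        idx = np.clip(np.floor(peaks.locations + 0.5).astype(int), 1, 10) - 1
        np.add.at(counts, idx, 1)
    return IntervalCounts(tuple(counts))


def transform_case(case: CaseRecord, config: DensityConfig | None = None) -> FeatureRow:
    """Full per-case transformation: density → peaks → interval counts.

    The class label is the single-character factor used downstream
    (oscc→``c``, olk→``k``, normal→``n``).  Unknown-group cases carry the
    non-training sentinel ``k`` so they can be risk-scored but are never
    eligible for classifier fitting (which uses ``c``/``n`` rows only).
    """
    try:
        curve = estimate_density(case.di_values, config)
    except (InsufficientDataError, DegenerateSampleError) as exc:
        raise type(exc)(f"case {case.case_id!r}: {exc}") from exc
    counts = bin_peaks(detect_peaks(curve))
    label = GROUP_TO_LABEL.get(case.group, "k")
    return FeatureRow(list(counts.counts), label, case.case_id)


def reconstruct_dataset(
    cases: Iterable[CaseRecord], config: DensityConfig | None = None
) -> FeatureTable:
    """Transform a cohort into its n×12 feature table, input order preserved.

    Any case that fails to transform aborts the whole reconstruction; the
    raised :class:`TransformError` lists every failing case id so problems
    can be fixed in one pass.
    """
    rows: list[FeatureRow] = []
    failures: list[tuple[str, str]] = []
    for case in cases:
        try:
            rows.append(transform_case(case, config))
        except (InsufficientDataError, DegenerateSampleError) as exc:
            failures.append((case.case_id, str(exc)))
    if failures:
        detail = "; ".join(f"{cid}: {msg}" for cid, msg in failures)
        raise TransformError(
            f"{len(failures)} case(s) could not be transformed: {detail}",
            case_ids=[cid for cid, _ in failures],
        )
    return FeatureTable(rows)
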