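"""Synthetic DI-value cohorts with the distributional structure the pipeline assumes.

Each group profile is a Gaussian mixture over DNA-index values:

* **normal** — a dominant diploid component near DI 1 plus a small
  tetraploid/G2 component near DI 2; density peaks land only in the first
  two ploidy intervals.
* **oscc** — retains the diploid/tetraploid backbone but adds heavy
  aneuploid components whose locations are drawn per case uniformly over
  DI 2.5–8, so peaks scatter across the higher intervals and no two
  tumours look alike.
* **olk_low / olk_high** — leukoplakia profiles: normal-like with a small
  chance of a light aneuploid component, and oscc-like with aneuploid
  components present in a fraction of cases, respectively.

Aneuploid components are included per *case* (clonal lesions), not per
cell: a case either carries its aneuploid clone(s) or it does not, with
probability ``aneuploid_prevalence``.  Cell counts are drawn uniformly
from 50–300, a typical brush-biopsy yield.  All parameters are exposed so
power experiments can move them; DI values are resampled until positive
(with the default means and spreads this essentially never triggers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .io import CaseRecord, Group

__all__ = [
    "GroupProfile",
    "CohortSpec",
    "default_profiles",
    "simulate_case",
    "simulate_cohort",
]


@dataclass(frozen=True)
class GroupProfile:
    """Mixture profile for one clinical group.

    Parameters
    ----------
    name : str
        ``normal``, ``olk_low``, ``olk_high`` or ``oscc`` (the two olk
        profiles both yield group label ``olk``).
    components : tuple of (mean, sd, weight)
        Fixed mixture components; weights must be positive and sum to 1.
    aneuploid_prevalence : float
        Probability a case carries aneuploid component(s).
    aneuploid_weight : float
        Total mixture weight taken by the aneuploid components when
        present (the fixed components are rescaled by ``1 − weight``).
    aneuploid_components_range : (int, int)
        Number of aneuploid components per affected case, drawn uniformly.
    aneuploid_location_range : (float, float)
        DI range the aneuploid component means are drawn from.
    aneuploid_sd : float
        Spread of each aneuploid component.
    cells_range : (int, int)
        Per-case cell count, drawn uniformly (inclusive).
    """

    name: str
    components: tuple[tuple[float, float, float], ...]
    aneuploid_prevalence: float = 0.0
    aneuploid_weight: float = 0.0
    aneuploid_components_range: tuple[int, int] = (2, 4)
    aneuploid_location_range: tuple[float, float] = (2.5, 8.0)
    aneuploid_sd: float = 0.25
    cells_range: tuple[int, int] = (50, 300)

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigurationError("profile needs at least one mixture component")
        weights = [w for _, _, w in self.components]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigurationError("component weights must be >= 0 and sum to 1")
        if any(m <= 0 or s <= 0 for m, s, _ in self.components):
            raise ConfigurationError("component means and sds must be > 0")
        if not 0 <= self.aneuploid_prevalence <= 1:
            raise ConfigurationError("aneuploid_prevalence must be in [0, 1]")
        if not 0 <= self.aneuploid_weight < 1:
            raise ConfigurationError("aneuploid_weight must be in [0, 1)")
        if self.aneuploid_prevalence > 0 and self.aneuploid_weight == 0:
            raise ConfigurationError(
                "aneuploid_prevalence > 0 requires a positive aneuploid_weight"
            )
        lo, hi = self.cells_range
        if not (0 < lo <= hi):
            raise ConfigurationError("cells_range must satisfy 0 < min <= max")
        klo, khi = self.aneuploid_components_range
        if not (1 <= klo <= khi):
            raise ConfigurationError("aneuploid_components_range must satisfy 1 <= min <= max")

    @property
    def group(self) -> Group:
        return Group.OLK if self.name.startswith("olk") else Group(self.name)


def default_profiles() -> dict[str, GroupProfile]:
    """The study-condition profiles used throughout the tests and examples."""
    normal = GroupProfile(
        name="normal",
        components=((1.0, 0.05, 0.93), (2.0, 0.10, 0.07)),
        aneuploid_prevalence=0.0,
        aneuploid_weight=0.0,
    )
    oscc = GroupProfile(
        name="oscc",
        components=((1.0, 0.05, 0.85), (2.0, 0.10, 0.15)),
        aneuploid_prevalence=1.0,
        aneuploid_weight=0.45,
    )
    return {
        "normal": normal,
        "oscc": oscc,
        "olk_low": replace(
            normal, name="olk_low", aneuploid_prevalence=0.1, aneuploid_weight=0.2,
            aneuploid_components_range=(1, 2),
        ),
        "olk_high": replace(oscc, name="olk_high", aneuploid_prevalence=0.6),
    }


@dataclass(frozen=True)
class CohortSpec:
    """A list of (profile, case count) pairs plus the cohort seed."""

    groups: tuple[tuple[GroupProfile, int], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for _, n in self.groups):
            raise ConfigurationError("case counts must be >= 0")


def _realized_components(
    profile: GroupProfile, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    comps = list(profile.components)
    if profile.aneuploid_prevalence > 0 and rng.random() < profile.aneuploid_prevalence:
        klo, khi = profile.aneuploid_components_range
        k = int(rng.integers(klo, khi + 1))
        locs = rng.uniform(*profile.aneuploid_location_range, size=k)
        base_scale = 1.0 - profile.aneuploid_weight
        comps = [(m, s, w * base_scale) for m, s, w in comps]
        comps += [(float(m), profile.aneuploid_sd, profile.aneuploid_weight / k) for m in locs]
    return comps


def simulate_case(
    profile: GroupProfile, rng: np.random.Generator, case_id: str | None = None
) -> CaseRecord:
    """Draw one case from a profile using the supplied generator state."""
    n_cells = int(rng.integers(profile.cells_range[0], profile.cells_range[1] + 1))
    comps = _realized_components(profile, rng)
    means = np.array([m for m, _, _ in comps])
    sds = np.array([s for _, s, _ in comps])
    weights = np.array([w for _, _, w in comps])
    which = rng.choice(len(comps), size=n_cells, p=weights / weights.sum())
    values = rng.normal(means[which], sds[which])
    while np.any(values <= 0):  # truncate to positive DI by resampling
        bad = values <= 0
        values[bad] = rng.normal(means[which[bad]], sds[which[bad]])
    return CaseRecord(
        case_id or f"{profile.name}-1",
        profile.group,
        values.tolist(),
    )


def simulate_cohort(spec: CohortSpec) -> list[CaseRecord]:
    """Simulate a full cohort; deterministic given the spec's seed.

    Case ids are systematic (``<profile>-<index>``); both olk profiles are
    labelled ``olk``.
    """
    rng = np.random.default_rng(spec.seed)
    cases: list[CaseRecord] = []
    for profile, count in spec.groups:
        for i in range(1, count + 1):
            cases.append(simulate_case(profile, rng, case_id=f"{profile.name}-{i:03d}"))
    return cases
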