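import numpy as np
import pytest

from ocri2 import (
    CohortSpec,
    FeatureRow,
    FeatureTable,
    default_profiles,
    reconstruct_dataset,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def bimodal_sample():
    """300 DI values: 90% diploid (1.0, sd 0.05), 10% tetraploid (2.0, sd 0.1)."""
    rng = np.random.default_rng(0)
    return np.concatenate([rng.normal(1.0, 0.05, 270), rng.normal(2.0, 0.1, 30)])


def planted_table(n_per_class: int, seed: int, rng=None) -> FeatureTable:
    """Feature table with planted class structure: normals peak in intervals
    1-2 only, cancers add peaks in intervals >= 3.  Built directly (no KDE)
    so classifier tests are fast and the signal is known exactly."""
    rng = rng or np.random.default_rng(seed)
    rows = []
    for i in range(n_per_class):
        counts = [0] * 10
        counts[0] = 1
        counts[1] = int(rng.integers(1, 4))
        rows.append(FeatureRow(counts, "n", f"n{seed}-{i}"))
    for i in range(n_per_class):
        counts = [0] * 10
        counts[0] = 1
        for j in rng.choice(np.arange(2, 10), size=int(rng.integers(2, 5)), replace=False):
            counts[j] = int(rng.integers(1, 3))
        rows.append(FeatureRow(counts, "c", f"c{seed}-{i}"))
    return FeatureTable(rows)


@pytest.fixture(scope="session")
def separable_table():
    return planted_table(20, seed=11)


@pytest.fixture(scope="session")
def synthetic_cohort_features(profiles):
    """Small simulated cohort run through the full KDE transformation."""
    spec = CohortSpec(((profiles["normal"], 8), (profiles["oscc"], 8)), seed=5)
    return reconstruct_dataset(simulate_cohort(spec))
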