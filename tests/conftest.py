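import numpy as np
import pytest

from adrisk.cohort import GenotypeMatrix, SampleRecord, VariantRecord


def make_matrix(dose_by_marker: dict[str, list], sample_ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {marker_id: dose list} (None = missing)."""
    markers = list(dose_by_marker)
    n = len(next(iter(dose_by_marker.values())))
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    cols = []
    for m in markers:
        col = [np.nan if d is None else float(d) for d in dose_by_marker[m]]
        cols.append(col)
    dose = np.array(cols, dtype=float).T
    variants = [VariantRecord(m, "", "a", "b") for m in markers]
    return GenotypeMatrix(sample_ids, variants, dose)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_cohort(rng):
    """60-sample, 5-marker cohort with one strong planted marker."""
    n = 60
    status = np.array([0] * 30 + [1] * 30, dtype=float)
    dose = {}
    for k in range(4):
        dose[f"null{k}"] = rng.integers(0, 3, size=n).tolist()
    planted = rng.integers(0, 2, size=n) + (status * rng.integers(0, 2, size=n))
    dose["planted"] = np.clip(planted, 0, 2).tolist()
    g = make_matrix(dose)
    samples = [
        SampleRecord(f"s{i}", "AmnAD" if status[i] else "control", 75, "female")
        for i in range(n)
    ]
    return g, samples, status.astype(bool)
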