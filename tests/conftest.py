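import numpy as np
import pytest

from mfc_spectra import MFCSeries, generate_cohort
from mfc_spectra.synthetic import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 6+6 synthetic cohort used across test modules."""
    return generate_cohort(
        CohortConfig(n_per_class={"improved": 6, "unimproved": 6}, seed=42)
    )


@pytest.fixture(scope="session")
def calibrated_cohort():
    """A 50/50 cohort at the published group statistics (seeded)."""
    return generate_cohort(
        CohortConfig(n_per_class={"improved": 50, "unimproved": 50}, seed=1)
    )


def make_series(values, subject_id="s", label=None, normalized=False):
    return MFCSeries(subject_id, np.asarray(values, float), label=label,
                     normalized=normalized)


@pytest.fixture
def cohort_csv(tmp_path):
    """Write a tidy cohort CSV and return its path factory."""

    def _write(rows, name="cohort.csv", header="subject_id,stride_index,mfc_value,label"):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write
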