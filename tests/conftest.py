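import numpy as np
import pytest

from stromabalance import GeneratorParams, SampleRecord, generate_cohort


def make_records(stromas_cancer, stromas_normal, prefix=("C", "N")):
    """Records with given stroma fractions; remainder split between the other tissues."""
    records = []
    for i, s in enumerate(stromas_cancer):
        rest = 1.0 - s
        records.append(
            SampleRecord(f"{prefix[0]}{i + 1:03d}", "cancer", rest * 0.7, s, rest * 0.3)
        )
    for i, s in enumerate(stromas_normal):
        records.append(
            SampleRecord(f"{prefix[1]}{i + 1:03d}", "normal", 0.0, s, 1.0 - s)
        )
    return records


@pytest.fixture(scope="session")
def cohort_9534():
    """Synthetic 95-cancer / 34-normal composition table."""
    rng = np.random.default_rng(42)
    return make_records(rng.uniform(0.05, 0.6, size=95), rng.uniform(0.2, 0.9, size=34))


@pytest.fixture(scope="session")
def synth():
    """A small default-parameter cohort plus its truth table (shared, read-only)."""
    params = GeneratorParams(n_genes=800, seed=123)
    return generate_cohort(params)
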