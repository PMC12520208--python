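import numpy as np
import pytest

from heatlmtp import CohortConfig, LearnerLibrary, generate_cohort
from heatlmtp.benchmarks import DiscreteInstance


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-child cohort for unit-level checks (not for inference)."""
    return generate_cohort(CohortConfig(n_children=400, seed=7))


@pytest.fixture(scope="session")
def fast_library():
    return LearnerLibrary.fast()


@pytest.fixture(scope="session")
def discrete_instance():
    return DiscreteInstance()


def brute_force_spike_counts(values, threshold, min_run, direction="above"):
    """Independent run-enumeration oracle: walk each 70-day block and count
    maximal qualifying runs of length >= min_run.  Deliberately naive."""
    counts = []
    for p in range(12):
        block = values[p * 70 : (p + 1) * 70]
        n_spikes = 0
        run = 0
        for v in block:
            hot = v > threshold if direction == "above" else v < threshold
            if hot:
                run += 1
            else:
                if run >= min_run:
                    n_spikes += 1
                run = 0
        if run >= min_run:
            n_spikes += 1
        counts.append(n_spikes)
    return np.array(counts)
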