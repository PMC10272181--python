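import numpy as np
import pytest

import brainstates as bs

#: The worked dwell-time example sequence from the methods definition.
EXAMPLE_SEQ = [1, 1, 1, 2, 2, 1, 1, 2, 2, 2, 1]


@pytest.fixture
def example_seq():
    return np.array(EXAMPLE_SEQ)


@pytest.fixture(scope="session")
def small_study():
    """A down-scaled synthetic study shared across tests: 6 subjects
    (5 with music), 30 parcels, 100 TRs, default planted effects."""
    spec = bs.SyntheticSpec(n_subjects=6, n_music_subjects=5, P=30, T=100, seed=3)
    return bs.simulate_study(spec)


@pytest.fixture(scope="session")
def small_concat(small_study):
    runs = [bs.zscore_run(r) for r in small_study.runs]
    return bs.concatenate_runs(runs)


@pytest.fixture(scope="session")
def small_model(small_concat):
    model = bs.fit_states(small_concat, 4, n_init=3, seed=42)
    return bs.canonical_order(model)
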