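import numpy as np
import pytest

import lrtab


@pytest.fixture
def large_trial():
    """20,000-patient trial: treatment vs placebo, death vs survival."""
    return lrtab.make_table([[80, 9920], [120, 9880]])


@pytest.fixture
def small_trial():
    """2,000-patient replication with a modified treatment."""
    return lrtab.make_table([[3, 997], [10, 990]])


@pytest.fixture
def replication_probs():
    """Outcome probabilities estimated from the large trial."""
    return np.array([[0.004, 0.496], [0.006, 0.494]])


@pytest.fixture
def rng():
    return np.random.default_rng(20240428)


def random_positive_table(rng, max_count=500):
    """A random 2x2 table with all margins positive."""
    while True:
        counts = rng.integers(0, max_count, size=(2, 2))
        t = lrtab.make_table(counts)
        if (t.row_totals > 0).all() and (t.col_totals > 0).all():
            return t
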