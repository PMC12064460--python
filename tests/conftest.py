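import numpy as np
import pytest

import promis_irt as pi


@pytest.fixture(scope="session")
def anxiety_bank():
    return pi.load_item_bank("anxiety_sv")


@pytest.fixture(scope="session")
def depressive_bank():
    return pi.load_item_bank("depressive_sv")


@pytest.fixture(scope="session")
def anxiety_cohort(anxiety_bank):
    """Medium synthetic cohort (n=900, standard-normal thetas), complete."""
    rng = np.random.default_rng(12345)
    thetas = rng.normal(0.0, 1.0, 900)
    return pi.simulate_responses(anxiety_bank, thetas, rng)


def two_group_matrix(bank, reference_bank, focal_bank, n_per_group, rng):
    """Stack reference- and focal-group responses into one matrix + labels."""
    import pandas as pd

    th_r = rng.normal(0.0, 1.0, n_per_group)
    th_f = rng.normal(0.0, 1.0, n_per_group)
    m_r = pi.simulate_responses(reference_bank, th_r, rng)
    m_f = pi.simulate_responses(focal_bank, th_f, rng)
    resp = pd.concat([m_r.responses, m_f.responses], ignore_index=True)
    resp.index.name = "person_id"
    groups = np.array(["ref"] * n_per_group + ["foc"] * n_per_group)
    return pi.ResponseMatrix(resp), groups
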