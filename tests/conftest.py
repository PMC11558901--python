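"""Shared fixtures: one mid-size cohort and its truth values, reused
across modules to keep the suite fast."""

import numpy as np
import pytest

import mnarpba as m


@pytest.fixture(scope="session")
def demo():
    """Default selection-model generator (beta_x = ln 3, delta_sm = 7.85)."""
    return m.demo_params()


@pytest.fixture(scope="session")
def cohort100k(demo):
    """One n=100,000 complete dataset from the SM generator."""
    return m.generate_sm_complete(100_000, demo, seed=101)


@pytest.fixture(scope="session")
def observed100k(cohort100k):
    return m.apply_missingness(cohort100k, seed=102)


@pytest.fixture(scope="session")
def small_pair(demo):
    """(complete, observed) pair at n=8,000 for imputation-level tests."""
    complete = m.generate_sm_complete(8_000, demo, seed=111)
    return complete, m.apply_missingness(complete, seed=112)


@pytest.fixture(scope="session")
def truth(demo):
    """Truth values derived at reduced scale (n=400,000)."""
    return m.derive_truth("SM", demo, n_truth=400_000, seed=103)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
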