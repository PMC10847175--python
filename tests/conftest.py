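"""Shared fixtures: one fully simulated integration event reused across tests."""

import pytest

from intragene import simulate


@pytest.fixture(scope="session")
def event():
    """Default single-copy integration event with reads (seed 1)."""
    return simulate.simulate_event(seed=1)


@pytest.fixture(scope="session")
def wild_type_event():
    """Reads drawn from the untransformed reference of the same study (seed 1)."""
    return simulate.simulate_event(seed=1, wild_type=True)


@pytest.fixture(scope="session")
def clean_event():
    """Error-free, read-light event for junction-level tests (seed 7)."""
    return simulate.simulate_event(seed=7, error_rate=0.0, with_reads=False)
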