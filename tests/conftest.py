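"""Shared fixtures: instruments, simulated datasets and calibrations.

Expensive simulations and fits are session-scoped so that several tests
can interrogate the same calibration.
"""

import numpy as np
import pandas as pd
import pytest

import ctclqol as cq


@pytest.fixture(scope="session")
def instrument():
    return cq.published_instrument()


@pytest.fixture(scope="session")
def bank():
    return cq.item_bank()


def min_interference_row(instrument):
    """Response codes for the least-interference answer on every item."""
    return {
        it.id: (5 if it.reverse_scored else 1) for it in instrument.items
    }


def max_interference_row(instrument):
    return {
        it.id: (1 if it.reverse_scored else 5) for it in instrument.items
    }


@pytest.fixture(scope="session")
def sim1000(instrument):
    """n=1000 model-true draw plus its generating truth."""
    truth = cq.make_truth(instrument, seed=20260)
    rm, _, theta = cq.simulate_responses(
        instrument, 1000, truth, with_covariates=False
    )
    return {"responses": rm, "truth": truth, "theta": theta}


@pytest.fixture(scope="session")
def calib1000(instrument, sim1000):
    """G-RSM calibration of the n=1000 model-true dataset."""
    return cq.fit(sim1000["responses"], instrument, "grsm")


@pytest.fixture(scope="session")
def purge_fixture(bank):
    """14-item bank, two uniform-random (off-model) items, n=400."""
    truth = cq.make_truth(
        bank, seed=314, misfit_items={"q08", "q13"}, dna_rate=0.0
    )
    rm, _, _ = cq.simulate_responses(bank, 400, truth, with_covariates=False)
    return {"responses": rm, "truth": truth}


@pytest.fixture(scope="session")
def purge_result(bank, purge_fixture):
    return cq.purge_items(purge_fixture["responses"], bank)


@pytest.fixture(scope="session")
def study():
    return cq.simulate_study(seed=2024)
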