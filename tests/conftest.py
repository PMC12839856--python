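"""Shared fixtures: one trained scaffold and one evaluation case suite.

The trained fixture is expensive (~1 min of CPU), so it is built once per
session and shared by the scaffold, CAM, reasoning and acceptance tests.
All fixtures are pure functions of fixed seeds.
"""

import warnings

import numpy as np
import pytest

from cxrtrust.synth import fixture_model, make_dataset

FIXTURE_SEED = 7
CASE_SUITE_SEED = 123


@pytest.fixture(scope="session")
def trained_checkpoint():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fixture_model(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def trained_model(trained_checkpoint):
    return trained_checkpoint.model(use_ema=True)


@pytest.fixture(scope="session")
def case_suite():
    """75 single-finding cases (60 with boxes, 15 normals) at 64 px."""
    _, _, cases = make_dataset(CASE_SUITE_SEED, 75, size=64)
    return cases


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
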