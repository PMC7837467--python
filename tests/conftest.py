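"""Shared fixtures: a small phantom case and its analysis, built once."""

from __future__ import annotations

import numpy as np
import pytest

from jawmotion.phantom import default_validation_case, to_case_inputs
from jawmotion.pipeline import analyze_case

# reduced problem size for routine tests; the acceptance suite runs the
# full-resolution canonical case
SMALL = dict(grid_size=112, spacing=0.7)
SMALL_SEED = 11


@pytest.fixture(scope="session")
def small_case():
    return default_validation_case(seed=SMALL_SEED, **SMALL)


@pytest.fixture(scope="session")
def small_inputs(small_case):
    return to_case_inputs(small_case)


@pytest.fixture(scope="session")
def small_report(small_inputs):
    return analyze_case(small_inputs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
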