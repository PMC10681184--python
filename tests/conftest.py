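"""Shared fixtures: small designs, lists and simulated datasets.

Everything is generated programmatically and seeded, so the suite needs no
data files.  Expensive artifacts (the selected full-scale list) are
session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from pcstroop import (GenerativeParams, HGFParams, assign_primes,
                      default_design, generate_candidates, pseudorandomize,
                      simulate_dataset, trialwise_predictors)
from pcstroop import design as dsn
from pcstroop import hgf as hgf_mod


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def trial_list(design):
    tl = pseudorandomize(design, seed=1234)
    return assign_primes(tl, seed=99)


@pytest.fixture(scope="session")
def beliefs(trial_list):
    return trialwise_predictors(trial_list, HGFParams())


@pytest.fixture(scope="session")
def small_dataset(trial_list, beliefs):
    """Six synthetic participants over the default list."""
    params = GenerativeParams(n_participants=6)
    data, meta = simulate_dataset(params, trial_list, beliefs, master_seed=7)
    return data, meta, params
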