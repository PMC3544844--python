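import numpy as np
import pytest

from ecmsim import Phenotype, ProbabilityModel, config_from_dict


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(**overrides):
    """A small, fast simulation configuration for engine-level tests.

    A 20^3 cellular region inside a 30^3 ECM region with a few hundred fibers
    and a handful of cells keeps every invariant of the full-size system while
    running orders of magnitude faster.
    """
    raw = {
        "lattice": {"cell_lattice_size": 20, "ecm_lattice_size": 30, "spacing": 4.5},
        "matrix": {"n_fibers": 250},
        "phenotype": {
            "name": "low_invasive",
            "initial_cells": 4,
            "min_cells": 3,
        },
        "run": {"n_steps": 20, "record_every": 5},
        "quantify": {"n_slices": 3},
    }
    for key, value in overrides.items():
        if isinstance(value, dict) and key in raw:
            raw[key].update(value)
        else:
            raw[key] = value
    return config_from_dict(raw)


@pytest.fixture
def tiny_config():
    return small_config()
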