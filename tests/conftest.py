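import numpy as np
import pytest

from cellens.ensemble_metrics import Ensemble
from cellens.model_core import StrainSpec
from cellens.toy_model import (
    DEFAULT_ELIMINABLE_RATES,
    ToyConfig,
    default_training_constraint,
    make_reference_ensemble,
    make_strain_panel,
    make_toy_model,
)


@pytest.fixture(scope="session")
def toy_cfg():
    return ToyConfig()


@pytest.fixture(scope="session")
def toy(toy_cfg):
    """(model, reference parameter vector) of the default fixture."""
    return make_toy_model(toy_cfg)


@pytest.fixture(scope="session")
def model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def reference(toy):
    return toy[1]


@pytest.fixture(scope="session")
def sim(toy_cfg):
    """Screening-resolution simulation settings used throughout the tests."""
    return dict(dt=toy_cfg.dt, horizon=toy_cfg.horizon,
                size_cap=toy_cfg.size_cap, band=toy_cfg.band)


@pytest.fixture(scope="session")
def constraint(model):
    return default_training_constraint(model)


@pytest.fixture(scope="session")
def small_panel():
    """21 prediction strains from 6 eliminable rates, orders 1-2."""
    return make_strain_panel(DEFAULT_ELIMINABLE_RATES[:6], max_order=2)


@pytest.fixture(scope="session")
def feasible_ensemble(model, reference, constraint, toy_cfg):
    """30 FC1-feasible vectors around the reference (heavy-tailed jitter)."""
    values = make_reference_ensemble(model, reference, 30, 0.10, seed=11,
                                     constraint=constraint, dt=toy_cfg.dt,
                                     horizon=toy_cfg.horizon)
    names = tuple(model.params) + tuple(model.species)
    return Ensemble(values=values, param_names=names)


def strain(*rates, id=99):
    return StrainSpec(id=id, label="+".join(rates),
                      overrides=tuple((r, 0.0) for r in rates))
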