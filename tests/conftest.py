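"""Shared fixtures: synthetic models, datasets and small ensembles."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import kincontrol as kc
from kincontrol.model import Compartment, MetabolicModel, Metabolite, Reaction
from kincontrol.synth import (
    MassActionSystem,
    SyntheticSpec,
    generate_condition_series,
    generate_ground_truth,
    generate_toy_model,
    standard_gibbs_table,
)

# scipy's LSODA prints convergence chatter when the steady-state fallback
# integrates a stiff system; it is handled (Newton polish follows)
warnings.filterwarnings("ignore", message=".*lsoda.*")


@pytest.fixture(scope="session")
def branched_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def branched_model(branched_spec):
    return generate_toy_model(branched_spec)


@pytest.fixture(scope="session")
def branched_truth(branched_spec, branched_model):
    return generate_ground_truth(branched_model, branched_spec)


@pytest.fixture(scope="session")
def branched_datasets(branched_truth, branched_spec):
    return generate_condition_series(branched_truth, branched_spec)


@pytest.fixture(scope="session")
def branched_std(branched_model, branched_spec):
    return standard_gibbs_table(branched_model, branched_spec)


@pytest.fixture(scope="session")
def small_ensemble(branched_model, branched_datasets, branched_std):
    """20 retained instances on the mid-dilution glucose-limited condition."""
    cfg = kc.PipelineConfig(n_target=20, min_attempts=20, base_seed=42)
    return kc.EnsembleModel(
        branched_model, branched_datasets[2], branched_std, cfg
    ).fit()


@pytest.fixture(scope="session")
def chain_fixture():
    """Linear chain template with its datasets and Gibbs table."""
    spec = SyntheticSpec(seed=1, template="linear_chain")
    model = generate_toy_model(spec)
    truth = generate_ground_truth(model, spec)
    datasets = generate_condition_series(truth, spec)
    std = standard_gibbs_table(model, spec)
    return spec, model, truth, datasets, std


@pytest.fixture(scope="session")
def two_comp_fixture():
    spec = SyntheticSpec(seed=2, template="two_compartment_mini")
    model = generate_toy_model(spec)
    truth = generate_ground_truth(model, spec)
    datasets = generate_condition_series(truth, spec)
    std = standard_gibbs_table(model, spec)
    return spec, model, truth, datasets, std


@pytest.fixture()
def two_step_chain():
    """Hand-written mass-action fixture with known closed-form control.

    v1 = E1 (k1 s - k-1 x) with s held fixed, v2 = E2 k2 x: at unit
    constants the steady state is x* = 1/2 and both control coefficients
    equal 1/2.
    """
    model = MetabolicModel(
        [Compartment("c")],
        [Metabolite("s_c", "c", is_fixed=True), Metabolite("x_c", "c")],
        [
            Reaction("R1", {"s_c": -1.0, "x_c": +1.0}),
            Reaction("R2", {"x_c": -1.0}, is_drain=True),
        ],
    )
    return MassActionSystem(
        model,
        kf={"R1": 1.0, "R2": 1.0},
        kr={"R1": 1.0, "R2": 0.0},
        x_ref={"s_c": 1.0, "x_c": 0.5},
    )


@pytest.fixture(scope="session")
def yeast_model():
    return kc.yeast_ccm()


def nanmedian(stack, axis=0):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(stack, axis=axis)
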