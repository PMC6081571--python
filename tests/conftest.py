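"""Shared fixtures: generated trees, ventilation tables and flow solutions.

Session-scoped so the generator and flow solver run once per phenotype; the
transport-heavy fixtures keep particle counts modest — the full study-scale
ensembles live in the acceptance tests.
"""

import warnings

import numpy as np
import pytest

from aerotree.boundary_conditions import flow_solution
from aerotree.flow_field import build_frames
from aerotree.particle_transport import ReleaseSpec, TransportConfig, run_ensemble
from aerotree.synthetic_data import (
    PHENOTYPES,
    generate_tree,
    generate_volume_change,
)


@pytest.fixture(scope="session")
def healthy_tree():
    return generate_tree(PHENOTYPES["healthy_1"])


@pytest.fixture(scope="session")
def healthy_dv():
    return generate_volume_change(PHENOTYPES["healthy_1"])


@pytest.fixture(scope="session")
def healthy_flow(healthy_tree, healthy_dv):
    return flow_solution(healthy_tree, healthy_dv)


@pytest.fixture(scope="session")
def healthy_frames(healthy_tree, healthy_flow):
    return build_frames(healthy_tree, healthy_flow)


@pytest.fixture(scope="session")
def tracer_summary(healthy_tree, healthy_flow):
    """Small tracer ensemble, turbulence off (pure flow-split mechanics)."""
    rs = ReleaseSpec(n_particles=4000, n_releases=2, diameters=(0.0,), rng_seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_ensemble(
            healthy_tree, healthy_flow, rs, TransportConfig(turbulence=None)
        )


@pytest.fixture(scope="session")
def inertial_summary(healthy_tree, healthy_flow):
    """Small 5/10 um ensemble on the healthy tree, turbulence off."""
    rs = ReleaseSpec(
        n_particles=3000, n_releases=2, diameters=(5e-6, 10e-6), rng_seed=6
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_ensemble(
            healthy_tree, healthy_flow, rs, TransportConfig(turbulence=None)
        )
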