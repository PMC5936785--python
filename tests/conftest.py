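"""Shared fixtures.

Expensive artefacts (the default cavity surface, the solver validation
cases, the desk-scale paired study) are session-scoped so that unit tests
and the acceptance tests measure the same computation exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from lvflow import anatomy, study, validation


@pytest.fixture(scope="session")
def cavity_params():
    return anatomy.CavityParams()


@pytest.fixture(scope="session")
def cavity_surface(cavity_params):
    return anatomy.build_smoothed_cavity(cavity_params)


@pytest.fixture(scope="session")
def trabeculated_surface(cavity_surface):
    trab = anatomy.TrabeculationParams(target_volume_fraction=0.20, seed=3)
    return anatomy.add_trabeculation(cavity_surface, trab)


@pytest.fixture(scope="session")
def cavity_mesh(cavity_surface):
    return anatomy.tetrahedralize(cavity_surface, edge_length=0.004)


@pytest.fixture(scope="session")
def poiseuille_result():
    return validation.poiseuille_case()


@pytest.fixture(scope="session")
def tg_decay_result():
    return validation.taylor_green_decay_case()


@pytest.fixture(scope="session")
def inviscid_result():
    return validation.inviscid_energy_case()


@pytest.fixture(scope="session")
def darcy_result():
    return validation.darcy_channel_case()


@pytest.fixture(scope="session")
def qsphere_result():
    return validation.q_sphere_case()


@pytest.fixture(scope="session")
def mass_result():
    return validation.mass_conservation_case(t_end=0.2)


@pytest.fixture(scope="session")
def desk_result():
    return study.reproduce_desk(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
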