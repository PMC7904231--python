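"""Shared fixtures: small synthetic systems and session-cached scenario runs."""

import numpy as np
import pytest

from lipidmap.membrane import MembraneSpec, PentamerModel, build_membrane
from lipidmap.dynamics import SyntheticTruth, simulate
from lipidmap.scenarios import DIFFUSION


@pytest.fixture(scope="session")
def small_system():
    """A 20-lipids-per-leaflet membrane around a reduced pentamer."""
    spec = MembraneSpec(nominal_per_leaflet=20)
    pent = PentamerModel.make(n_res_per_helix=4)
    top, init = build_membrane(spec, pent, (9.0, 6.0), seed=42)
    return spec, pent, top, init


@pytest.fixture(scope="session")
def small_run(small_system):
    """A short free-diffusion run of the small system (no sites, no flips)."""
    _, _, top, init = small_system
    truth = SyntheticTruth(sites=[], diffusion={}, flipflop_rate=0.0,
                           protein_core_radius=1.4)
    traj = simulate(top, init, truth, n_steps=600, step_dt=1.0,
                    write_every=10, seed=7)
    return top, traj


@pytest.fixture(scope="session")
def hierarchy_result():
    """One seed of the lipid-hierarchy recovery scenario (shared, expensive)."""
    from lipidmap.scenarios import run_hierarchy

    return run_hierarchy(1)


@pytest.fixture(scope="session")
def state_pair_result():
    """Paired active/inactive interface-site scenario (shared, expensive)."""
    from lipidmap.scenarios import run_state_pair

    return run_state_pair(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
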