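"""Shared fixtures.

Expensive ensembles are session-scoped and reused across tests; everything
is seeded, so the suite is deterministic.
"""

from __future__ import annotations

import pytest

import halorheo as h
from halorheo.experiments_io import azimuthal_modulus_recovery, jeffreys_run_config


@pytest.fixture(scope="session")
def ou_fixture():
    """32-particle mini-ensemble whose z channel is a unit-stiffness OU process."""
    return h.fixture_ensemble("ou_1d", seed=7)


@pytest.fixture(scope="session")
def newtonian_main():
    """The scaled Newtonian ring protocol: 200 particles, t_max = 200, R = 150."""
    cfg = h.SimulationConfig(dt_hat=0.02, n_steps=10000, n_particles=200,
                             seed=101, burn_in_hat=10.0)
    traj = h.simulate_newtonian(150.0, 1.0 / 3.0, cfg)
    return traj, h.correlate_ensemble(traj)


@pytest.fixture(scope="session")
def newtonian_stiffness_sweep(newtonian_main):
    """Correlation sets at kz/kr in {1/9, 1/3, 1} for the axial master curve."""
    ratios = [1.0 / 9.0, 1.0 / 3.0, 1.0]
    corrsets = []
    for i, ratio in enumerate(ratios):
        if ratio == 1.0 / 3.0:
            corrsets.append(newtonian_main[1])
            continue
        cfg = h.SimulationConfig(dt_hat=0.02, n_steps=10000, n_particles=200,
                                 seed=111 + i,
                                 burn_in_hat=10.0 / min(1.0, ratio))
        traj = h.simulate_newtonian(150.0, ratio, cfg)
        corrsets.append(h.correlate_ensemble(traj))
    return corrsets, ratios


@pytest.fixture(scope="session")
def anisotropy_runs():
    """Long Newtonian runs at small torus radii, plus a wide-torus reference."""
    out = {}
    for i, R in enumerate([5.0, 10.0, 20.0, 150.0]):
        # the R = 20 plateau is ~2.5e-3: resolving it above noise needs the
        # long horizon and the large ensemble
        cfg = h.SimulationConfig(dt_hat=0.04, n_steps=20000, n_particles=400,
                                 seed=201 + i, burn_in_hat=20.0)
        traj = h.simulate_newtonian(R, 1.0 / 3.0, cfg)
        out[R] = (traj, h.correlate_ensemble(traj))
    return out


@pytest.fixture(scope="session")
def jeffreys_recovery_cache():
    """Factory caching the four (De, kstar/kr) recovery runs of the G* study."""
    cache: dict[tuple[float, float], dict] = {}

    def get(De: float, ratio: float):
        key = (De, ratio)
        if key not in cache:
            seed = 301 + 10 * int(De) + int(100 * ratio)
            cfg = jeffreys_run_config(De, ratio, 1.0 / 3.0, 500, seed)
            traj = h.simulate_jeffreys(150.0, 1.0 / 3.0, ratio, De, cfg)
            rec, cs, curve = azimuthal_modulus_recovery(traj, De, ratio)
            cache[key] = {"traj": traj, "recovery": rec, "cs": cs,
                          "curve": curve}
        return cache[key]

    return get
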