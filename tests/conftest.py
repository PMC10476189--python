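"""Shared fixtures.

The expensive session-scoped fixtures run seeded BD simulations once and
are shared between the unit suites and the acceptance tests; everything is
generated in-process (no data files).
"""

import numpy as np
import pytest

from iggbd import engine, model, pipelines


@pytest.fixture(scope="session")
def dilute_igg_runs():
    """Dilute-limit IgG sampling with intra-molecule RPY hydrodynamics.

    One seeded run of eight well-separated IgG copies, 6 us production
    each: 48 us of effective dilute sampling for the transport targets.
    """
    params = engine.SimulationParameters(dt=2.5e-7, mobility_stride=10,
                                         neighbour_skin=3.0)
    return pipelines.dilute_igg_trajectories(
        n_seeds=1, production=3.0, burn_in=0.3, seed=2024, params=params,
        n_igg=8, sample_interval=0.002)


@pytest.fixture(scope="session")
def dilute_transport(dilute_igg_runs):
    return pipelines.dilute_summary(dilute_igg_runs,
                                    msd_window=(0.5, 1.2),
                                    acf_window=(0.1, 0.8))


@pytest.fixture(scope="session")
def angle_sampling_run():
    """Free-draining IgG run for equilibrium angle statistics.

    Bond stiffness does not enter the angular equilibrium distribution
    (the configurational measure factorises over bond vectors), so bonds
    are softened to kappa = 50 to lift the timestep, and 3e5 angle samples
    are collected over 300 us.
    """
    soft = {k: {"kappa": 50.0}
            for k in ["S-H", "H-A1", "H-A1p", "A1-A2", "A1p-A2p"]}
    igg = model.build_igg({"bonds": soft})
    pos = model.igg_reference_geometry(igg) + 50.0
    cfg = model.SystemConfiguration(
        positions=pos, molecules=[igg], mol_index=np.zeros(6, dtype=np.int64),
        box=np.full(3, 100.0), periodic=np.array([True] * 3))
    params = engine.SimulationParameters(hydrodynamics="free_draining",
                                         dt=1.05e-5)
    return engine.run(cfg, params,
                      engine.Schedule(burn_in=1.5, production=280.0,
                                      sample_interval=0.0027), seed=881)


@pytest.fixture(scope="session")
def crowding_sweep_result():
    """Scaled-down occupied-volume-fraction sweep.

    Free-draining dynamics (the hydrodynamic coupling scope in crowded
    boxes is a mode switch; see docs/methods.md) at a fraction of the
    sampling the quantitative sensitivities would need -- the directional
    content is what this fixture can support.
    """
    params = engine.SimulationParameters(hydrodynamics="free_draining",
                                         dt=2.5e-7, neighbour_skin=1.5)
    return pipelines.crowding_sweep(
        [0.0, 0.05, 0.10, 0.15], n_igg=4, box_edge=50.0, production=0.8,
        burn_in=0.25, seed=515, params=params, msd_window=(0.2, 0.6))
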