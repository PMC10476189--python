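"""Ermak-McCammon propagator: drift contract, determinism, sampling laws."""

import numpy as np
import pytest

from iggbd import analysis, model
from iggbd.engine import (Schedule, SimulationParameters, StabilityError,
                          run, step)
from iggbd.model import (BeadSpec, BondTerm, AngleTerm, MoleculeTopology,
                         SystemConfiguration)
from iggbd.units import kbt, stokes_diffusion


def _single_bead(radius=2.42, box=60.0, wall=None, z0=30.0):
    topo = MoleculeTopology([BeadSpec("b", radius, radius)], [], [], set(),
                            kind="crowder")
    return SystemConfiguration(
        positions=np.array([[box / 2, box / 2, z0]]), molecules=[topo],
        mol_index=np.zeros(1, dtype=np.int64), box=np.full(3, box),
        periodic=np.array([True, True, wall is None]), wall=wall)


def _chain(radii, bonds, angles=(), box=80.0, positions=None, kind="crowder"):
    beads = [BeadSpec(f"b{i}", r, r) for i, r in enumerate(radii)]
    topo = MoleculeTopology(beads, list(bonds), list(angles), set(),
                            kind=kind)
    n = len(radii)
    if positions is None:
        positions = np.zeros((n, 3))
        positions[:, 0] = np.arange(n) * 5.0
    return SystemConfiguration(
        positions=np.asarray(positions) + box / 2, molecules=[topo],
        mol_index=np.zeros(n, dtype=np.int64), box=np.full(3, box),
        periodic=np.array([True] * 3))


class TestStep:
    def test_deterministic_drift_equals_einstein_relation(self):
        """Constant wall force, noise disabled: dz = D * F * dt / kBT."""
        a = 2.42
        wall = model.Wall()
        cfg = _single_bead(radius=a, wall=wall, z0=a - 0.1)  # 0.1 nm overlap
        params = SimulationParameters(hydrodynamics="free_draining", dt=1e-6)
        new = step(cfg, params, noise=np.zeros((1, 3)))
        F = 4000.0 * 0.1  # k_ov * overlap
        expected = stokes_diffusion(a) * F * params.dt / kbt()
        assert new.positions[0, 2] - cfg.positions[0, 2] == pytest.approx(
            expected, rel=1e-12)

    def test_zero_force_mean_square_step(self):
        cfg = _single_bead(radius=5.1)
        params = SimulationParameters(hydrodynamics="free_draining", dt=1e-4)
        rng = np.random.default_rng(8)
        d2 = []
        for _ in range(4000):
            new = step(cfg, params, rng=rng)
            d2.append(np.sum((new.positions - cfg.positions) ** 2))
        d2 = np.asarray(d2)
        expected = 6 * stokes_diffusion(5.1) * params.dt
        assert d2.mean() == pytest.approx(
            expected, rel=4 * np.sqrt(2.0 / 3.0 / len(d2)))

    def test_oversized_step_raises_stability_error(self):
        cfg = _single_bead(radius=1.0)
        params = SimulationParameters(hydrodynamics="free_draining", dt=1.0,
                                      allow_large_dt=True)
        with pytest.raises(StabilityError):
            step(cfg, params, rng=np.random.default_rng(0))


class TestRun:
    def test_same_seed_bitwise_identical(self):
        cfg = _chain([1.5, 1.5], [BondTerm(0, 1, 5.0, 100.0)])
        params = SimulationParameters(dt=4e-6)
        sched = Schedule(burn_in=0.0, production=0.01, sample_interval=1e-3)
        t1 = run(cfg, params, sched, seed=99)
        t2 = run(cfg, params, sched, seed=99)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        t3 = run(cfg, params, sched, seed=100)
        assert not np.array_equal(t1.positions, t3.positions)

    def test_zero_production_gives_single_frame_with_metadata(self):
        cfg = _single_bead()
        params = SimulationParameters(hydrodynamics="free_draining", dt=1e-4)
        traj = run(cfg, params, Schedule(burn_in=0.0, production=0.0,
                                         sample_interval=1e-3), seed=1)
        assert traj.n_frames == 1
        assert traj.seed == 1
        assert traj.params is params

    def test_dt_stability_precheck(self):
        cfg = _chain([1.0, 1.0], [BondTerm(0, 1, 3.0, 1909.9)])
        params = SimulationParameters(dt=1e-5)  # far above tau/5 for a=1
        with pytest.raises(StabilityError, match="relaxation"):
            run(cfg, params, Schedule(production=0.001), seed=1)

    def test_unwrapped_and_wrapped_differ_by_box_multiples(self):
        cfg = _single_bead(radius=5.1, box=12.0)
        params = SimulationParameters(hydrodynamics="free_draining", dt=1e-4)
        traj = run(cfg, params, Schedule(burn_in=0.0, production=30.0,
                                         sample_interval=0.01), seed=4)
        wrapped = traj.wrapped_positions()
        ratio = (traj.positions - wrapped) / traj.config.box
        assert np.allclose(ratio, np.round(ratio), atol=1e-9)
        assert np.all(wrapped >= 0) and np.all(wrapped <= 12.0)
        # the walk must actually have crossed the boundary for this test
        assert np.abs(traj.positions - traj.positions[0]).max() > 12.0

    @pytest.mark.parametrize("radius", [1.0, 2.42, 5.1])
    def test_free_sphere_stokes_einstein(self, radius):
        """Long-run translational D matches kBT/(6 pi eta a) within ~2%.

        A 16-walker free-draining batch (one topology, no interactions)
        gives the statistics cheaply.
        """
        n = 32
        beads = [BeadSpec(f"b{i}", radius, radius) for i in range(n)]
        topo = MoleculeTopology(beads, [], [],
                                {(i, j) for i in range(n)
                                 for j in range(i + 1, n)}, kind="crowder")
        rng = np.random.default_rng(0)
        cfg = SystemConfiguration(
            positions=rng.uniform(0, 500.0, (n, 3)), molecules=[topo],
            mol_index=np.zeros(n, dtype=np.int64), box=np.full(3, 500.0),
            periodic=np.array([True] * 3))
        # rms step ~5% of the radius keeps the displacement guard quiet
        params = SimulationParameters(hydrodynamics="free_draining",
                                      dt=5.8e-6 * radius ** 3)
        traj = run(cfg, params, Schedule(burn_in=0.0, production=90.0,
                                         sample_interval=0.005),
                   seed=1000 + int(radius * 10))
        curve = analysis.msd_from_positions(traj.times,
                                            traj.positions)
        # free diffusion has no transient, so short lags are unbiased and
        # carry far more independent increments
        est = analysis.fit_diffusion(curve, window=(0.01, 0.25))
        assert est.D == pytest.approx(stokes_diffusion(radius), rel=0.02)


def _ks_against_quadrature(samples, grid, cdf_ref):
    emp = np.searchsorted(np.sort(samples), grid, side="right") / len(samples)
    return np.abs(emp - cdf_ref).max()


class TestBoltzmannSampling:
    def test_dumbbell_bond_length_distribution(self):
        """Bond lengths follow r^2 exp(-U/kBT) (KS < 0.02 at 1e5 samples)."""
        kap, req = 20.0, 6.0
        cfg = _chain([1.5, 1.5], [BondTerm(0, 1, req, kap)])
        params = SimulationParameters(hydrodynamics="free_draining", dt=2e-5)
        traj = run(cfg, params, Schedule(burn_in=1.0, production=100.0,
                                         sample_interval=1e-3), seed=21)
        r = np.linalg.norm(traj.positions[:, 0] - traj.positions[:, 1],
                           axis=1)
        assert len(r) == 100_001
        grid = np.linspace(req - 3, req + 3, 800)
        u = 0.5 * kap * (grid - req) ** 2
        pdf = grid ** 2 * np.exp(-(u - u.min()) / kbt())
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        assert _ks_against_quadrature(r, grid, cdf) < 0.02

    def test_trimer_angle_distribution_with_jacobian(self):
        """A single harmonic angle samples sin(theta) exp(-U/kBT)."""
        xi = 1.0
        bonds = [BondTerm(0, 1, 4.0, 30.0), BondTerm(1, 2, 4.0, 30.0)]
        angles = [AngleTerm(0, 1, 2, 90.0, xi)]
        pos = np.array([[4.0, 0, 0], [0.0, 0, 0], [0.0, 4.0, 0]])
        cfg = _chain([1.5, 1.0, 1.5], bonds, angles, positions=pos)
        params = SimulationParameters(hydrodynamics="free_draining", dt=1.2e-5)
        traj = run(cfg, params, Schedule(burn_in=2.0, production=220.0,
                                         sample_interval=2e-3), seed=31)
        u = traj.positions[:, 0] - traj.positions[:, 1]
        v = traj.positions[:, 2] - traj.positions[:, 1]
        c = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        theta = np.degrees(np.arccos(np.clip(c, -1, 1)))
        from iggbd.analysis import boltzmann_angle_cdf
        grid, cdf = boltzmann_angle_cdf(90.0, xi)
        assert _ks_against_quadrature(theta, grid, cdf) < 0.02
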