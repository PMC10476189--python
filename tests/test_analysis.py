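"""Observable extraction: MSD/D, ACF/D_r, angles, R_g, alpha fits."""

import numpy as np
import pandas as pd
import pytest

from iggbd import analysis, model
from iggbd.analysis import (AngleSample, CrowdingSeries, boltzmann_angle_cdf,
                            calibrate_angles, empirical_cdf_pdf, fit_alpha,
                            fit_diffusion, fit_rotational, igg_angles,
                            igg_hinge_quadrature, msd_from_positions,
                            hydrodynamic_radius, radius_of_gyration,
                            rot_trans_parameter)


class TestMsd:
    def test_stationary_particle_is_identically_zero(self):
        t = np.arange(50) * 0.1
        x = np.ones((50, 1, 3)) * 5.0
        curve = msd_from_positions(t, x)
        assert np.allclose(curve["msd"], 0.0, atol=1e-10)
        assert curve["msd"].iloc[0] == 0.0

    def test_random_walk_recovers_known_diffusion(self):
        """Synthetic ideal walk with D = 25: fitted slope/6 within 2%."""
        rng = np.random.default_rng(123)
        D, dt = 25.0, 0.01
        n, m = 4000, 200
        steps = rng.normal(scale=np.sqrt(2 * D * dt), size=(n, m, 3))
        x = np.cumsum(steps, axis=0)
        curve = msd_from_positions(np.arange(n) * dt, x)
        est = fit_diffusion(curve, window=(0.05, 1.0))
        assert est.D == pytest.approx(D, rel=0.02)

    def test_exact_line_gives_exact_slope(self):
        t = np.linspace(0, 10, 200)
        curve = pd.DataFrame({"lag": t, "msd": 6 * 10.0 * t})
        assert fit_diffusion(curve, (0.5, 5)).D == pytest.approx(10.0)

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            msd_from_positions(np.array([0.0]), np.zeros((1, 1, 3)))


class TestRotational:
    def test_exact_exponential(self):
        t = np.linspace(0, 2, 400)
        acf = pd.DataFrame({"lag": t, "acf": np.exp(-2 * 1.5 * t)})
        assert fit_rotational(acf, window=(0.0, 1.0)) == pytest.approx(1.5)

    def test_frozen_configuration_zero_dr(self):
        t = np.linspace(0, 2, 100)
        acf = pd.DataFrame({"lag": t, "acf": np.ones_like(t)})
        assert fit_rotational(acf, window=(0.0, 1.0)) == pytest.approx(0.0,
                                                                       abs=1e-12)

    def test_rigid_dumbbell_matches_rigid_body_mobility(self):
        """D_r of a stiff two-bead dumbbell vs the analytic rigid-body value
        from the pair RPY resistance (5%)."""
        from iggbd.engine import Schedule, SimulationParameters, run
        from iggbd.hydrodynamics import mobility_matrix
        from iggbd.model import (BeadSpec, BondTerm, MoleculeTopology,
                                 SystemConfiguration)
        a, L = 1.5, 6.0
        topo = MoleculeTopology(
            [BeadSpec("S", a, a), BeadSpec("H", a, a)],
            [BondTerm(0, 1, L, 100.0)], [], set(), kind="IgG")
        pos = np.array([[0.0, 0, 0], [0.0, 0, L]]) + 40.0
        cfg = SystemConfiguration(
            positions=pos, molecules=[topo],
            mol_index=np.zeros(2, dtype=np.int64), box=np.full(3, 80.0),
            periodic=np.array([True] * 3))
        # analytic rigid-body D_r via projection of the RPY resistance onto
        # translations + the two transverse rotations (rotation about the
        # rod axis moves no bead and must be excluded)
        M = mobility_matrix(cfg).matrix
        R = np.linalg.inv(M)
        center = pos.mean(axis=0)
        axis = np.array([0.0, 0.0, 1.0])
        e1, e2 = np.array([1.0, 0, 0]), np.array([0.0, 1.0, 0])
        K = np.zeros((6, 5))
        for i in range(2):
            K[3 * i:3 * i + 3, :3] = np.eye(3)
            arm = pos[i] - center
            K[3 * i:3 * i + 3, 3] = np.cross(e1, arm)
            K[3 * i:3 * i + 3, 4] = np.cross(e2, arm)
        mob = np.linalg.inv(K.T @ R @ K)
        dr_axis = 0.5 * (mob[3, 3] + mob[4, 4])
        params = SimulationParameters(dt=6e-6)
        traj = run(cfg, params, Schedule(burn_in=0.5, production=50.0,
                                         sample_interval=1e-3), seed=77)
        acf = analysis.orientation_acf(traj, axis=("S", "H"))
        dr_sim = fit_rotational(acf, window=(0.0, 3.0 / (2 * dr_axis)),
                                min_acf=0.05)
        assert dr_sim == pytest.approx(dr_axis, rel=0.05)

    def test_estimates_invariant_under_rigid_rotation(self):
        rng = np.random.default_rng(5)
        t = np.arange(2000) * 0.01
        x = np.cumsum(rng.normal(size=(2000, 1, 3)), axis=0)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, xq, yq, zq = q
        rot = np.array([
            [1 - 2 * (yq * yq + zq * zq), 2 * (xq * yq - zq * w),
             2 * (xq * zq + yq * w)],
            [2 * (xq * yq + zq * w), 1 - 2 * (xq * xq + zq * zq),
             2 * (yq * zq - xq * w)],
            [2 * (xq * zq - yq * w), 2 * (yq * zq + xq * w),
             1 - 2 * (xq * xq + yq * yq)]])
        c1 = msd_from_positions(t, x)
        c2 = msd_from_positions(t, x @ rot.T)
        assert np.allclose(c1["msd"], c2["msd"], rtol=1e-9)


class TestDerivedScalars:
    def test_hydrodynamic_radius_paper_point(self):
        assert hydrodynamic_radius(36.80) == pytest.approx(5.8, abs=0.05)

    def test_hydrodynamic_radius_inverse_proportionality(self):
        assert hydrodynamic_radius(2 * 36.80) == pytest.approx(
            hydrodynamic_radius(36.80) / 2)

    def test_hydrodynamic_radius_round_trip(self):
        from iggbd.units import stokes_diffusion
        assert hydrodynamic_radius(stokes_diffusion(5.1)) == pytest.approx(5.1)

    def test_rot_trans_parameter(self):
        assert rot_trans_parameter(36.80, 0.0) == 0.0
        k = rot_trans_parameter(36.80, 1.110)
        assert k == pytest.approx(8.1, abs=0.1)
        assert rot_trans_parameter(2 * 36.80, 2 * 1.110) == pytest.approx(k)


class TestAngles:
    def test_collinear_and_perpendicular_geometries(self):
        frame = model.igg_reference_geometry()
        psi, phi1, phi2 = igg_angles(frame)
        assert psi == pytest.approx(90.0)
        assert phi1 == pytest.approx(90.0)
        assert phi2 == pytest.approx(90.0)
        # fold both arms onto the same direction: psi -> 0
        f2 = frame.copy()
        f2[4] = f2[2]
        f2[5] = f2[3]
        assert igg_angles(f2)[0] == pytest.approx(0.0)

    def test_zero_length_axis_error(self):
        frame = model.igg_reference_geometry()
        frame[0] = frame[1]  # stem collapses onto hinge
        with pytest.raises(ValueError, match="zero-length"):
            igg_angles(frame)

    def test_angle_sample_validation(self):
        with pytest.raises(ValueError):
            AngleSample(psi=np.array([190.0]), phi=np.array([10.0]))


class TestCdfPdf:
    def test_uniform_samples(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 180, size=10_000)
        table = empirical_cdf_pdf(s)
        grid = table["angle"].to_numpy()
        assert np.abs(table["cdf"] - grid / 180.0).max() < 0.02
        assert table["cdf"].iloc[0] == pytest.approx(0.0, abs=1e-3)
        assert table["cdf"].iloc[-1] == 1.0
        assert (np.diff(table["cdf"]) >= -1e-12).all()
        assert np.trapezoid(table["pdf"], grid) == pytest.approx(1.0,
                                                                 abs=0.01)
        assert (table["pdf"] >= 0).all()

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            empirical_cdf_pdf(np.ones(10))


class TestRg:
    def test_coincident_beads(self):
        assert radius_of_gyration(np.zeros((6, 3))) == 0.0

    def test_two_beads_half_distance(self):
        frame = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert radius_of_gyration(frame) == pytest.approx(2.0)


class TestAlphaFit:
    def test_exact_synthetic_line(self):
        phi = np.array([0.0, 0.05, 0.10, 0.15])
        series = CrowdingSeries(phi_occ=phi, D_over_D0=1 - 0.5 * phi)
        assert fit_alpha(series).alpha == pytest.approx(0.5, rel=1e-12)

    def test_alpha_g_and_nonflex_composition(self):
        phi = np.array([0.0, 0.05, 0.10, 0.15])
        series = CrowdingSeries(phi_occ=phi, D_over_D0=1 - 0.71 * phi,
                                rg_mean=5.0 * (1 - 0.17 * phi))
        fit = fit_alpha(series)
        assert fit.alpha == pytest.approx(0.71, rel=1e-9)
        assert fit.alpha_g == pytest.approx(0.17, rel=1e-9)
        assert fit.alpha_nonflex == pytest.approx(0.88, rel=1e-9)

    def test_requires_dilute_point(self):
        with pytest.raises(ValueError):
            fit_alpha(CrowdingSeries(phi_occ=np.array([0.05, 0.1, 0.15]),
                                     D_over_D0=np.array([0.9, 0.8, 0.7])))


class TestCalibration:
    def test_parameter_recovery_from_boltzmann_target(self):
        grid, cdf = boltzmann_angle_cdf(95.0, 1.4)
        target = pd.DataFrame({"angle": grid, "cdf": cdf})
        theta, xi, dist = calibrate_angles(target, initial=(90.0, 1.0))
        assert theta == pytest.approx(95.0, rel=0.02)
        assert xi == pytest.approx(1.4, rel=0.02)
        assert dist < 1e-3

    def test_identical_target_distance_zero(self):
        grid, cdf = boltzmann_angle_cdf(90.0, 1.0)
        target = pd.DataFrame({"angle": grid, "cdf": cdf})
        _, _, dist = calibrate_angles(target, initial=(90.0, 1.0))
        assert dist < 1e-6

    def test_stiff_limit_approaches_step(self):
        grid, cdf = boltzmann_angle_cdf(90.0, 500.0)
        below = cdf[grid < 80].max()
        above = cdf[grid > 100].min()
        assert below < 0.01 and above > 0.99

    def test_non_monotone_target_rejected(self):
        bad = pd.DataFrame({"angle": [0.0, 90.0, 180.0],
                            "cdf": [0.0, 0.8, 0.5]})
        with pytest.raises(ValueError, match="monotone"):
            calibrate_angles(bad)


class TestHingeQuadrature:
    def test_cdf_properties_and_peak_location(self):
        q = igg_hinge_quadrature()
        for col in ("psi_cdf", "phi_cdf"):
            c = q[col].to_numpy()
            assert (np.diff(c) >= -1e-12).all()
            assert c[0] == pytest.approx(0.0, abs=1e-4)
            assert c[-1] == pytest.approx(1.0)
            pdf = np.gradient(c, q["angle"].to_numpy())
            peak = q["angle"].to_numpy()[np.argmax(pdf)]
            assert 80.0 <= peak <= 100.0
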