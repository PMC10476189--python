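"""Interaction energies, analytic forces, and their consistency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iggbd import model, potentials
from iggbd.model import AngleTerm, BondTerm, SystemConfiguration, build_igg
from iggbd.potentials import (angle_energy, bond_energy, compile_system,
                              steric_energy, total_forces, wall_energy)

SH_BOND = BondTerm(0, 1, 6.0, 1909.9)
HINGE = AngleTerm(0, 1, 2, 90.0, 1.0)


class TestScalarTerms:
    def test_bond_minimum_at_equilibrium(self):
        assert bond_energy(6.0, SH_BOND) == 0.0

    def test_bond_adopted_convention_value(self):
        # 0.5 * 1909.9 * 0.1^2
        assert bond_energy(6.1, SH_BOND) == pytest.approx(9.5495, abs=1e-4)

    @given(delta=st.floats(0.001, 3.0))
    @settings(max_examples=30, deadline=None)
    def test_bond_symmetric_about_equilibrium(self, delta):
        assert bond_energy(6.0 + delta, SH_BOND) == pytest.approx(
            bond_energy(6.0 - delta, SH_BOND), rel=1e-12)

    def test_bond_requires_positive_distance(self):
        with pytest.raises(ValueError):
            bond_energy(-1.0, SH_BOND)

    def test_angle_minimum_and_value(self):
        assert angle_energy(90.0, HINGE) == 0.0
        expected = 0.5 * (10 * math.pi / 180) ** 2
        assert angle_energy(100.0, HINGE) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.01523, abs=2e-5)

    @given(d1=st.floats(0.5, 40.0), d2=st.floats(0.5, 40.0))
    @settings(max_examples=30, deadline=None)
    def test_angle_energy_increases_away_from_minimum(self, d1, d2):
        lo, hi = sorted([d1, d2])
        assert angle_energy(90.0 + hi, HINGE) > angle_energy(90.0 + lo, HINGE) \
            or lo == hi
        assert angle_energy(90.0 - hi, HINGE) > angle_energy(90.0 - lo, HINGE) \
            or lo == hi

    def test_angle_range_validation(self):
        with pytest.raises(ValueError):
            angle_energy(190.0, HINGE)

    def test_steric_contact_and_overlap(self):
        assert steric_energy(5.0, 5.0) == 0.0
        assert steric_energy(7.0, 5.0) == 0.0
        assert steric_energy(4.9, 5.0, k_overlap=4000.0) == pytest.approx(
            20.0, rel=1e-9)

    def test_steric_exempt_pair_is_zero_at_any_separation(self):
        for r in (0.1, 1.0, 3.0):
            assert steric_energy(r, 4.84, exempt=True) == 0.0

    def test_wall_energy(self):
        assert wall_energy(2.42, 2.42) == 0.0
        assert wall_energy(7.42, 2.42) == 0.0
        assert wall_energy(2.32, 2.42, k_overlap=4000.0) == pytest.approx(
            20.0, rel=1e-9)


def _random_crowded_config(seed, with_wall=False):
    """Two IgG plus one crowder, randomly perturbed (some steric overlap)."""
    rng = np.random.default_rng(seed)
    igg = build_igg()
    fic = model.build_ficoll()
    ref = model.igg_reference_geometry(igg)
    p1 = ref + rng.normal(scale=0.4, size=ref.shape) + [20.0, 20, 15]
    p2 = ref + rng.normal(scale=0.4, size=ref.shape) + [28.0, 24, 18]
    p3 = np.array([[24.0, 22.0, 16.0]])
    wall = model.Wall(z_top=40.0) if with_wall else None
    return SystemConfiguration(
        positions=np.concatenate([p1, p2, p3]),
        molecules=[igg, igg, fic],
        mol_index=np.repeat([0, 1, 2], [6, 6, 1]),
        box=np.array([40.0, 40.0, 40.0]),
        periodic=np.array([True, True, not with_wall]), wall=wall)


class TestWholeSystem:
    def test_reference_geometry_is_force_free(self):
        igg = build_igg()
        pos = model.igg_reference_geometry(igg) + 50.0
        cfg = SystemConfiguration(
            positions=pos, molecules=[igg],
            mol_index=np.zeros(6, dtype=np.int64), box=np.full(3, 100.0),
            periodic=np.array([True] * 3))
        F, report = total_forces(cfg)
        assert np.abs(F).max() < 1e-8
        assert report.total == pytest.approx(0.0, abs=1e-12)

    def test_energy_report_total_is_component_sum(self):
        cfg = _random_crowded_config(1, with_wall=True)
        _, report = total_forces(cfg)
        assert report.total == report.bond + report.angle + report.steric \
            + report.wall

    @pytest.mark.parametrize("seed,with_wall", [(0, False), (1, True),
                                                (2, False), (3, True)])
    def test_forces_match_finite_differences(self, seed, with_wall):
        cfg = _random_crowded_config(seed, with_wall)
        arrays = compile_system(cfg)
        if with_wall:
            # exercise the tether path too
            arrays.rest_bead = np.array([3], dtype=np.int64)
            arrays.rest_pt = np.array([[20.0, 20.0, 3.5]])
            arrays.rest_req = np.array([3.42])
            arrays.rest_kap = np.array([1909.9])
        F, rep = total_forces(cfg, arrays=arrays)
        eps = 1e-6
        rng = np.random.default_rng(seed + 100)
        beads = rng.choice(cfg.n_beads, size=6, replace=False)
        for i in beads:
            for c in range(3):
                for sgn, store in ((1, "p"), (-1, "m")):
                    pert = cfg.copy()
                    pert.positions = cfg.positions.copy()
                    pert.positions[i, c] += sgn * eps
                    _, r = total_forces(pert, arrays=arrays)
                    if sgn == 1:
                        ep = r.total
                    else:
                        em = r.total
                fd = -(ep - em) / (2 * eps)
                scale = max(1.0, abs(F[i, c]))
                assert abs(fd - F[i, c]) / scale < 1e-5

    def test_translation_invariance_and_zero_net_force(self):
        cfg = _random_crowded_config(5)
        F, rep = total_forces(cfg)
        shifted = cfg.copy()
        shifted.positions = cfg.positions + np.array([1.234, -0.77, 2.5])
        F2, rep2 = total_forces(shifted)
        assert rep2.total == pytest.approx(rep.total, abs=1e-10)
        # net force vanishes (all interactions are internal pairs here)
        assert np.abs(F.sum(axis=0)).max() < 1e-9

    def test_intra_igg_overlap_exempt_from_sterics(self):
        # arm beads A1/A2 overlap in the reference geometry; squeeze the
        # whole arm so even more beads overlap: still zero steric energy
        igg = build_igg()
        pos = model.igg_reference_geometry(igg)
        pos[3] = pos[2] + 0.5  # A2 nearly on top of A1
        cfg = SystemConfiguration(
            positions=pos + 50.0, molecules=[igg],
            mol_index=np.zeros(6, dtype=np.int64), box=np.full(3, 100.0),
            periodic=np.array([True] * 3))
        F, report = total_forces(cfg)
        assert report.steric == 0.0

    def test_nonfinite_positions_raise(self):
        cfg = _random_crowded_config(6)
        with pytest.raises(ValueError, match="finite"):
            bad = cfg.copy()
            bad.positions = cfg.positions.copy()
            bad.positions[0, 0] = np.nan
            SystemConfiguration(
                positions=bad.positions, molecules=cfg.molecules,
                mol_index=cfg.mol_index, box=cfg.box, periodic=cfg.periodic)
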