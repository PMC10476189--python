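"""Topology construction, occupied volume and system packing."""

import math

import numpy as np
import pytest

from iggbd import model
from iggbd.model import (build_ficoll, build_igg, igg_reference_geometry,
                         occupied_volume, pack_system, sphere_volume)


class TestBuildIgg:
    def test_default_radii_and_counts(self):
        igg = build_igg()
        assert igg.n_beads == 6
        assert len(igg.bonds) == 5
        assert igg.labels == ["S", "H", "A1", "A2", "A1p", "A2p"]
        radii = dict(zip(igg.labels, igg.hydrodynamic_radii()))
        assert radii["S"] == pytest.approx(4.50)
        assert radii["H"] == pytest.approx(1.00)
        for arm in ("A1", "A2", "A1p", "A2p"):
            assert radii[arm] == pytest.approx(2.42)

    def test_bond_table(self):
        igg = build_igg()
        by_pair = {tuple(sorted((b.bead_i, b.bead_j))): b for b in igg.bonds}
        sh = by_pair[(0, 1)]
        assert sh.r_eq == pytest.approx(6.0)
        assert sh.kappa == pytest.approx(1909.9)
        assert by_pair[(1, 2)].r_eq == pytest.approx(3.9)
        assert by_pair[(2, 3)].r_eq == pytest.approx(3.0)
        assert all(b.kappa == pytest.approx(1909.9) for b in igg.bonds)

    def test_angle_terms_present(self):
        igg = build_igg()
        assert len(igg.angles) == 5
        apexes = [a.bead_j for a in igg.angles]
        assert apexes.count(1) == 3  # three hinge terms at H
        straight = [a for a in igg.angles if a.theta_eq == 180.0]
        assert len(straight) == 2

    def test_reference_geometry_satisfies_equilibrium(self):
        igg = build_igg()
        pos = igg_reference_geometry(igg)
        for b in igg.bonds:
            d = np.linalg.norm(pos[b.bead_i] - pos[b.bead_j])
            assert d == pytest.approx(b.r_eq, abs=1e-12)
        for a in igg.angles:
            u = pos[a.bead_i] - pos[a.bead_j]
            v = pos[a.bead_k] - pos[a.bead_j]
            c = np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v)
            theta = math.degrees(math.acos(np.clip(c, -1, 1)))
            assert theta == pytest.approx(a.theta_eq, abs=1e-9)

    def test_overrides(self):
        igg = build_igg({"radii": {"S": 5.0}})
        assert igg.beads[0].hydrodynamic_radius == 5.0
        with pytest.raises(ValueError, match="radius 'S'"):
            build_igg({"radii": {"S": -1.0}})
        with pytest.raises(ValueError, match="S-H"):
            build_igg({"bonds": {"S-H": {"r_eq": -2.0}}})
        with pytest.raises(ValueError, match="unknown"):
            build_igg({"bogus_section": {}})


class TestFicoll:
    def test_single_inert_sphere(self):
        fic = build_ficoll()
        assert fic.n_beads == 1
        assert fic.beads[0].hydrodynamic_radius == pytest.approx(5.1)
        assert fic.beads[0].hard_core_radius == pytest.approx(5.1)
        assert fic.bonds == [] and fic.angles == []

    def test_occupied_volume_is_sphere_volume(self):
        fic = build_ficoll()
        assert occupied_volume(fic) == pytest.approx(
            4.0 / 3.0 * math.pi * 5.1 ** 3, rel=1e-12)
        assert occupied_volume(fic) == pytest.approx(555.65, abs=0.01)


class TestOccupiedVolume:
    def test_disjoint_spheres_sum(self):
        topo = model.MoleculeTopology(
            [model.BeadSpec("a", 1.0, 1.0), model.BeadSpec("b", 1.0, 1.0)],
            [], [], set(), kind="crowder")
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        expected = 2 * 4.0 / 3.0 * math.pi
        assert occupied_volume(topo, pos) == pytest.approx(expected, rel=1e-3)

    def test_igg_union_below_sum_and_matches_monte_carlo(self):
        igg = build_igg()
        v_pair = occupied_volume(igg)
        v_sum = sum(sphere_volume(r) for r in igg.hard_core_radii())
        assert v_pair < v_sum  # arm beads overlap at 3.0 nm separation
        v_mc = occupied_volume(igg, method="mc", mc_points=10_000_000,
                               mc_seed=3)
        assert v_pair == pytest.approx(v_mc, rel=2e-3)

    def test_nonoverlapping_matches_analytic_sum(self):
        rng = np.random.default_rng(0)
        beads = [model.BeadSpec(f"b{i}", 1.0 + i * 0.3, 1.0 + i * 0.3)
                 for i in range(4)]
        topo = model.MoleculeTopology(beads, [], [], set(), kind="crowder")
        pos = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10.0]])
        pos = pos + rng.normal(scale=0.1, size=pos.shape)
        expected = sum(sphere_volume(b.hard_core_radius) for b in beads)
        assert occupied_volume(topo, pos) == pytest.approx(expected, rel=1e-3)

    def test_missing_positions_error(self):
        igg = build_igg()
        with pytest.raises(ValueError, match="one position per bead"):
            occupied_volume(igg, np.zeros((3, 3)))


class TestPackSystem:
    def test_single_dilute_igg(self):
        sys0 = pack_system(1, 0.0, box=[100.0] * 3, rng_seed=1)
        assert len(sys0.molecules) == 1
        assert sys0.molecules[0].kind == "IgG"

    def test_ficoll_count_from_volume_arithmetic(self):
        sys0 = pack_system(0, 0.10, box=[60.0] * 3, rng_seed=2)
        expected = int(round(0.10 * 60.0 ** 3 / sphere_volume(5.1)))
        assert len(sys0.molecules) == expected  # ~39
        assert abs(sys0.phi_occ - 0.10) <= 0.005

    def test_determinism(self):
        a = pack_system(2, 0.08, box=[60.0] * 3, rng_seed=7)
        b = pack_system(2, 0.08, box=[60.0] * 3, rng_seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_no_intermolecular_hard_core_overlaps(self):
        sys0 = pack_system(2, 0.15, box=[60.0] * 3, rng_seed=3)
        pos = sys0.positions
        radii = sys0.hard_core_radii()
        mol = sys0.mol_index
        box = sys0.box
        delta = pos[:, None, :] - pos[None, :, :]
        delta -= box * np.round(delta / box)
        d = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
        sig = radii[:, None] + radii[None, :]
        inter = mol[:, None] != mol[None, :]
        assert np.all(d[inter] >= sig[inter] - 1e-9)

    def test_phi_out_of_range(self):
        with pytest.raises(ValueError, match="phi_occ_target"):
            pack_system(1, 0.5, box=[60.0] * 3, rng_seed=1)

    def test_packing_failure_reports_achieved_fraction(self):
        with pytest.raises(model.PackingError) as exc:
            pack_system(0, 0.30, box=[14.0] * 3, rng_seed=1,
                        max_attempts_per_molecule=50)
        assert exc.value.achieved_phi < 0.30


class TestParameterFiles:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "params.yaml"
        model.write_parameters(model.DEFAULT_IGG_PARAMS, path)
        loaded = model.read_parameters(path)
        assert loaded == model.DEFAULT_IGG_PARAMS
        igg = build_igg(loaded)
        assert igg.n_beads == 6

    def test_unknown_section_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("nonsense: {x: 1}\n")
        with pytest.raises(ValueError, match="unknown parameter section"):
            model.read_parameters(path)
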