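"""Bonded, angular, steric and wall interactions: energies and forces.

Bond and angle terms are harmonic, ``U = 1/2 k (x - x_eq)^2`` (the prefactor
convention is switchable through ``bond_prefactor``; 0.5 is the default).
Steric interactions apply only between beads of *different* molecules --
beads within one IgG may overlap freely -- and are modelled as a finite
harmonic overlap repulsion, a differentiable stand-in for hard cores that is
steep enough (k_ov = 4000 kcal/mol/nm^2 by default) that thermal overlaps
stay below ~0.05 nm.  The wall at z=0 uses the same quadratic penalty below
bead-surface contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .model import AngleTerm, BondTerm, SystemConfiguration

__all__ = ["EnergyReport", "bond_energy", "angle_energy", "steric_energy",
           "wall_energy", "total_forces", "SystemArrays", "compile_system",
           "DEFAULT_K_OVERLAP"]

#: default overlap force constant, kcal mol^-1 nm^-2
DEFAULT_K_OVERLAP = 4000.0


@dataclass(frozen=True)
class EnergyReport:
    """Energy bookkeeping in kcal/mol; ``total`` is the exact component sum."""

    bond: float
    angle: float
    steric: float
    wall: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.steric + self.wall


def bond_energy(r_ij: float, term: BondTerm, bond_prefactor: float = 0.5) -> float:
    """Harmonic bond energy; minimum exactly at ``term.r_eq``."""
    if r_ij <= 0:
        raise ValueError(f"bond distance must be positive, got {r_ij}")
    dr = r_ij - term.r_eq
    return bond_prefactor * term.kappa * dr * dr


def angle_energy(theta_deg: float, term: AngleTerm,
                 bond_prefactor: float = 0.5) -> float:
    """Harmonic angle energy, evaluated in radians internally."""
    if not (0.0 <= theta_deg <= 180.0):
        raise ValueError(f"angle must be in [0, 180] degrees, got {theta_deg}")
    dth = math.radians(theta_deg) - math.radians(term.theta_eq)
    return bond_prefactor * term.xi * dth * dth


def steric_energy(r_ij: float, sigma_ij: float, exempt: bool = False,
                  k_overlap: float = DEFAULT_K_OVERLAP) -> float:
    """Finite harmonic overlap repulsion; zero at and beyond contact."""
    if r_ij <= 0:
        raise ValueError(f"distance must be positive, got {r_ij}")
    if exempt or r_ij >= sigma_ij:
        return 0.0
    ov = sigma_ij - r_ij
    return 0.5 * k_overlap * ov * ov


def wall_energy(z: float, hard_core_radius: float,
                k_overlap: float = DEFAULT_K_OVERLAP) -> float:
    """Penalty for a bead centre closer to the z=0 wall than its radius."""
    if z >= hard_core_radius:
        return 0.0
    ov = hard_core_radius - z
    return 0.5 * k_overlap * ov * ov


# ---------------------------------------------------------------------------
# whole-system evaluation
# ---------------------------------------------------------------------------

@dataclass
class SystemArrays:
    """Flat-array view of a configuration, ready for the numba kernels."""

    a_h: np.ndarray
    a_core: np.ndarray
    mol_id: np.ndarray
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_req: np.ndarray
    bond_kap: np.ndarray
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    ang_teq: np.ndarray       # radians
    ang_xi: np.ndarray
    cand_i: np.ndarray        # all inter-molecular steric pair candidates
    cand_j: np.ndarray
    cand_sig: np.ndarray
    grp_start: np.ndarray     # mobility group bead offsets
    box: np.ndarray
    periodic: np.ndarray
    wall_on: int
    wall_ztop: float
    rest_bead: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.int64))
    rest_pt: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    rest_req: np.ndarray = field(default_factory=lambda: np.zeros(0))
    rest_kap: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_beads(self) -> int:
        return self.a_h.shape[0]


def compile_system(config: SystemConfiguration,
                   hydrodynamics: str = "rpy_intra") -> SystemArrays:
    """Flatten a configuration into kernel-ready arrays.

    ``hydrodynamics`` selects the mobility coupling groups: ``"rpy_intra"``
    couples beads within each molecule, ``"free_draining"`` keeps every bead
    independent, ``"rpy_all"`` couples all beads (minimum image).
    """
    bond_i, bond_j, bond_req, bond_kap = [], [], [], []
    ang_i, ang_j, ang_k, ang_teq, ang_xi = [], [], [], [], []
    offset = 0
    for mol in config.molecules:
        for b in mol.bonds:
            bond_i.append(offset + b.bead_i)
            bond_j.append(offset + b.bead_j)
            bond_req.append(b.r_eq)
            bond_kap.append(b.kappa)
        for a in mol.angles:
            ang_i.append(offset + a.bead_i)
            ang_j.append(offset + a.bead_j)
            ang_k.append(offset + a.bead_k)
            ang_teq.append(math.radians(a.theta_eq))
            ang_xi.append(a.xi)
        offset += mol.n_beads

    a_core = config.hard_core_radii()
    n = config.n_beads
    mol_id = config.mol_index
    ci, cj, csig = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            if mol_id[i] != mol_id[j]:
                ci.append(i)
                cj.append(j)
                csig.append(a_core[i] + a_core[j])

    if hydrodynamics == "free_draining":
        grp_start = np.arange(n + 1, dtype=np.int64)
    elif hydrodynamics == "rpy_intra":
        starts = [0]
        for mol in config.molecules:
            starts.append(starts[-1] + mol.n_beads)
        grp_start = np.asarray(starts, dtype=np.int64)
    elif hydrodynamics == "rpy_all":
        grp_start = np.array([0, n], dtype=np.int64)
    else:
        raise ValueError(f"unknown hydrodynamics mode {hydrodynamics!r}")

    wall_on = 1 if config.wall is not None else 0
    wall_ztop = -1.0
    if config.wall is not None and config.wall.z_top is not None:
        wall_ztop = float(config.wall.z_top)

    return SystemArrays(
        a_h=config.hydrodynamic_radii(), a_core=a_core,
        mol_id=np.asarray(mol_id, dtype=np.int64),
        bond_i=np.asarray(bond_i, dtype=np.int64),
        bond_j=np.asarray(bond_j, dtype=np.int64),
        bond_req=np.asarray(bond_req, dtype=float),
        bond_kap=np.asarray(bond_kap, dtype=float),
        ang_i=np.asarray(ang_i, dtype=np.int64),
        ang_j=np.asarray(ang_j, dtype=np.int64),
        ang_k=np.asarray(ang_k, dtype=np.int64),
        ang_teq=np.asarray(ang_teq, dtype=float),
        ang_xi=np.asarray(ang_xi, dtype=float),
        cand_i=np.asarray(ci, dtype=np.int64),
        cand_j=np.asarray(cj, dtype=np.int64),
        cand_sig=np.asarray(csig, dtype=float),
        grp_start=grp_start,
        box=np.asarray(config.box, dtype=float),
        periodic=np.asarray(config.periodic, dtype=np.bool_),
        wall_on=wall_on, wall_ztop=wall_ztop)


def total_forces(config: SystemConfiguration,
                 arrays: Optional[SystemArrays] = None,
                 k_overlap: float = DEFAULT_K_OVERLAP,
                 bond_prefactor: float = 0.5
                 ) -> tuple[np.ndarray, EnergyReport]:
    """Forces (kcal mol^-1 nm^-1) and energy report for a configuration.

    Forces are exact negative gradients of the total energy, with
    minimum-image periodic distances for steric pairs and raw (unwrapped)
    geometry for bonded terms.
    """
    if arrays is None:
        arrays = compile_system(config)
    pos = np.ascontiguousarray(config.positions, dtype=float)
    n = pos.shape[0]
    F = np.zeros((n, 3))
    E = np.zeros(4)
    n_cand = arrays.cand_i.shape[0]
    _kernels.compute_forces(
        pos, arrays.box, arrays.periodic,
        arrays.bond_i, arrays.bond_j, arrays.bond_req, arrays.bond_kap,
        arrays.ang_i, arrays.ang_j, arrays.ang_k, arrays.ang_teq,
        arrays.ang_xi,
        arrays.cand_i, arrays.cand_j, arrays.cand_sig, n_cand,
        k_overlap, arrays.wall_on, arrays.wall_ztop, arrays.a_core,
        arrays.rest_bead, arrays.rest_pt, arrays.rest_req, arrays.rest_kap,
        bond_prefactor, F, E)
    if not np.all(np.isfinite(E)) or not np.all(np.isfinite(F)):
        bad = np.argwhere(~np.isfinite(F))
        raise FloatingPointError(
            f"non-finite energy/force (first offending bead index: "
            f"{bad[0][0] if len(bad) else 'energy only'})")
    report = EnergyReport(bond=E[0], angle=E[1], steric=E[2], wall=E[3])
    return F, report
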