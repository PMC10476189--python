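"""Coarse-grained molecule topologies and simulation-system construction.

The IgG antibody is represented by six spherical beads: a stem bead ``S``
(the Fc fragment), a small hinge bead ``H``, and two arms of two beads each
(``A1``-``A2`` and ``A1p``-``A2p``, the Fab fragments with the paratope at
the terminal bead).  Arms attach to the hinge through soft angular terms
that act like a ball-and-socket joint, which is what gives IgG its large
conformational freedom.  Beads of the same molecule are exempt from steric
repulsion (arm beads overlap by construction); beads of different molecules
interact as (soft) hard cores.

Ficoll 70 crowders are single inert spheres of radius 5.1 nm with equal
hard-core and hydrodynamic radii.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "BeadSpec", "BondTerm", "AngleTerm", "MoleculeTopology", "AntigenSite",
    "Wall", "SystemConfiguration", "build_igg", "build_ficoll",
    "igg_reference_geometry", "occupied_volume", "pack_system",
    "sphere_volume", "write_parameters", "read_parameters",
    "DEFAULT_IGG_PARAMS",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadSpec:
    """A spherical bead with separate hydrodynamic and hard-core radii (nm)."""

    label: str
    hydrodynamic_radius: float
    hard_core_radius: float

    def __post_init__(self):
        if self.hydrodynamic_radius <= 0 or self.hard_core_radius <= 0:
            raise ValueError(
                f"bead {self.label!r}: radii must be positive, got "
                f"a_H={self.hydrodynamic_radius}, a_c={self.hard_core_radius}")


@dataclass(frozen=True)
class BondTerm:
    """Harmonic bond between beads ``i`` and ``j``.

    ``r_eq`` in nm, ``kappa`` in kcal mol^-1 nm^-2.
    """

    bead_i: int
    bead_j: int
    r_eq: float
    kappa: float

    def __post_init__(self):
        if self.bead_i == self.bead_j:
            raise ValueError("bond must connect two distinct beads")
        if self.r_eq <= 0:
            raise ValueError(f"bond r_eq must be positive, got {self.r_eq}")
        if self.kappa <= 0:
            raise ValueError(f"bond kappa must be positive, got {self.kappa}")


@dataclass(frozen=True)
class AngleTerm:
    """Harmonic angle term; ``bead_j`` is the apex.

    ``theta_eq`` in degrees, ``xi`` in kcal mol^-1 rad^-2.
    """

    bead_i: int
    bead_j: int
    bead_k: int
    theta_eq: float
    xi: float

    def __post_init__(self):
        if not (0.0 < self.theta_eq <= 180.0):
            raise ValueError(f"theta_eq must be in (0, 180], got {self.theta_eq}")
        if self.xi < 0:
            raise ValueError(f"xi must be non-negative, got {self.xi}")


@dataclass
class MoleculeTopology:
    beads: list[BeadSpec]
    bonds: list[BondTerm]
    angles: list[AngleTerm]
    overlap_exempt_pairs: set[tuple[int, int]]
    kind: str  # "IgG" | "crowder"

    def __post_init__(self):
        n = len(self.beads)
        for b in self.bonds:
            if not (0 <= b.bead_i < n and 0 <= b.bead_j < n):
                raise ValueError("bond indices out of range")
        for a in self.angles:
            if not all(0 <= i < n for i in (a.bead_i, a.bead_j, a.bead_k)):
                raise ValueError("angle indices out of range")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.beads]

    def hard_core_radii(self) -> np.ndarray:
        return np.array([b.hard_core_radius for b in self.beads])

    def hydrodynamic_radii(self) -> np.ndarray:
        return np.array([b.hydrodynamic_radius for b in self.beads])


@dataclass(frozen=True)
class AntigenSite:
    """A hemispherical antigen site sitting on the wall plane z=0.

    ``position`` is the in-plane (x, y) location of the site centre; the
    centre itself lies on the plane.  The site is purely geometric: binding
    criteria measure distances to it but it exerts no force.
    """

    position: tuple[float, float]
    radius: float = 1.0

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("antigen radius must be non-negative")

    def center3(self) -> np.ndarray:
        return np.array([self.position[0], self.position[1], 0.0])


@dataclass
class Wall:
    """Repulsive plane at z=0 (and optionally a second one at z=z_top)."""

    z_top: Optional[float] = None
    antigens: list[AntigenSite] = field(default_factory=list)


@dataclass
class SystemConfiguration:
    """All bead coordinates plus the per-bead molecule bookkeeping."""

    positions: np.ndarray               # (N, 3) nm
    molecules: list[MoleculeTopology]
    mol_index: np.ndarray               # (N,) molecule id per bead
    box: np.ndarray                     # (3,) edge lengths nm
    periodic: np.ndarray                # (3,) bool
    wall: Optional[Wall] = None
    phi_occ: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.box = np.asarray(self.box, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        self.mol_index = np.asarray(self.mol_index, dtype=np.int64)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def molecule_slices(self) -> list[slice]:
        out, start = [], 0
        for mol in self.molecules:
            out.append(slice(start, start + mol.n_beads))
            start += mol.n_beads
        return out

    def hard_core_radii(self) -> np.ndarray:
        return np.concatenate([m.hard_core_radii() for m in self.molecules])

    def hydrodynamic_radii(self) -> np.ndarray:
        return np.concatenate([m.hydrodynamic_radii() for m in self.molecules])

    def copy(self) -> "SystemConfiguration":
        return SystemConfiguration(
            positions=self.positions.copy(), molecules=self.molecules,
            mol_index=self.mol_index.copy(), box=self.box.copy(),
            periodic=self.periodic.copy(), wall=self.wall, phi_occ=self.phi_occ)


# ---------------------------------------------------------------------------
# default model parameters
# ---------------------------------------------------------------------------

#: Default six-bead IgG parameters: subunit radii (nm), bonds (nm,
#: kcal/mol/nm^2) and angles (deg, kcal/mol/rad^2).  The three soft hinge
#: angles make the ball-and-socket joint; the two stiff 180-degree terms keep
#: each two-bead arm straight.
DEFAULT_IGG_PARAMS: dict = {
    "radii": {"S": 4.50, "H": 1.00, "A": 2.42},
    "bonds": {
        "S-H": {"r_eq": 6.0, "kappa": 1909.9},
        "H-A1": {"r_eq": 3.9, "kappa": 1909.9},
        "H-A1p": {"r_eq": 3.9, "kappa": 1909.9},
        "A1-A2": {"r_eq": 3.0, "kappa": 1909.9},
        "A1p-A2p": {"r_eq": 3.0, "kappa": 1909.9},
    },
    "angles": {
        "S-H-A1": {"theta_eq": 90.0, "xi": 1.0},
        "S-H-A1p": {"theta_eq": 90.0, "xi": 1.0},
        "A1-H-A1p": {"theta_eq": 90.0, "xi": 1.0},
        "H-A1-A2": {"theta_eq": 180.0, "xi": 500.0},
        "H-A1p-A2p": {"theta_eq": 180.0, "xi": 500.0},
    },
}

IGG_BEAD_LABELS = ["S", "H", "A1", "A2", "A1p", "A2p"]
_IGG_INDEX = {lab: i for i, lab in enumerate(IGG_BEAD_LABELS)}

FICOLL_RADIUS = 5.1


def _merge_overrides(base: Mapping, overrides: Optional[Mapping]) -> dict:
    if overrides is None:
        return {k: (dict(v) if isinstance(v, Mapping) else v)
                for k, v in base.items()}
    out = {}
    for key, val in base.items():
        if isinstance(val, Mapping):
            sub = dict(overrides.get(key, {}))
            merged = {}
            for k2, v2 in val.items():
                if isinstance(v2, Mapping):
                    merged[k2] = {**v2, **sub.pop(k2, {})}
                else:
                    merged[k2] = sub.pop(k2, v2)
            if sub:
                raise ValueError(f"unknown parameter override(s) in {key!r}: "
                                 f"{sorted(sub)}")
            out[key] = merged
        else:
            out[key] = overrides.get(key, val)
    unknown = set(overrides) - set(base)
    if unknown:
        raise ValueError(f"unknown parameter section(s): {sorted(unknown)}")
    return out


def build_igg(parameter_overrides: Optional[Mapping] = None) -> MoleculeTopology:
    """Construct the six-bead IgG topology.

    ``parameter_overrides`` may partially override :data:`DEFAULT_IGG_PARAMS`
    (e.g. ``{"angles": {"S-H-A1": {"xi": 2.0}}}``).  Radii and bond lengths
    must remain positive; violations raise ``ValueError`` naming the field.
    """
    p = _merge_overrides(DEFAULT_IGG_PARAMS, parameter_overrides)

    for name, r in p["radii"].items():
        if not (isinstance(r, (int, float)) and r > 0):
            raise ValueError(f"radius {name!r} must be positive, got {r}")
    arm = p["radii"]["A"]
    beads = [
        BeadSpec("S", p["radii"]["S"], p["radii"]["S"]),
        BeadSpec("H", p["radii"]["H"], p["radii"]["H"]),
        BeadSpec("A1", arm, arm), BeadSpec("A2", arm, arm),
        BeadSpec("A1p", arm, arm), BeadSpec("A2p", arm, arm),
    ]

    bonds = []
    for name, term in p["bonds"].items():
        i, j = (_IGG_INDEX[s] for s in name.split("-"))
        try:
            bonds.append(BondTerm(i, j, term["r_eq"], term["kappa"]))
        except ValueError as err:
            raise ValueError(f"bond {name!r}: {err}") from None

    angles = []
    for name, term in p["angles"].items():
        i, j, k = (_IGG_INDEX[s] for s in name.split("-"))
        try:
            angles.append(AngleTerm(i, j, k, term["theta_eq"], term["xi"]))
        except ValueError as err:
            raise ValueError(f"angle {name!r}: {err}") from None

    exempt = {(i, j) for i, j in itertools.combinations(range(6), 2)}
    return MoleculeTopology(beads, bonds, angles, exempt, kind="IgG")


def build_ficoll() -> MoleculeTopology:
    """A Ficoll 70 crowder: one inert sphere, both radii 5.1 nm."""
    bead = BeadSpec("FIC", FICOLL_RADIUS, FICOLL_RADIUS)
    return MoleculeTopology([bead], [], [], set(), kind="crowder")


def igg_reference_geometry(topology: Optional[MoleculeTopology] = None) -> np.ndarray:
    """Reference IgG coordinates satisfying every equilibrium bond length.

    Stem below the hinge along -z; arms along +x and +y, i.e. all three hinge
    angles at 90 degrees and both arms straight.  Every bonded and angular
    term evaluates to zero energy at this geometry (for the default
    equilibrium angles).
    """
    if topology is None:
        topology = build_igg()
    req = {tuple(sorted((b.bead_i, b.bead_j))): b.r_eq for b in topology.bonds}
    d_sh = req[(0, 1)]
    d_ha = req[(1, 2)]
    d_aa = req[(2, 3)]
    h = np.array([0.0, 0.0, d_sh])
    return np.array([
        [0.0, 0.0, 0.0],                      # S
        h,                                    # H
        h + [d_ha, 0.0, 0.0],                 # A1
        h + [d_ha + d_aa, 0.0, 0.0],          # A2
        h + [0.0, d_ha, 0.0],                 # A1p
        h + [0.0, d_ha + d_aa, 0.0],          # A2p
    ])


# ---------------------------------------------------------------------------
# occupied volume
# ---------------------------------------------------------------------------

def sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * math.pi * radius ** 3


def _lens_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection of two spheres at centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return sphere_volume(min(r1, r2))
    return (math.pi * (r1 + r2 - d) ** 2 *
            (d * d + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2) ** 2) / (12.0 * d))


def _mc_union_volume(centers: np.ndarray, radii: np.ndarray,
                     n_points: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_points, 3))
    inside = np.zeros(n_points, dtype=bool)
    for c, r in zip(centers, radii):
        inside |= np.einsum("ij,ij->i", pts - c, pts - c) <= r * r
    return float(np.prod(hi - lo) * inside.mean())


def occupied_volume(topology: MoleculeTopology,
                    reference_geometry: Optional[np.ndarray] = None,
                    method: str = "auto",
                    mc_points: int = 2_000_000, mc_seed: int = 0) -> float:
    """Volume (nm^3) of the union of a molecule's hard-core spheres.

    Pairwise sphere overlaps are subtracted analytically; if three spheres
    mutually overlap the pairwise inclusion-exclusion is no longer exact and
    the function falls back to seeded hit-or-miss Monte Carlo integration.
    """
    if reference_geometry is None:
        if topology.kind == "IgG":
            reference_geometry = igg_reference_geometry(topology)
        elif topology.n_beads == 1:
            reference_geometry = np.zeros((1, 3))
        else:
            raise ValueError("reference_geometry required for this topology")
    pos = np.asarray(reference_geometry, dtype=float)
    if pos.shape != (topology.n_beads, 3):
        raise ValueError(
            f"geometry must have one position per bead: expected "
            f"({topology.n_beads}, 3), got {pos.shape}")
    radii = topology.hard_core_radii()
    if method not in ("auto", "pairwise", "mc"):
        raise ValueError(f"unknown method {method!r}")
    if method == "mc":
        return _mc_union_volume(pos, radii, mc_points, mc_seed)

    overlaps = []
    for i, j in itertools.combinations(range(len(radii)), 2):
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d < radii[i] + radii[j]:
            overlaps.append((i, j))
    # triple-overlap detection: any bead in two overlapping pairs whose
    # partners also overlap each other
    partners: dict[int, set[int]] = {}
    for i, j in overlaps:
        partners.setdefault(i, set()).add(j)
        partners.setdefault(j, set()).add(i)
    for i, js in partners.items():
        for j, k in itertools.combinations(sorted(js), 2):
            if k in partners.get(j, ()):  # i-j, i-k and j-k all overlap
                if method == "pairwise":
                    raise ValueError("triple sphere overlap: pairwise "
                                     "inclusion-exclusion is not exact here")
                return _mc_union_volume(pos, radii, mc_points, mc_seed)

    total = float(sum(sphere_volume(r) for r in radii))
    for i, j in overlaps:
        d = float(np.linalg.norm(pos[i] - pos[j]))
        total -= _lens_volume(radii[i], radii[j], d)
    return total


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

class PackingError(RuntimeError):
    def __init__(self, msg: str, achieved_phi: float):
        super().__init__(msg)
        self.achieved_phi = achieved_phi


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _min_image(delta: np.ndarray, box: np.ndarray,
               periodic: np.ndarray) -> np.ndarray:
    for k in range(3):
        if periodic[k]:
            delta[..., k] -= box[k] * np.round(delta[..., k] / box[k])
    return delta


def pack_system(n_igg: int, phi_occ_target: float,
                box: Sequence[float], rng_seed: int,
                wall: Optional[Wall] = None,
                igg_topology: Optional[MoleculeTopology] = None,
                max_attempts_per_molecule: int = 20_000) -> SystemConfiguration:
    """Pack ``n_igg`` IgG molecules plus Ficoll crowders to a target phi_occ.

    Random sequential insertion with rejection: each molecule gets a uniform
    random position and orientation and is accepted if no inter-molecular
    hard-core pair overlaps (minimum-image distances).  The number of Ficoll
    spheres is chosen so the total occupied volume fraction (IgG union
    volumes plus Ficoll volumes) comes within +-0.005 of the target.

    With a ``wall``, the z direction is non-periodic and bounded by repulsive
    planes at z=0 and (if set) z=z_top; molecules are inserted clear of them.
    """
    if not (0.0 <= phi_occ_target <= 0.30):
        raise ValueError(f"phi_occ_target must be in [0, 0.30], "
                         f"got {phi_occ_target}")
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive edge lengths")
    periodic = np.array([True, True, wall is None])
    rng = np.random.default_rng(rng_seed)

    igg = igg_topology if igg_topology is not None else build_igg()
    fic = build_ficoll()
    v_box = float(np.prod(box))
    v_igg = occupied_volume(igg)
    v_fic = sphere_volume(FICOLL_RADIUS)

    n_fic = max(0, int(round((phi_occ_target * v_box - n_igg * v_igg) / v_fic)))
    phi_achieved = (n_igg * v_igg + n_fic * v_fic) / v_box
    if abs(phi_achieved - phi_occ_target) > 0.005 and phi_occ_target > 0:
        raise PackingError(
            f"cannot reach phi_occ={phi_occ_target:.3f} within +-0.005 with "
            f"whole crowders (closest: {phi_achieved:.4f})", phi_achieved)

    ref = igg_reference_geometry(igg)
    ref = ref - ref.mean(axis=0)

    placed_pos: list[np.ndarray] = []
    placed_rad: list[np.ndarray] = []
    molecules: list[MoleculeTopology] = []
    placed_volume = 0.0

    def try_insert(template: np.ndarray, radii: np.ndarray, mol) -> bool:
        span = np.ptp(template, axis=0) / 2 + radii.max()
        for _ in range(max_attempts_per_molecule):
            rot = _random_rotation(rng) if len(template) > 1 else np.eye(3)
            center = rng.uniform(0.0, 1.0, 3) * box
            if wall is not None:
                z_top = wall.z_top if wall.z_top is not None else box[2]
                # keep every bead clear of the walls
                lo = radii.max() + span[2]
                hi = z_top - radii.max() - span[2]
                if hi <= lo:
                    return False
                center[2] = rng.uniform(lo, hi)
            pos = template @ rot.T + center
            if wall is not None:
                if np.any(pos[:, 2] < radii) or (
                        wall.z_top is not None and
                        np.any(pos[:, 2] > wall.z_top - radii)):
                    continue
            ok = True
            for other_pos, other_rad in zip(placed_pos, placed_rad):
                delta = pos[:, None, :] - other_pos[None, :, :]
                delta = _min_image(delta, box, periodic)
                d2 = np.einsum("ijk,ijk->ij", delta, delta)
                sig = radii[:, None] + other_rad[None, :]
                if np.any(d2 < sig * sig):
                    ok = False
                    break
            if ok:
                placed_pos.append(pos)
                placed_rad.append(radii)
                molecules.append(mol)
                return True
        return False

    for m in range(n_igg):
        if not try_insert(ref, igg.hard_core_radii(), igg):
            raise PackingError(
                f"failed to insert IgG {m + 1}/{n_igg} "
                f"(achieved phi_occ={placed_volume / v_box:.4f})",
                placed_volume / v_box)
        placed_volume += v_igg
    for m in range(n_fic):
        if not try_insert(np.zeros((1, 3)), fic.hard_core_radii(), fic):
            raise PackingError(
                f"failed to insert Ficoll {m + 1}/{n_fic} "
                f"(achieved phi_occ={placed_volume / v_box:.4f})",
                placed_volume / v_box)
        placed_volume += v_fic

    if molecules:
        positions = np.concatenate(placed_pos, axis=0)
        mol_index = np.concatenate([
            np.full(mol.n_beads, i, dtype=np.int64)
            for i, mol in enumerate(molecules)])
    else:
        positions = np.zeros((0, 3))
        mol_index = np.zeros(0, dtype=np.int64)

    return SystemConfiguration(
        positions=positions, molecules=molecules, mol_index=mol_index,
        box=box, periodic=periodic, wall=wall,
        phi_occ=placed_volume / v_box)


# ---------------------------------------------------------------------------
# parameter file I/O (YAML mirror of the subunit-size / bond tables)
# ---------------------------------------------------------------------------

def write_parameters(params: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(params), fh, sort_keys=False)


def read_parameters(path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ValueError(f"parameter file {path} is not a mapping")
    unknown = set(loaded) - set(DEFAULT_IGG_PARAMS)
    if unknown:
        raise ValueError(f"unknown parameter section(s): {sorted(unknown)}")
    return _merge_overrides(DEFAULT_IGG_PARAMS, loaded)
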