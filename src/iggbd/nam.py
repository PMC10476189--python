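"""Association kinetics via the Northrup-Allison-McCammon (NAM) method.

The NAM estimator launches many independent BD trajectories with the two
reactants at centre separation ``l0`` and classifies each as *reactive*
(binding criterion met) or *escaping* (separation exceeded ``l_esc``).
With the reactive fraction beta and the return probability
``Omega = l0/l_esc`` (exact for free spheres), the diffusion-controlled rate
constant is

    k = 4 pi D R_eff,      R_eff = beta l0 / (1 - (1 - beta) Omega),

where D is the mutual diffusion coefficient.  For a perfectly absorbing
sphere this reduces to the Smoluchowski rate ``4 pi D R``, which serves as
the analytic validation limit of the whole pipeline.

For the IgG first binding step the criterion is geometric: a terminal arm
bead (A2 or A2') within 0.1 nm surface-to-surface distance of a
hemispherical antigen site on the wall; l0 = 30 nm and l_esc = 35 nm,
measured from the IgG geometric centre to the antigen centre.  The second
binding step tethers one arm tip to a first antigen and measures the
first-passage time of the free tip to a second antigen at in-plane
separation d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit

from . import _kernels
from .engine import SimulationParameters
from .model import (AntigenSite, SystemConfiguration, Wall, build_igg,
                    igg_reference_geometry, pack_system)
from .potentials import compile_system
from .units import kbt, viscosity_internal

__all__ = ["NamSetup", "RateEstimate", "SecondStepResult",
           "omega", "effective_radius", "rate", "wilson_interval",
           "absorbing_sphere_experiment", "first_step_experiment",
           "second_step_experiment"]

#: default reaction criterion: tip-antigen surface-to-surface distance, nm
REACTION_CUTOFF = 0.1
#: default antigen site radius, nm
ANTIGEN_RADIUS = 1.0


@dataclass(frozen=True)
class NamSetup:
    """Geometry and statistics of a NAM first-step experiment."""

    l0: float = 30.0
    l_esc: float = 35.0
    reaction_cutoff: float = REACTION_CUTOFF
    n_trajectories: int = 1000
    phi_occ: float = 0.0
    antigen_radius: float = ANTIGEN_RADIUS

    def __post_init__(self):
        if not (self.l_esc > self.l0 > 0):
            raise ValueError("require l_esc > l0 > 0")
        if self.reaction_cutoff <= 0:
            raise ValueError("reaction cutoff must be positive")
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")


@dataclass
class RateEstimate:
    beta: float
    beta_ci: tuple[float, float]       # Wilson 95% interval
    omega: float
    R_eff: float                       # nm
    k: float                           # nm^3/us
    n_trajectories: int
    n_reactive: int
    n_censored: int = 0                # budget-exhausted, counted non-reactive
    D_mutual: float = float("nan")
    ratio_to_dilute: float = float("nan")

    def r_eff_ci(self, l0: float) -> tuple[float, float]:
        return (effective_radius(self.beta_ci[0], self.omega, l0),
                effective_radius(self.beta_ci[1], self.omega, l0))


@dataclass
class SecondStepResult:
    antigen_separation: float
    binding_times: np.ndarray          # us, bound runs only
    n_runs: int
    n_censored: int
    censor_time: float
    zr_hist: np.ndarray                # normalised (z, rho) occupancy
    z_edges: np.ndarray
    rho_edges: np.ndarray

    def cdf(self, t: np.ndarray) -> np.ndarray:
        """Empirical CDF of binding times; censored runs count as unbound."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.searchsorted(np.sort(self.binding_times), t,
                               side="right") / self.n_runs


# ---------------------------------------------------------------------------
# scalar pieces
# ---------------------------------------------------------------------------

def omega(l0: float, l_esc: float) -> float:
    """Return probability from l_esc back to l0 for free spheres: l0/l_esc."""
    if not (l_esc > l0 > 0):
        raise ValueError(f"require l_esc > l0 > 0, got l0={l0}, l_esc={l_esc}")
    return l0 / l_esc


def effective_radius(beta: float, omega_: float, l0: float) -> float:
    """R_eff = beta l0 / (1 - (1 - beta) Omega); monotone increasing in beta."""
    if not (0.0 <= beta <= 1.0):
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    if not (0.0 <= omega_ < 1.0):
        raise ValueError(f"Omega must be in [0, 1), got {omega_}")
    return beta * l0 / (1.0 - (1.0 - beta) * omega_)


def rate(D_mutual: float, R_eff: float) -> float:
    """Diffusion-controlled rate k = 4 pi D R_eff, nm^3/us."""
    if D_mutual < 0 or R_eff < 0:
        raise ValueError("D and R_eff must be non-negative")
    return 4.0 * math.pi * D_mutual * R_eff


def wilson_interval(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    """Wilson 95% confidence interval for a binomial fraction."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, center - half)
    hi = 1.0 if k == n else min(1.0, center + half)
    return lo, hi


def _estimate(n_react: int, n_total: int, setup_l0: float, setup_lesc: float,
              D_mutual: float, n_censored: int = 0) -> RateEstimate:
    beta = n_react / n_total
    om = omega(setup_l0, setup_lesc)
    reff = effective_radius(beta, om, setup_l0)
    return RateEstimate(
        beta=beta, beta_ci=wilson_interval(n_react, n_total), omega=om,
        R_eff=reff, k=rate(D_mutual, reff) if np.isfinite(D_mutual) else
        float("nan"),
        n_trajectories=n_total, n_reactive=n_react, n_censored=n_censored,
        D_mutual=D_mutual)


# ---------------------------------------------------------------------------
# absorbing-sphere validation pipeline
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sphere_nam_batch(n_traj, l0, l_esc, R, D, dt_max, max_steps, seed,
                      step_frac, min_step):
    """Free tracer around a perfectly absorbing sphere; returns n_reactive.

    Adaptive timestep: the per-axis rms step is ``step_frac`` of the gap to
    the nearer boundary (absorber or escape surface), floored at
    ``min_step`` nm so boundary approaches terminate.  The residual
    first-passage discretisation bias is ~0.6*min_step of boundary
    displacement, far inside the Smoluchowski-oracle tolerance.
    """
    np.random.seed(seed)
    n_react = 0
    dt_min = min_step ** 2 / (2.0 * D)
    for _ in range(n_traj):
        # random start direction at |r| = l0
        while True:
            x = np.random.standard_normal(3)
            nrm = np.sqrt(x[0] ** 2 + x[1] ** 2 + x[2] ** 2)
            if nrm > 1e-12:
                break
        r = x * (l0 / nrm)
        for _ in range(max_steps):
            dist = np.sqrt(r[0] ** 2 + r[1] ** 2 + r[2] ** 2)
            if dist <= R:
                n_react += 1
                break
            if dist >= l_esc:
                break
            gap = min(dist - R, l_esc - dist)
            dt = (step_frac * gap) ** 2 / (2.0 * D)
            if dt > dt_max:
                dt = dt_max
            if dt < dt_min:
                dt = dt_min
            sd = np.sqrt(2.0 * D * dt)
            r[0] += sd * np.random.standard_normal()
            r[1] += sd * np.random.standard_normal()
            r[2] += sd * np.random.standard_normal()
    return n_react


def absorbing_sphere_experiment(R: float, D: float, l0: float = 30.0,
                                l_esc: float = 35.0, n_trajectories: int = 5000,
                                seed: int = 0, dt_max: float = 1e-2,
                                max_steps: int = 10_000_000,
                                step_frac: float = 0.1,
                                min_step: float = 0.02) -> RateEstimate:
    """Full NAM pipeline for a free tracer and an absorbing sphere.

    The resulting ``k`` should match the Smoluchowski rate ``4 pi D R``;
    this is the analytic guard on the reconstructed NAM formulas.
    """
    n_react = _sphere_nam_batch(n_trajectories, l0, l_esc, R, D, dt_max,
                                max_steps, int(seed) & 0x7FFFFFFF, step_frac,
                                min_step)
    return _estimate(n_react, n_trajectories, l0, l_esc, D_mutual=D)


# ---------------------------------------------------------------------------
# IgG first binding step
# ---------------------------------------------------------------------------

def _default_box(setup: NamSetup) -> np.ndarray:
    side = 2.0 * (setup.l_esc + 10.0)
    return np.array([side, side, setup.l_esc + 25.0])


def _launch_igg(rng: np.random.Generator, antigen: np.ndarray, l0: float,
                ref: np.ndarray, radii: np.ndarray, z_top: float
                ) -> np.ndarray:
    """IgG at centre distance l0 from the antigen, random orientation,
    every bead clear of the walls."""
    from .model import _random_rotation
    for _ in range(10_000):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        u[2] = abs(u[2])  # upper hemisphere
        center = antigen + l0 * u
        rot = _random_rotation(rng)
        pos = (ref - ref.mean(axis=0)) @ rot.T + center
        if np.all(pos[:, 2] > radii) and np.all(pos[:, 2] < z_top - radii):
            return pos
    raise RuntimeError("could not place IgG above the wall at l0")


def _crowded_wall_system(setup: NamSetup, box: np.ndarray, igg_pos: np.ndarray,
                         antigens: list[AntigenSite], seed: int,
                         igg_topology) -> SystemConfiguration:
    """IgG at its launch position plus freshly packed crowders."""
    wall = Wall(z_top=float(box[2]), antigens=antigens)
    base = pack_system(0, setup.phi_occ, box, rng_seed=seed, wall=wall) \
        if setup.phi_occ > 0 else None
    molecules = [igg_topology]
    positions = [igg_pos]
    if base is not None:
        # drop crowders overlapping the launched IgG
        radii = igg_topology.hard_core_radii()
        keep_pos, keep_mols = [], []
        for sl, mol in zip(base.molecule_slices(), base.molecules):
            p = base.positions[sl]
            delta = p[:, None, :] - igg_pos[None, :, :]
            for k in range(2):  # x, y periodic
                delta[..., k] -= box[k] * np.round(delta[..., k] / box[k])
            d2 = np.einsum("ijk,ijk->ij", delta, delta)
            sig = mol.hard_core_radii()[:, None] + radii[None, :]
            if np.all(d2 > sig * sig):
                keep_pos.append(p)
                keep_mols.append(mol)
        molecules += keep_mols
        positions += keep_pos
    mol_index = np.concatenate([np.full(m.n_beads, i, dtype=np.int64)
                                for i, m in enumerate(molecules)])
    phi = sum(float((4 / 3) * math.pi * (r ** 3)) for m in molecules[1:]
              for r in m.hard_core_radii()) / float(np.prod(box))
    return SystemConfiguration(
        positions=np.concatenate(positions, axis=0), molecules=molecules,
        mol_index=mol_index, box=box,
        periodic=np.array([True, True, False]), wall=wall,
        phi_occ=setup.phi_occ if setup.phi_occ > 0 else 0.0)


def _run_nam_trajectory(config: SystemConfiguration,
                        params: SimulationParameters,
                        tip_beads: np.ndarray, target: np.ndarray,
                        react_dist: float, center_beads: np.ndarray,
                        esc_center: np.ndarray, esc_dist: float,
                        max_steps: int, seed: int,
                        burn_in_steps: int = 0,
                        restraints: Optional[tuple] = None,
                        record_bead: int = -1,
                        record_origin: Optional[np.ndarray] = None,
                        record_every: int = 0,
                        record_cap: int = 0):
    arrays = compile_system(config, hydrodynamics=params.hydrodynamics)
    if restraints is not None:
        (arrays.rest_bead, arrays.rest_pt,
         arrays.rest_req, arrays.rest_kap) = restraints
    pos = np.ascontiguousarray(config.positions, dtype=float).copy()
    kt6pe = params.kbt / (6.0 * np.pi * viscosity_internal(params.viscosity))
    frozen = np.zeros(arrays.n_beads, dtype=np.uint8)

    common = dict(
        dt=params.dt, kbt=params.kbt, box=arrays.box,
        periodic=arrays.periodic,
        bond_i=arrays.bond_i, bond_j=arrays.bond_j,
        bond_req=arrays.bond_req, bond_kap=arrays.bond_kap,
        ang_i=arrays.ang_i, ang_j=arrays.ang_j, ang_k=arrays.ang_k,
        ang_teq=arrays.ang_teq, ang_xi=arrays.ang_xi,
        cand_i=arrays.cand_i, cand_j=arrays.cand_j,
        cand_sig=arrays.cand_sig, skin=params.neighbour_skin,
        k_ov=params.k_overlap, wall_on=arrays.wall_on,
        wall_ztop=arrays.wall_ztop, a_core=arrays.a_core,
        rest_bead=arrays.rest_bead, rest_pt=arrays.rest_pt,
        rest_req=arrays.rest_req, rest_kap=arrays.rest_kap,
        bond_pref=params.bond_prefactor,
        a_h=arrays.a_h, grp_start=arrays.grp_start,
        use_min_image=params.hydrodynamics == "rpy_all", kt6pe=kt6pe,
        mob_stride=params.mobility_stride,
        stab_limit=0.5 * float(arrays.a_core.min()))

    if burn_in_steps > 0 and config.molecules[0].kind == "IgG":
        # equilibrate crowders with the IgG held fixed
        frz = frozen.copy()
        frz[:config.molecules[0].n_beads] = 1
        scratch = np.empty((1, arrays.n_beads, 3))
        e_scratch = np.empty((1, 4))
        _kernels.run_bd(pos, n_steps=burn_in_steps, sample_every=burn_in_steps + 1,
                        samples=scratch, energies_out=e_scratch,
                        frozen=frz, seed=(seed + 0x3A9) & 0x7FFFFFFF, **common)

    rec = np.empty((max(record_cap, 1), 2))
    status, steps, n_rec = _kernels.run_nam(
        pos, n_steps=max_steps, frozen=frozen,
        center_beads=center_beads, tip_beads=tip_beads,
        target_pos=target, react_dist=react_dist,
        esc_center_pos=esc_center, esc_dist=esc_dist,
        record_bead=record_bead,
        record_origin=record_origin if record_origin is not None
        else np.zeros(3),
        record_every=record_every, record_zr=rec,
        seed=seed & 0x7FFFFFFF, **common)
    return status, steps, rec[:n_rec]


def first_step_experiment(setup: NamSetup, seed: int,
                          params: Optional[SimulationParameters] = None,
                          box: Optional[Sequence[float]] = None,
                          D_mutual: float = float("nan"),
                          dilute_reference: Optional[RateEstimate] = None,
                          max_steps: int = 100_000_000,
                          crowder_burn_in: float = 0.02) -> RateEstimate:
    """NAM estimate of the first IgG-antigen binding step.

    Each of the ``setup.n_trajectories`` runs starts a freshly oriented IgG
    with its geometric centre at distance ``l0`` from a wall antigen, with
    crowders re-packed and re-equilibrated per run; a run is reactive when
    an arm tip comes within the reaction cutoff (surface-to-surface) of the
    antigen, and escaping when the centre-antigen distance exceeds
    ``l_esc``.  Budget-exhausted runs are counted as non-reactive and
    reported through ``n_censored``.

    ``D_mutual`` (the IgG translational D at this phi_occ; the antigen is
    immobile) is required for an absolute k; ``ratio_to_dilute`` is filled
    when a dilute reference estimate is supplied.
    """
    if params is None:
        params = SimulationParameters()
    box = np.asarray(box, dtype=float) if box is not None \
        else _default_box(setup)
    igg = build_igg()
    ref = igg_reference_geometry(igg)
    radii = igg.hard_core_radii()
    antigen = np.array([box[0] / 2.0, box[1] / 2.0, 0.0])
    site = AntigenSite((antigen[0], antigen[1]), setup.antigen_radius)
    tip_radius = igg.beads[3].hard_core_radius
    react_dist = tip_radius + setup.antigen_radius + setup.reaction_cutoff
    rng = np.random.default_rng(seed)
    burn_steps = int(round(crowder_burn_in / params.dt)) \
        if setup.phi_occ > 0 else 0

    n_react = 0
    n_censored = 0
    for t in range(setup.n_trajectories):
        traj_seed = int(rng.integers(0, 2 ** 31 - 1))
        igg_pos = _launch_igg(rng, antigen, setup.l0, ref, radii,
                              z_top=float(box[2]))
        config = _crowded_wall_system(setup, box, igg_pos, [site],
                                      seed=traj_seed ^ 0x55AA, igg_topology=igg)
        status, _, _ = _run_nam_trajectory(
            config, params, tip_beads=np.array([3, 5], dtype=np.int64),
            target=antigen, react_dist=react_dist,
            center_beads=np.arange(6, dtype=np.int64),
            esc_center=antigen, esc_dist=setup.l_esc,
            max_steps=max_steps, seed=traj_seed, burn_in_steps=burn_steps)
        if status == _kernels.STATUS_REACTED:
            n_react += 1
        elif status == _kernels.STATUS_OK:
            n_censored += 1  # budget exhausted -> counted non-reactive
        elif status == _kernels.STATUS_UNSTABLE:
            raise RuntimeError(f"instability in NAM trajectory {t}")

    est = _estimate(n_react, setup.n_trajectories, setup.l0, setup.l_esc,
                    D_mutual=D_mutual, n_censored=n_censored)
    if dilute_reference is not None and np.isfinite(est.k) \
            and np.isfinite(dilute_reference.k) and dilute_reference.k > 0:
        est.ratio_to_dilute = est.k / dilute_reference.k
    elif dilute_reference is est:
        est.ratio_to_dilute = 1.0
    return est


# ---------------------------------------------------------------------------
# IgG second binding step
# ---------------------------------------------------------------------------

def _tethered_igg_geometry(anchor: np.ndarray, contact: float) -> np.ndarray:
    """IgG bound by arm 1: A2 at tether contact above antigen 1, arm
    vertical, stem along +x, free arm along +y."""
    a2 = anchor + np.array([0.0, 0.0, contact])
    a1 = a2 + [0.0, 0.0, 3.0]
    h = a1 + [0.0, 0.0, 3.9]
    return np.array([
        h + [6.0, 0.0, 0.0],   # S
        h,
        a1, a2,
        h + [0.0, 3.9, 0.0],   # A1p
        h + [0.0, 6.9, 0.0],   # A2p
    ])


def second_step_experiment(d: float, phi_occ: float, n_runs: int, seed: int,
                           params: Optional[SimulationParameters] = None,
                           box: Optional[Sequence[float]] = None,
                           censor_time: float = 5.0,
                           antigen_radius: float = ANTIGEN_RADIUS,
                           reaction_cutoff: float = REACTION_CUTOFF,
                           record_interval: float = 2e-4,
                           crowder_burn_in: float = 0.02,
                           tether_kappa: float = 1909.9) -> SecondStepResult:
    """First-passage statistics of the second binding step.

    An IgG is tethered by one arm tip to antigen 1 (stiff harmonic bond at
    the contact distance, preserving the ball-and-socket flexibility); the
    run ends when the free arm tip meets the binding criterion at antigen 2,
    a distance ``d`` away on the surface.  Runs longer than ``censor_time``
    are right-censored.  The (z, rho) occupancy of the free tip relative to
    antigen 1 is accumulated over all pre-binding samples.
    """
    if d <= 0:
        raise ValueError("antigen separation must be positive")
    if params is None:
        params = SimulationParameters()
    setup = NamSetup(phi_occ=phi_occ, n_trajectories=n_runs,
                     antigen_radius=antigen_radius,
                     reaction_cutoff=reaction_cutoff)
    if box is None:
        box = np.array([70.0, 70.0, 50.0])
    box = np.asarray(box, dtype=float)
    igg = build_igg()
    tip_radius = igg.beads[3].hard_core_radius
    contact = tip_radius + antigen_radius
    react_dist = contact + reaction_cutoff
    ag1 = np.array([box[0] / 2.0 - d / 2.0, box[1] / 2.0, 0.0])
    ag2 = ag1 + np.array([d, 0.0, 0.0])
    sites = [AntigenSite((ag1[0], ag1[1]), antigen_radius),
             AntigenSite((ag2[0], ag2[1]), antigen_radius)]
    rng = np.random.default_rng(seed)
    max_steps = int(round(censor_time / params.dt))
    record_every = max(1, int(round(record_interval / params.dt)))
    burn_steps = int(round(crowder_burn_in / params.dt)) if phi_occ > 0 else 0

    z_edges = np.linspace(0.0, 24.0, 49)
    rho_edges = np.linspace(0.0, 24.0, 49)
    hist = np.zeros((len(z_edges) - 1, len(rho_edges) - 1))
    times = []
    n_censored = 0
    for t in range(n_runs):
        traj_seed = int(rng.integers(0, 2 ** 31 - 1))
        igg_pos = _tethered_igg_geometry(ag1, contact)
        config = _crowded_wall_system(setup, box, igg_pos, sites,
                                      seed=traj_seed ^ 0x2C7, igg_topology=igg)
        tether = (np.array([3], dtype=np.int64),
                  np.ascontiguousarray(ag1[None, :]),
                  np.array([contact]), np.array([tether_kappa]))
        status, steps, rec = _run_nam_trajectory(
            config, params,
            tip_beads=np.array([5], dtype=np.int64), target=ag2,
            react_dist=react_dist,
            center_beads=np.arange(6, dtype=np.int64),
            esc_center=np.zeros(3), esc_dist=-1.0,
            max_steps=max_steps, seed=traj_seed,
            burn_in_steps=burn_steps, restraints=tether,
            record_bead=5, record_origin=ag1,
            record_every=record_every,
            record_cap=max_steps // record_every + 2)
        if status == _kernels.STATUS_REACTED:
            times.append(steps * params.dt)
        elif status == _kernels.STATUS_OK:
            n_censored += 1
        else:
            raise RuntimeError(f"instability in second-step run {t}")
        if len(rec):
            h, _, _ = np.histogram2d(rec[:, 0], rec[:, 1],
                                     bins=(z_edges, rho_edges))
            hist += h

    total = hist.sum()
    if total > 0:
        dz = np.diff(z_edges)[0]
        drho = np.diff(rho_edges)[0]
        hist = hist / (total * dz * drho)
    return SecondStepResult(
        antigen_separation=d, binding_times=np.asarray(times),
        n_runs=n_runs, n_censored=n_censored, censor_time=censor_time,
        zr_hist=hist, z_edges=z_edges, rho_edges=rho_edges)
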