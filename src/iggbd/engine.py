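"""Overdamped Brownian-dynamics propagation (Ermak-McCammon scheme).

Per step each bead moves by ``(D F) dt / k_B T`` plus correlated Gaussian
noise of covariance ``2 D dt``, where D is the (configuration-dependent)
RPY diffusion matrix.  Positions are integrated unwrapped; periodicity
enters through minimum-image convention in the non-bonded interactions, so
wrapped coordinates are a pure view of the trajectory.

:func:`step` is a plain-numpy reference implementation of a single update,
convenient for unit tests; :func:`run` drives the compiled kernel for
production trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .hydrodynamics import correlated_noise, mobility_matrix
from .model import SystemConfiguration
from .potentials import (DEFAULT_K_OVERLAP, SystemArrays, compile_system,
                         total_forces)
from .units import kbt

__all__ = ["SimulationParameters", "Schedule", "Trajectory", "StabilityError",
           "step", "run", "bond_relaxation_time"]

logger = logging.getLogger(__name__)


class StabilityError(RuntimeError):
    """Raised when a step moves a bead too far for the overdamped scheme."""


@dataclass(frozen=True)
class SimulationParameters:
    """Physical and numerical settings of a BD run.

    ``dt`` defaults to 2e-7 us (0.2 ps), about one fifth of the relaxation
    time of the stiffest bead-bond combination of the default IgG model;
    :func:`run` refuses timesteps above that threshold unless
    ``allow_large_dt`` is set.
    """

    temperature: float = 293.15          # K
    viscosity: float = 1.002             # mPa s
    dt: float = 2.0e-7                   # us
    hydrodynamics: str = "rpy_intra"     # rpy_intra | free_draining | rpy_all
    mobility_stride: int = 1             # steps between mobility refreshes
    k_overlap: float = DEFAULT_K_OVERLAP
    bond_prefactor: float = 0.5
    neighbour_skin: float = 0.8          # nm
    allow_large_dt: bool = False

    @property
    def kbt(self) -> float:
        return kbt(self.temperature)


@dataclass(frozen=True)
class Schedule:
    """Run lengths in us; samples are spaced ``sample_interval`` apart."""

    burn_in: float = 0.0
    production: float = 1.0
    sample_interval: float = 0.002


@dataclass
class Trajectory:
    """Sampled BD trajectory (unwrapped coordinates)."""

    times: np.ndarray                    # (n_frames,) us
    positions: np.ndarray                # (n_frames, N, 3) nm, unwrapped
    config: SystemConfiguration          # final-state configuration template
    params: SimulationParameters
    seed: int
    energies: Optional[np.ndarray] = None  # (n_frames, 4)
    phi_occ: float = 0.0

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def wrapped_positions(self) -> np.ndarray:
        """Positions folded into the primary box along periodic directions."""
        pos = self.positions.copy()
        box = self.config.box
        for k in range(3):
            if self.config.periodic[k]:
                pos[..., k] -= box[k] * np.floor(pos[..., k] / box[k])
        return pos

    def molecule_centers(self, kind: Optional[str] = None) -> np.ndarray:
        """Geometric centres per frame, (n_frames, n_molecules, 3).

        ``kind`` filters molecules ("IgG" or "crowder").
        """
        slices = self.config.molecule_slices()
        cols = [s for s, m in zip(slices, self.config.molecules)
                if kind is None or m.kind == kind]
        if not cols:
            raise ValueError(f"no molecules of kind {kind!r}")
        return np.stack([self.positions[:, s].mean(axis=1) for s in cols],
                        axis=1)


def bond_relaxation_time(arrays: SystemArrays,
                         params: SimulationParameters) -> float:
    """Smallest bond relaxation time  tau = k_B T / (D_bead * k_eff)  in us."""
    from .units import viscosity_internal
    kt6pe = params.kbt / (6.0 * np.pi * viscosity_internal(params.viscosity))
    tau = np.inf
    kaps = list(zip(arrays.bond_i, arrays.bond_j, arrays.bond_kap))
    kaps += [(b, b, k) for b, k in zip(arrays.rest_bead, arrays.rest_kap)]
    for i, j, kap in kaps:
        d = kt6pe / min(arrays.a_h[i], arrays.a_h[j])
        k_eff = 2.0 * params.bond_prefactor * kap
        tau = min(tau, params.kbt / (d * k_eff))
    return tau


def _stability_limit(arrays: SystemArrays) -> float:
    return 0.5 * float(arrays.a_core.min()) if arrays.n_beads else np.inf


def step(config: SystemConfiguration, params: SimulationParameters,
         rng: Optional[np.random.Generator] = None,
         noise: Optional[np.ndarray] = None,
         arrays: Optional[SystemArrays] = None) -> SystemConfiguration:
    """One Ermak-McCammon update (reference implementation, pure numpy).

    ``noise`` may be supplied explicitly (e.g. zeros to disable the random
    part for drift checks); otherwise it is drawn from ``rng``.
    """
    if arrays is None:
        arrays = compile_system(config, hydrodynamics=params.hydrodynamics)
    M = mobility_matrix(config, mode=params.hydrodynamics,
                        eta_mpas=params.viscosity,
                        temperature=params.temperature, arrays=arrays)
    F, _ = total_forces(config, arrays=arrays, k_overlap=params.k_overlap,
                        bond_prefactor=params.bond_prefactor)
    drift = (M.matrix @ F.ravel()).reshape(-1, 3) * params.dt / params.kbt
    if noise is None:
        if rng is None:
            raise ValueError("either rng or noise must be given")
        noise = correlated_noise(M, params.dt, rng)
    disp = drift + noise
    max_disp = float(np.linalg.norm(disp, axis=1).max())
    if max_disp > _stability_limit(arrays):
        raise StabilityError(
            f"bead displacement {max_disp:.3g} nm exceeds half the smallest "
            f"hard-core radius; reduce dt (currently {params.dt:g} us)")
    new = config.copy()
    new.positions = config.positions + disp
    return new


def run(config: SystemConfiguration, params: SimulationParameters,
        schedule: Schedule, seed: int,
        frozen: Optional[np.ndarray] = None) -> Trajectory:
    """Propagate a system and return the sampled trajectory.

    Burn-in steps are discarded; production frames are sampled every
    ``schedule.sample_interval``.  The initial (post burn-in) configuration
    is frame 0.  Identical inputs and seed give bit-identical trajectories.
    """
    arrays = compile_system(config, hydrodynamics=params.hydrodynamics)
    tau = bond_relaxation_time(arrays, params)
    if params.dt > tau / 5.0 and not params.allow_large_dt:
        raise StabilityError(
            f"dt={params.dt:g} us exceeds one fifth of the stiffest bond "
            f"relaxation time ({tau:.3g} us); reduce dt or set allow_large_dt")

    pos = np.ascontiguousarray(config.positions, dtype=float).copy()
    if frozen is None:
        frozen = np.zeros(arrays.n_beads, dtype=np.uint8)
    else:
        frozen = np.asarray(frozen, dtype=np.uint8)
    from .units import viscosity_internal
    kt6pe = params.kbt / (6.0 * np.pi * viscosity_internal(params.viscosity))
    use_min_image = params.hydrodynamics == "rpy_all"
    seed = int(seed) & 0x7FFFFFFF

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
        use_min_image=use_min_image, kt6pe=kt6pe,
        mob_stride=params.mobility_stride, frozen=frozen,
        stab_limit=_stability_limit(arrays))

    n_burn = int(round(schedule.burn_in / params.dt))
    if n_burn > 0:
        logger.info("burn-in: %d steps (%.3g us)", n_burn, schedule.burn_in)
        scratch = np.empty((1, arrays.n_beads, 3))
        e_scratch = np.empty((1, 4))
        status, at = _kernels.run_bd(
            pos, n_steps=n_burn, sample_every=n_burn + 1, samples=scratch,
            energies_out=e_scratch, seed=(seed + 0x5D1) & 0x7FFFFFFF,
            **common)
        if status == _kernels.STATUS_UNSTABLE:
            raise StabilityError(
                f"instability during burn-in at step {at} "
                f"(t={at * params.dt:.4g} us); reduce dt")

    n_steps = int(round(schedule.production / params.dt))
    sample_every = max(1, int(round(schedule.sample_interval / params.dt)))
    n_frames = n_steps // sample_every + 1
    samples = np.empty((n_frames, arrays.n_beads, 3))
    energies = np.zeros((n_frames, 4))
    logger.info("production: %d steps, %d frames", n_steps, n_frames)
    status, at = _kernels.run_bd(
        pos, n_steps=n_steps, sample_every=sample_every, samples=samples,
        energies_out=energies, seed=seed, **common)
    if status == _kernels.STATUS_UNSTABLE:
        raise StabilityError(
            f"instability at step {at} (t={at * params.dt:.4g} us); "
            f"diagnostic frame retained in the exception")

    times = np.arange(n_frames) * sample_every * params.dt
    final = config.copy()
    final.positions = pos
    return Trajectory(times=times, positions=samples, config=final,
                      params=params, seed=seed, energies=energies,
                      phi_occ=config.phi_occ)
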