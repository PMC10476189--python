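"""High-level experiment pipelines shared by the CLI, tests and scripts.

These functions wire the model, engine and analysis modules together for
the study's standard numerical experiments:

* dilute single-IgG runs -> D0, D_r0, a_H, rotation parameter,
* occupied-volume-fraction sweeps -> D/D0 and R_g series with alpha fits,
* NAM first/second binding-step experiments.

All randomness flows from explicit integer seeds; per-run seeds are drawn
from a seeded generator so a pipeline is reproducible end to end.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis
from .engine import Schedule, SimulationParameters, Trajectory, run
from .model import (FICOLL_RADIUS, SystemConfiguration, build_igg,
                    igg_reference_geometry, pack_system)
from .units import stokes_diffusion

__all__ = ["dilute_igg_trajectories", "dilute_summary", "crowding_sweep"]


def _dilute_igg_system(box_edge: float = 100.0, n_igg: int = 1,
                       rng_seed: int = 0) -> SystemConfiguration:
    if n_igg == 1:
        igg = build_igg()
        pos = igg_reference_geometry(igg)
        pos = pos - pos.mean(axis=0) + box_edge / 2.0
        return SystemConfiguration(
            positions=pos, molecules=[igg],
            mol_index=np.zeros(6, dtype=np.int64),
            box=np.full(3, box_edge), periodic=np.array([True, True, True]))
    return pack_system(n_igg, 0.0, box=np.full(3, box_edge),
                       rng_seed=rng_seed)


def dilute_igg_trajectories(n_seeds: int = 2, production: float = 4.0,
                            burn_in: float = 0.2, seed: int = 1,
                            params: Optional[SimulationParameters] = None,
                            sample_interval: float = 0.002,
                            n_igg: int = 8, box_edge: float = 250.0
                            ) -> list[Trajectory]:
    """Independent dilute IgG runs with intra-molecule RPY coupling.

    Several well-separated copies share each box (inter-molecule coupling is
    off in ``rpy_intra`` mode and encounters are vanishingly rare at the
    default density), which amortises per-step overheads: the effective
    sampling is ``n_seeds * n_igg * production``.
    """
    if params is None:
        params = SimulationParameters()
    sched = Schedule(burn_in=burn_in, production=production,
                     sample_interval=sample_interval)
    trajs = []
    for s in range(n_seeds):
        system = _dilute_igg_system(box_edge, n_igg,
                                    rng_seed=(seed * 31 + s) & 0x7FFFFFFF)
        trajs.append(run(system, params, sched,
                         seed=(seed * 7919 + s * 104729) & 0x7FFFFFFF))
    return trajs


def dilute_summary(trajectories: Sequence[Trajectory],
                   msd_window: tuple[float, float] = (0.5, 1.5),
                   acf_window: tuple[float, float] = (0.1, 0.8)) -> dict:
    """D0, D_r0, a_H and the rotation-per-distance parameter with errors."""
    d_est = analysis.estimate_diffusion(list(trajectories), species="IgG",
                                        window=msd_window)
    r_est = analysis.estimate_rotational(list(trajectories), window=acf_window)
    t = trajectories[0].params.temperature
    eta = trajectories[0].params.viscosity
    a_h = analysis.hydrodynamic_radius(d_est.D, t, eta)
    return {
        "D0": d_est.D, "D0_se": d_est.D_se,
        "Dr0": r_est.D_r, "Dr0_se": r_est.D_r_se,
        "a_H": a_h,
        "a_H_se": a_h * d_est.D_se / d_est.D,
        "rot_trans_deg_per_nm": analysis.rot_trans_parameter(d_est.D,
                                                             r_est.D_r),
        "total_sampling_us": float(sum(
            t.times[-1] - t.times[0] for t in trajectories)),
    }


def crowding_sweep(phi_values: Sequence[float], n_igg: int = 8,
                   box_edge: float = 60.0, production: float = 15.0,
                   burn_in: float = 0.5, seed: int = 1,
                   params: Optional[SimulationParameters] = None,
                   msd_window: tuple[float, float] = (0.3, 2.0),
                   dilute_reference: Optional[dict] = None
                   ) -> dict:
    """D(phi_occ)/D0 and R_g(phi_occ) for IgG and Ficoll, plus alpha fits.

    ``phi_values`` must include 0 (the dilute reference point).  The IgG
    dilute reference D0 is measured from the phi=0 run (same box, same HI
    mode) unless supplied via ``dilute_reference``; the Ficoll dilute
    reference is its exact Stokes value (a single inert bead has no other
    dilute limit).

    Returns a dict with a tidy per-phi DataFrame and the fitted
    sensitivities alpha_IgG, alpha_Ficoll, alpha_g.
    """
    if params is None:
        params = SimulationParameters(mobility_stride=10)
    phi_values = sorted(float(p) for p in phi_values)
    if not math.isclose(phi_values[0], 0.0, abs_tol=1e-12):
        raise ValueError("phi_values must include the dilute point 0")
    sched = Schedule(burn_in=burn_in, production=production,
                     sample_interval=0.002)
    d0_ficoll = stokes_diffusion(FICOLL_RADIUS, params.temperature,
                                 params.viscosity)

    rows = []
    rng = np.random.default_rng(seed)
    for phi in phi_values:
        pack_seed = int(rng.integers(0, 2 ** 31 - 1))
        run_seed = int(rng.integers(0, 2 ** 31 - 1))
        system = pack_system(n_igg, phi, box=np.full(3, box_edge),
                             rng_seed=pack_seed)
        traj = run(system, params, sched, seed=run_seed)
        d_igg = analysis.estimate_diffusion(traj, species="IgG",
                                            window=msd_window)
        has_fic = any(m.kind == "crowder" for m in system.molecules)
        d_fic = analysis.estimate_diffusion(traj, species="crowder",
                                            window=msd_window) if has_fic \
            else None
        rg_mean, rg_sd, _ = analysis.rg_distribution(traj)
        rows.append({
            "phi_occ": system.phi_occ if phi > 0 else 0.0,
            "phi_target": phi,
            "D_igg": d_igg.D, "D_igg_se": d_igg.D_se,
            "D_ficoll": d_fic.D if d_fic else float("nan"),
            "D_ficoll_se": d_fic.D_se if d_fic else float("nan"),
            "rg_mean": rg_mean, "rg_sd": rg_sd,
        })
    table = pd.DataFrame(rows)

    if dilute_reference is not None and "D0" in dilute_reference:
        d0_igg = float(dilute_reference["D0"])
    else:
        d0_igg = float(table.loc[table.phi_target == 0.0, "D_igg"].iloc[0])
    table["D_igg_ratio"] = table["D_igg"] / d0_igg
    table["D_ficoll_ratio"] = table["D_ficoll"] / d0_ficoll

    igg_series = analysis.CrowdingSeries(
        phi_occ=table["phi_target"].to_numpy(),
        D_over_D0=np.clip(table["D_igg_ratio"].to_numpy(), 1e-6, 1.05),
        rg_mean=table["rg_mean"].to_numpy())
    alpha_igg = analysis.fit_alpha(igg_series)

    fic_rows = table[np.isfinite(table["D_ficoll_ratio"])
                     | (table.phi_target == 0.0)]
    fic_ratio = fic_rows["D_ficoll_ratio"].to_numpy().copy()
    fic_ratio[fic_rows.phi_target.to_numpy() == 0.0] = 1.0
    alpha_fic = analysis.fit_alpha(analysis.CrowdingSeries(
        phi_occ=fic_rows["phi_target"].to_numpy(),
        D_over_D0=np.clip(fic_ratio, 1e-6, 1.05)))

    return {
        "table": table,
        "D0_igg": d0_igg,
        "D0_ficoll": d0_ficoll,
        "alpha_igg": alpha_igg.alpha,
        "alpha_ficoll": alpha_fic.alpha,
        "alpha_g": alpha_igg.alpha_g,
        "alpha_igg_nonflex": alpha_igg.alpha_nonflex,
    }
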