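"""Run configuration, trajectory/structure file I/O and fixture systems.

Configs are YAML with a strict schema (unknown keys are rejected -- silent
typos are the classic failure mode of simulation configs).  Structures and
trajectories go through MDAnalysis writers: XYZ and PDB for humans and
quick-look tools, DCD for long trajectories.  Every run directory gets a
plain-text manifest tying outputs to the config hash, seed and package
versions.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import Schedule, SimulationParameters, Trajectory
from .model import FICOLL_RADIUS, SystemConfiguration, sphere_volume
from .units import stokes_diffusion

__all__ = ["RunConfig", "load_config", "save_config", "write_trajectory",
           "read_structure", "write_manifest", "generate_fixture"]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class _SystemSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_igg: int = 1
    phi_occ: float | list[float] = 0.0
    box: list[float] = Field(default_factory=lambda: [100.0, 100.0, 100.0])

    @model_validator(mode="after")
    def _check(self):
        phis = self.phi_occ if isinstance(self.phi_occ, list) else [self.phi_occ]
        for p in phis:
            if not (0.0 <= p <= 0.30):
                raise ValueError(f"phi_occ {p} outside the supported [0, 0.30]")
        if self.n_igg < 0:
            raise ValueError("n_igg must be non-negative")
        if len(self.box) != 3 or any(b <= 0 for b in self.box):
            raise ValueError("box must be three positive edge lengths")
        return self


class _PhysicsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    temperature: float = 293.15
    viscosity: float = 1.002
    dt: float = 2.0e-7
    hydrodynamics: Literal["rpy_intra", "free_draining", "rpy_all"] = "rpy_intra"
    mobility_stride: int = 1


class _ScheduleSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    burn_in: float = 0.2
    production: float = 10.0
    sample_interval: float = 0.002


class _NamSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    l0: float = 30.0
    l_esc: float = 35.0
    reaction_cutoff: float = 0.1
    n_trajectories: int = 1000
    antigen_separation: float = 10.0
    censor_time: float = 5.0


class RunConfig(BaseModel):
    """Validated simulation configuration (strict: unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    experiment: Literal["dilute", "sweep", "nam_first", "nam_second"] = "dilute"
    seed: int = 1
    output_dir: str = "runs"
    parameter_file: Optional[str] = None
    system: _SystemSection = Field(default_factory=_SystemSection)
    physics: _PhysicsSection = Field(default_factory=_PhysicsSection)
    schedule: _ScheduleSection = Field(default_factory=_ScheduleSection)
    nam: _NamSection = Field(default_factory=_NamSection)

    def simulation_parameters(self) -> SimulationParameters:
        return SimulationParameters(
            temperature=self.physics.temperature,
            viscosity=self.physics.viscosity, dt=self.physics.dt,
            hydrodynamics=self.physics.hydrodynamics,
            mobility_stride=self.physics.mobility_stride)

    def run_schedule(self) -> Schedule:
        return Schedule(burn_in=self.schedule.burn_in,
                        production=self.schedule.production,
                        sample_interval=self.schedule.sample_interval)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; defaults are filled in."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig.model_validate(raw)
    if cfg.parameter_file is not None:
        ref = (path.parent / cfg.parameter_file)
        if not ref.exists():
            raise FileNotFoundError(f"parameter_file {ref} does not exist")
    return cfg


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh,
                       sort_keys=False)


# ---------------------------------------------------------------------------
# structure / trajectory formats
# ---------------------------------------------------------------------------

def _universe_for(config: SystemConfiguration, positions: np.ndarray):
    import MDAnalysis as mda
    n = config.n_beads
    u = mda.Universe.empty(n, n_residues=len(config.molecules),
                           atom_resindex=np.asarray(config.mol_index),
                           trajectory=True)
    names = [b.label for m in config.molecules for b in m.beads]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames",
                       ["IGG" if m.kind == "IgG" else "FIC"
                        for m in config.molecules])
    u.add_TopologyAttr("tempfactors")
    radii = config.hard_core_radii()
    u.atoms.tempfactors = radii
    if positions.ndim == 2:
        positions = positions[None]
    u.load_new(np.asarray(positions, dtype=np.float32), order="fac")
    u.dimensions = [*config.box, 90.0, 90.0, 90.0]
    return u


def write_trajectory(trajectory: Trajectory | SystemConfiguration, path,
                     fmt: Optional[str] = None) -> Path:
    """Write a trajectory (or single configuration) as XYZ, PDB or DCD.

    Coordinates are written in nm (note: the PDB/DCD convention is
    Angstrom-agnostic here -- the bead model has no atomic meaning, so the
    numbers are nm throughout and the metadata sidecar records that).
    Bead labels are the stable set S, H, A1, A2, A1p, A2p, FIC.
    """
    import MDAnalysis as mda
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in ("XYZ", "PDB", "DCD"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    if isinstance(trajectory, Trajectory):
        config = trajectory.config
        pos = trajectory.positions
        meta = {"seed": int(trajectory.seed),
                "phi_occ": float(trajectory.phi_occ),
                "n_frames": int(trajectory.n_frames),
                "sample_times_us": [float(trajectory.times[0]),
                                    float(trajectory.times[-1])],
                "units": "nm, us"}
    else:
        config = trajectory
        pos = config.positions[None]
        meta = {"n_frames": 1, "units": "nm"}
    u = _universe_for(config, pos)
    with mda.Writer(str(path), n_atoms=u.atoms.n_atoms) as w:
        for _ in u.trajectory:
            w.write(u.atoms)
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_structure(path) -> np.ndarray:
    """Read coordinates (first frame) from an XYZ/PDB file, shape (N, 3)."""
    import MDAnalysis as mda
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        return u.atoms.positions.astype(float).copy()


def write_manifest(outdir, config_like, seed: int) -> Path:
    """Plain-text manifest: config hash, seed, package versions."""
    import numba
    import iggbd
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(config_like, RunConfig):
        blob = config_like.model_dump_json().encode()
    else:
        blob = json.dumps(config_like, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "iggbd_version": iggbd.__version__,
        "numpy_version": np.__version__,
        "numba_version": numba.__version__,
    }
    path = outdir / "MANIFEST.txt"
    with open(path, "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}: {v}\n")
    return path


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_CASES = ("sphere", "dumbbell", "igg_dilute", "mini_crowded",
                 "absorbing_sphere")


def generate_fixture(case: str, outdir, seed: int = 1234) -> dict:
    """Deterministic small systems with documented analytic expectations.

    Writes a run config plus an ``expectations.yaml`` stating the analytic
    value(s) the fixture is meant to reproduce; returns the expectations.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if case == "sphere":
        a = FICOLL_RADIUS
        exp = {"case": case,
               "D_nm2_us": stokes_diffusion(a),
               "statement": "free single sphere: D = kBT/(6 pi eta a)"}
        cfg = RunConfig(experiment="dilute", seed=seed,
                        system=_SystemSection(n_igg=0, phi_occ=0.0,
                                              box=[60.0, 60.0, 60.0]),
                        physics=_PhysicsSection(hydrodynamics="free_draining",
                                                dt=1e-4))
    elif case == "dumbbell":
        exp = {"case": case,
               "bond": {"r_eq": 6.0, "kappa": 100.0},
               "statement": "bond length follows r^2 exp(-U/kBT); D_r from "
                            "rigid two-bead RPY mobility"}
        cfg = RunConfig(experiment="dilute", seed=seed,
                        physics=_PhysicsSection(dt=4e-6))
    elif case == "igg_dilute":
        exp = {"case": case,
               "D0_nm2_us": 36.80, "Dr0_rad2_us": 1.110,
               "statement": "dilute six-bead IgG with intra-molecule RPY"}
        cfg = RunConfig(experiment="dilute", seed=seed)
    elif case == "mini_crowded":
        exp = {"case": case, "phi_occ": 0.10,
               "n_ficoll": int(round((0.10 * 60.0 ** 3 -
                                      2 * 600.8) / sphere_volume(FICOLL_RADIUS))),
               "statement": "packs without inter-molecular overlap; achieved "
                            "phi within 0.005 of target"}
        cfg = RunConfig(experiment="sweep", seed=seed,
                        system=_SystemSection(n_igg=2, phi_occ=0.10,
                                              box=[60.0, 60.0, 60.0]))
    elif case == "absorbing_sphere":
        R, D = 5.0, stokes_diffusion(FICOLL_RADIUS)
        exp = {"case": case, "R_nm": R, "D_nm2_us": D,
               "k_nm3_us": 4.0 * math.pi * D * R,
               "statement": "NAM pipeline must reproduce Smoluchowski 4 pi D R"}
        cfg = RunConfig(experiment="nam_first", seed=seed)
    else:
        raise ValueError(f"unknown fixture case {case!r}; "
                         f"choose from {FIXTURE_CASES}")
    save_config(cfg, outdir / f"{case}.yaml")
    with open(outdir / f"{case}.expectations.yaml", "w") as fh:
        yaml.safe_dump(exp, fh, sort_keys=False)
    return exp
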