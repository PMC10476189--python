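"""Rotne-Prager-Yamakawa (far-field) hydrodynamics.

The mobility is represented as a diffusion matrix D (nm^2/us): the
Ermak-McCammon displacement is ``(D F) dt / k_B T`` plus Gaussian noise with
covariance ``2 D dt``.  The pair tensor is the standard RPY form generalised
to unequal bead radii, with the overlap-regularised branch for
``r < a_i + a_j`` (continuous at contact), so the matrix stays positive
definite for any configuration, overlapping beads included.  Because the RPY
tensor is divergence-free, the propagator needs no mobility-divergence drift
term; none exists in this code path.

Coupling scope is a mode switch: ``"rpy_intra"`` (default) applies RPY
coupling within each molecule and leaves different molecules hydrodynamically
independent, ``"free_draining"`` is plain Stokes drag per bead, and
``"rpy_all"`` couples every bead pair using minimum-image displacements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import SystemConfiguration
from .potentials import SystemArrays, compile_system
from .units import kbt, viscosity_internal

__all__ = ["MobilityMatrix", "rpy_block", "mobility_matrix",
           "correlated_noise"]


@dataclass
class MobilityMatrix:
    """Dense (3N, 3N) diffusion matrix plus its group structure."""

    matrix: np.ndarray
    mode: str
    grp_start: np.ndarray

    def assert_spd(self, tol: float = 1e-10) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-12 * max(1.0, np.abs(m).max())):
            raise ValueError("mobility matrix is not symmetric")
        # block structure: eigvalsh per group keeps this cheap
        for g in range(len(self.grp_start) - 1):
            s, e = 3 * self.grp_start[g], 3 * self.grp_start[g + 1]
            w = np.linalg.eigvalsh(m[s:e, s:e])
            if w.min() <= tol * max(1.0, w.max()):
                raise ValueError(
                    "mobility matrix is not positive definite "
                    "(invalid radii or coordinates?)")

    def cholesky(self) -> np.ndarray:
        L = np.zeros_like(self.matrix)
        _kernels.cholesky_groups(self.matrix, self.grp_start, L)
        return L


def rpy_block(r_vec: np.ndarray, a_i: float, a_j: float,
              eta_mpas: float = 1.002, temperature: float = 293.15
              ) -> np.ndarray:
    """The 3x3 RPY diffusion block for a bead pair (self block if r=0, i=j).

    Uses the unequal-radii generalisation with the overlap-regularised
    branch; at ``r_vec = 0`` with ``a_i == a_j`` this is the Stokes self
    mobility ``k_B T/(6 pi eta a) I``.
    """
    if a_i <= 0 or a_j <= 0:
        raise ValueError("bead radii must be positive")
    kt6pe = kbt(temperature) / (6.0 * np.pi * viscosity_internal(eta_mpas))
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r < 1e-12:
        return np.eye(3) * (kt6pe / max(a_i, a_j))
    c_iso, c_rr = _kernels._rpy_pair_coeffs(r, a_i, a_j, kt6pe)
    rhat = r_vec / r
    return c_iso * np.eye(3) + c_rr * np.outer(rhat, rhat)


def mobility_matrix(config: SystemConfiguration,
                    mode: str = "rpy_intra",
                    eta_mpas: float = 1.002,
                    temperature: float = 293.15,
                    arrays: SystemArrays | None = None,
                    check_spd: bool = False) -> MobilityMatrix:
    """Assemble the block-structured diffusion matrix for a configuration."""
    if arrays is None:
        arrays = compile_system(config, hydrodynamics=mode)
    n3 = 3 * config.n_beads
    M = np.zeros((n3, n3))
    kt6pe = kbt(temperature) / (6.0 * np.pi * viscosity_internal(eta_mpas))
    use_min_image = mode == "rpy_all"
    _kernels.build_mobility(
        np.ascontiguousarray(config.positions, dtype=float), arrays.a_h,
        arrays.grp_start, arrays.box, arrays.periodic, use_min_image,
        kt6pe, M)
    result = MobilityMatrix(matrix=M, mode=mode, grp_start=arrays.grp_start)
    if check_spd:
        result.assert_spd()
    return result


def correlated_noise(M: MobilityMatrix, dt: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Random displacements with zero mean and covariance ``2 M dt``.

    Generated through the per-group Cholesky factorisation of the diffusion
    matrix; returns an (N, 3) array in nm.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0.0:
        return np.zeros((M.matrix.shape[0] // 3, 3))
    try:
        L = M.cholesky()
    except Exception as err:  # numba raises LinAlgError through its wrapper
        raise np.linalg.LinAlgError(
            f"Cholesky factorisation of the mobility failed: {err}") from err
    z = rng.standard_normal(M.matrix.shape[0])
    step = np.sqrt(2.0 * dt) * (L @ z)
    return step.reshape(-1, 3)
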