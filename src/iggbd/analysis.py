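"""Trajectory observables: diffusion, flexibility and crowding response.

Implements the full observable set for the six-bead IgG model:

* time-origin-averaged mean square displacement of molecule centres and the
  long-time translational diffusion coefficient D = MSD/(6t),
* rotational diffusion from the first-rank orientation autocorrelation of
  the stem axis, ``<u(t).u(0)> = exp(-2 D_r t)``,
* hydrodynamic radius via Stokes-Einstein-Sutherland and the
  rotation-vs-translation parameter ``k = sqrt(4 D_r / (6 D))``,
* arm-arm (psi) and arm-stem (phi) angle samples, their empirical CDF/PDF,
  and Boltzmann-quadrature reference distributions,
* radius of gyration statistics and the linear crowding-sensitivity fits
  ``D/D0 = 1 - alpha*phi_occ`` and ``Rg/Rg0 = 1 - alpha_g*phi_occ``.

Molecule "position" is the unweighted geometric centre of the bead centres,
and R_g is likewise unweighted over the six beads; both choices are
rotation-invariant and free of an arbitrary mass assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

from .engine import Trajectory
from .model import MoleculeTopology, build_igg
from .units import hydrodynamic_radius as _ses_radius
from .units import kbt

__all__ = [
    "DiffusionEstimate", "AngleSample", "CrowdingSeries", "AlphaFit",
    "msd", "msd_from_positions", "fit_diffusion", "estimate_diffusion",
    "orientation_acf", "fit_rotational", "estimate_rotational",
    "hydrodynamic_radius", "rot_trans_parameter",
    "igg_angles", "angle_samples", "empirical_cdf_pdf",
    "radius_of_gyration", "rg_distribution",
    "fit_alpha", "calibrate_angles",
    "boltzmann_angle_pdf", "boltzmann_angle_cdf", "igg_hinge_quadrature",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class DiffusionEstimate:
    D: float                      # nm^2/us
    D_se: float                   # standard error (block averaging)
    window: tuple[float, float]   # lag-time fit window, us
    D_r: float = float("nan")     # rad^2/us
    D_r_se: float = float("nan")
    n_blocks: int = 0

    def __post_init__(self):
        if np.isfinite(self.D) and self.D <= 0:
            import warnings
            warnings.warn(f"non-positive diffusion estimate D={self.D:g}")


@dataclass
class AngleSample:
    """Per-frame angle samples in degrees: psi (arm-arm), phi (arm-stem)."""

    psi: np.ndarray   # one per IgG per frame
    phi: np.ndarray   # two per IgG per frame

    def __post_init__(self):
        for name, arr in (("psi", self.psi), ("phi", self.phi)):
            if arr.size and (arr.min() < 0 or arr.max() > 180):
                raise ValueError(f"{name} angles outside [0, 180] degrees")


@dataclass
class CrowdingSeries:
    """Observables along an occupied-volume-fraction sweep (one species)."""

    phi_occ: np.ndarray
    D_over_D0: np.ndarray
    rg_mean: Optional[np.ndarray] = None
    rg_sd: Optional[np.ndarray] = None

    def __post_init__(self):
        self.phi_occ = np.asarray(self.phi_occ, dtype=float)
        self.D_over_D0 = np.asarray(self.D_over_D0, dtype=float)
        if np.any((self.phi_occ < 0) | (self.phi_occ > 0.30)):
            raise ValueError("phi_occ outside [0, 0.30]")
        if np.any((self.D_over_D0 <= 0) | (self.D_over_D0 > 1.05)):
            raise ValueError("D/D0 outside (0, 1.05]")


@dataclass
class AlphaFit:
    """Linear crowding sensitivities; alpha_nonflex = alpha + alpha_g."""

    alpha: float
    alpha_g: float = float("nan")

    @property
    def alpha_nonflex(self) -> float:
        return self.alpha + self.alpha_g


# ---------------------------------------------------------------------------
# MSD and translational diffusion
# ---------------------------------------------------------------------------

def _msd_fft_single(x: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of one 3D track, all lags, O(n log n)."""
    n = x.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    s2 = np.zeros(n)
    for c in range(x.shape[1]):
        f = np.fft.rfft(x[:, c], nfft)
        ac = np.fft.irfft(f * np.conj(f), nfft)[:n]
        s2 += ac
    sq = np.einsum("ij,ij->i", x, x)
    css = np.concatenate(([0.0], np.cumsum(sq)))
    total = css[-1]
    lags = np.arange(n)
    # sum_{t} |x(t+tau)|^2 + |x(t)|^2 over the n-tau valid origins
    s1 = (total - css[lags]) + css[n - lags]
    return (s1 - 2.0 * s2) / (n - lags)


def msd_from_positions(times: np.ndarray, centers: np.ndarray) -> pd.DataFrame:
    """MSD curve from unwrapped centre tracks (n_frames, n_molecules, 3)."""
    times = np.asarray(times, dtype=float)
    if centers.ndim == 2:
        centers = centers[:, None, :]
    if len(times) < 2:
        raise ValueError("need at least two samples for an MSD")
    acc = np.zeros(len(times))
    for m in range(centers.shape[1]):
        acc += _msd_fft_single(np.ascontiguousarray(centers[:, m, :]))
    acc /= centers.shape[1]
    acc[0] = 0.0  # exact by definition; kill FFT round-off
    return pd.DataFrame({"lag": times - times[0], "msd": acc})


def msd(trajectory: Trajectory, species: Optional[str] = None) -> pd.DataFrame:
    """Time-origin-averaged MSD of molecule geometric centres.

    ``species`` restricts to "IgG" or "crowder" molecules.  Requires the
    trajectory's unwrapped coordinates (the native storage).
    """
    centers = trajectory.molecule_centers(kind=species)
    return msd_from_positions(trajectory.times, centers)


def fit_diffusion(msd_curve: pd.DataFrame,
                  window: tuple[float, float] = (0.5, 5.0)
                  ) -> DiffusionEstimate:
    """Least-squares line through the MSD over ``window``; D = slope/6."""
    lag = msd_curve["lag"].to_numpy()
    val = msd_curve["msd"].to_numpy()
    sel = (lag >= window[0]) & (lag <= window[1])
    if sel.sum() < 2:
        raise ValueError(f"fit window {window} contains fewer than 2 lags")
    slope, _ = np.polyfit(lag[sel], val[sel], 1)
    if slope <= 0:
        import warnings
        warnings.warn(f"non-positive MSD slope {slope:g} in window {window}")
    return DiffusionEstimate(D=slope / 6.0, D_se=float("nan"), window=window)


def _blocks(centers: np.ndarray, times: np.ndarray, n_blocks: int):
    n = centers.shape[0]
    edge = n // n_blocks
    for b in range(n_blocks):
        sl = slice(b * edge, (b + 1) * edge)
        yield times[sl], centers[sl]


def estimate_diffusion(trajectories: Trajectory | Sequence[Trajectory],
                       species: Optional[str] = None,
                       window: tuple[float, float] = (0.5, 5.0),
                       n_blocks: int = 3) -> DiffusionEstimate:
    """Translational D with a block-averaged uncertainty.

    The value comes from the fit to the MSD pooled over all molecules and
    trajectories.  The uncertainty comes from the spread of independent
    block estimates: one block per molecule track when several molecules
    are available (the statistically independent unit), otherwise
    ``n_blocks`` time-thirds of the single track.  In the latter case the
    window top is clipped to the block span.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    pooled = []
    block_est = []
    for traj in trajectories:
        centers = traj.molecule_centers(kind=species)
        pooled.append(fit_diffusion(
            msd_from_positions(traj.times, centers), window).D)
        if centers.shape[1] >= 4:
            for mcol in range(centers.shape[1]):
                curve = msd_from_positions(traj.times, centers[:, mcol])
                block_est.append(fit_diffusion(curve, window).D)
        else:
            for t_b, c_b in _blocks(centers, traj.times, n_blocks):
                curve = msd_from_positions(t_b, c_b)
                w_hi = min(window[1], 0.8 * float(curve["lag"].iloc[-1]))
                block_est.append(fit_diffusion(curve, (window[0], w_hi)).D)
    arr = np.asarray(block_est)
    se = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else float("nan")
    return DiffusionEstimate(D=float(np.mean(pooled)), D_se=float(se),
                             window=window, n_blocks=len(arr))


# ---------------------------------------------------------------------------
# orientation ACF and rotational diffusion
# ---------------------------------------------------------------------------

def _acf_fft(u: np.ndarray) -> np.ndarray:
    """Origin-averaged <u(t+tau).u(t)> for one unit-vector track (n, 3)."""
    n = u.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    acc = np.zeros(n)
    for c in range(3):
        f = np.fft.rfft(u[:, c], nfft)
        acc += np.fft.irfft(f * np.conj(f), nfft)[:n]
    return acc / (n - np.arange(n))


def orientation_acf(trajectory: Trajectory,
                    axis: tuple[str, str] = ("S", "H")) -> pd.DataFrame:
    """First-rank ACF of a molecular axis, averaged over IgG molecules.

    The default axis is the stem-to-hinge unit vector (S -> H), the most
    persistent internal direction of the model.
    """
    labels = None
    slices = trajectory.config.molecule_slices()
    acc = None
    count = 0
    for s, mol in zip(slices, trajectory.config.molecules):
        if mol.kind != "IgG":
            continue
        labels = mol.labels
        i0 = s.start + labels.index(axis[0])
        i1 = s.start + labels.index(axis[1])
        vec = trajectory.positions[:, i1] - trajectory.positions[:, i0]
        norm = np.linalg.norm(vec, axis=1)
        if np.any(norm < 1e-12):
            raise ValueError("degenerate (zero-length) orientation axis")
        u = vec / norm[:, None]
        a = _acf_fft(np.ascontiguousarray(u))
        acc = a if acc is None else acc + a
        count += 1
    if count == 0:
        raise ValueError("trajectory contains no IgG molecule")
    lags = trajectory.times - trajectory.times[0]
    return pd.DataFrame({"lag": lags, "acf": acc / count})


def fit_rotational(acf_curve: pd.DataFrame,
                   window: tuple[float, float] = (0.0, 1.0),
                   min_acf: float = 0.1) -> float:
    """D_r from a log-linear fit of ``acf = exp(-2 D_r t)`` over ``window``.

    Lags where the ACF has decayed below ``min_acf`` are excluded (their
    logarithm is noise-dominated).
    """
    lag = acf_curve["lag"].to_numpy()
    val = acf_curve["acf"].to_numpy()
    sel = (lag >= window[0]) & (lag <= window[1]) & (val > min_acf)
    if sel.sum() < 2:
        raise ValueError("too few ACF points in the fit window")
    slope, _ = np.polyfit(lag[sel], np.log(val[sel]), 1)
    return -slope / 2.0


def estimate_rotational(trajectories: Trajectory | Sequence[Trajectory],
                        window: tuple[float, float] = (0.0, 1.0),
                        n_blocks: int = 3,
                        axis: tuple[str, str] = ("S", "H")
                        ) -> DiffusionEstimate:
    """Block-averaged D_r across one or several trajectories."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    values = []
    for traj in trajectories:
        n = traj.n_frames
        edge = n // n_blocks
        for b in range(n_blocks):
            sub = Trajectory(
                times=traj.times[b * edge:(b + 1) * edge],
                positions=traj.positions[b * edge:(b + 1) * edge],
                config=traj.config, params=traj.params, seed=traj.seed)
            curve = orientation_acf(sub, axis=axis)
            values.append(fit_rotational(curve, window=window))
    arr = np.asarray(values)
    se = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else float("nan")
    return DiffusionEstimate(D=float("nan"), D_se=float("nan"), window=window,
                             D_r=float(arr.mean()), D_r_se=float(se),
                             n_blocks=len(arr))


def hydrodynamic_radius(D: float, temperature: float = 293.15,
                        viscosity_mpas: float = 1.002) -> float:
    """a_H = k_B T / (6 pi eta D), nm."""
    return _ses_radius(D, temperature, viscosity_mpas)


def rot_trans_parameter(D: float, D_r: float) -> float:
    """Rotation-per-distance parameter sqrt(4 D_r / (6 D)), in degrees/nm.

    Quantifies how far (in angle) a particle rotates while translating unit
    distance; ~8 deg/nm for the dilute IgG model.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if D_r < 0:
        raise ValueError("D_r must be non-negative")
    return math.degrees(math.sqrt(4.0 * D_r / (6.0 * D)))


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def _angle_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise ValueError("zero-length axis vector")
    c = np.clip(np.einsum("...i,...i->...", u, v) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def igg_angles(frame: np.ndarray) -> tuple[float, float, float]:
    """(psi, phi_1, phi_2) in degrees from one six-bead IgG frame.

    psi is the angle between the two arm axes (H->A2 and H->A2'); phi are
    the angles between the stem axis (H->S) and each arm axis.
    """
    frame = np.asarray(frame, dtype=float)
    s, h, a2, a2p = frame[0], frame[1], frame[3], frame[5]
    arm1, arm2, stem = a2 - h, a2p - h, s - h
    psi = float(_angle_between(arm1, arm2))
    return psi, float(_angle_between(stem, arm1)), \
        float(_angle_between(stem, arm2))


def angle_samples(trajectory: Trajectory) -> AngleSample:
    """psi/phi samples over all frames and all IgG molecules."""
    slices = trajectory.config.molecule_slices()
    psis, phis = [], []
    for s, mol in zip(slices, trajectory.config.molecules):
        if mol.kind != "IgG":
            continue
        sub = trajectory.positions[:, s]
        stem = sub[:, 0] - sub[:, 1]
        arm1 = sub[:, 3] - sub[:, 1]
        arm2 = sub[:, 5] - sub[:, 1]
        psis.append(_angle_between(arm1, arm2))
        phis.append(_angle_between(stem, arm1))
        phis.append(_angle_between(stem, arm2))
    if not psis:
        raise ValueError("trajectory contains no IgG molecule")
    return AngleSample(psi=np.concatenate(psis), phi=np.concatenate(phis))


def empirical_cdf_pdf(samples: np.ndarray,
                      grid: Optional[np.ndarray] = None,
                      smoothing: float = 5.0) -> pd.DataFrame:
    """Empirical CDF on a grid and the PDF by differentiating it.

    The CDF is smoothed with a Gaussian kernel (``smoothing`` in grid units,
    default 5 degrees) before central differencing -- raw numerical
    differentiation of an empirical CDF is too noisy to be useful.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 100:
        raise ValueError(f"need at least 100 samples, got {samples.size}")
    if grid is None:
        grid = np.linspace(0.0, 180.0, 361)
    grid = np.asarray(grid, dtype=float)
    sorted_s = np.sort(samples)
    cdf = np.searchsorted(sorted_s, grid, side="right") / samples.size
    dx = grid[1] - grid[0]
    cdf_smooth = gaussian_filter1d(cdf, sigma=smoothing / dx, mode="nearest")
    pdf = np.gradient(cdf_smooth, grid)
    pdf = np.clip(pdf, 0.0, None)
    norm = np.trapezoid(pdf, grid)
    if norm > 0:
        pdf = pdf / norm
    return pd.DataFrame({"angle": grid, "cdf": cdf, "pdf": pdf})


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------

def radius_of_gyration(frame: np.ndarray) -> float:
    """Unweighted R_g over bead centres of one molecule frame (n, 3)."""
    frame = np.asarray(frame, dtype=float)
    center = frame.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((frame - center) ** 2, axis=1))))


def rg_distribution(trajectory: Trajectory,
                    bins: int = 60) -> tuple[float, float, pd.DataFrame]:
    """Mean, SD and histogram of IgG R_g over frames and molecules."""
    slices = trajectory.config.molecule_slices()
    vals = []
    for s, mol in zip(slices, trajectory.config.molecules):
        if mol.kind != "IgG":
            continue
        sub = trajectory.positions[:, s]
        centered = sub - sub.mean(axis=1, keepdims=True)
        vals.append(np.sqrt(np.einsum("fij,fij->f", centered, centered)
                            / sub.shape[1]))
    if not vals:
        raise ValueError("trajectory contains no IgG molecule")
    rg = np.concatenate(vals)
    hist, edges = np.histogram(rg, bins=bins, density=True)
    table = pd.DataFrame({"rg": 0.5 * (edges[:-1] + edges[1:]), "pdf": hist})
    return float(rg.mean()), float(rg.std(ddof=1)), table


# ---------------------------------------------------------------------------
# crowding-sensitivity fits
# ---------------------------------------------------------------------------

def _slope_through_one(phi: np.ndarray, y: np.ndarray) -> float:
    """Least-squares alpha in  y = 1 - alpha*phi  (intercept pinned at 1)."""
    return float(np.sum(phi * (1.0 - y)) / np.sum(phi * phi))


def fit_alpha(series: CrowdingSeries) -> AlphaFit:
    """alpha from D/D0 vs phi_occ; alpha_g from Rg ratios when present.

    Requires at least three phi_occ points including the dilute reference.
    """
    phi = series.phi_occ
    if len(phi) < 3 or not np.isclose(phi.min(), 0.0):
        raise ValueError("need >= 3 phi_occ points including phi_occ = 0")
    order = np.argsort(phi)
    phi = phi[order]
    y = series.D_over_D0[order]
    alpha = _slope_through_one(phi[1:], y[1:])
    alpha_g = float("nan")
    if series.rg_mean is not None:
        rg = np.asarray(series.rg_mean, dtype=float)[order]
        alpha_g = _slope_through_one(phi[1:], rg[1:] / rg[0])
    return AlphaFit(alpha=alpha, alpha_g=alpha_g)


# ---------------------------------------------------------------------------
# Boltzmann references and calibration
# ---------------------------------------------------------------------------

def boltzmann_angle_pdf(theta_eq: float, xi: float,
                        temperature: float = 293.15,
                        grid: Optional[np.ndarray] = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium density of a single harmonic angle on the sphere.

    p(theta) ~ sin(theta) exp(-xi (theta-theta_eq)^2 / (2 k_B T)), on a
    degree grid.  This is exact for an isolated three-bead angle.
    """
    if grid is None:
        grid = np.linspace(0.0, 180.0, 721)
    th = np.radians(grid)
    u = 0.5 * xi * (th - math.radians(theta_eq)) ** 2
    w = np.sin(th) * np.exp(-(u - u.min()) / kbt(temperature))
    w /= np.trapezoid(w, grid)
    return grid, w


def boltzmann_angle_cdf(theta_eq: float, xi: float,
                        temperature: float = 293.15,
                        grid: Optional[np.ndarray] = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    grid, pdf = boltzmann_angle_pdf(theta_eq, xi, temperature, grid)
    cdf = np.concatenate(([0.0], np.cumsum(
        0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))))
    return grid, cdf / cdf[-1]


def igg_hinge_quadrature(topology: Optional[MoleculeTopology] = None,
                         temperature: float = 293.15,
                         n_theta: int = 241, n_dphi: int = 241
                         ) -> pd.DataFrame:
    """Reference psi/phi distributions of the coupled hinge by quadrature.

    Treats the stem and the two (straight) arm axes as unit vectors from the
    hinge, with the three angular potentials coupling them; integrates the
    Boltzmann weight over both arm directions relative to the stem
    (polar angles theta1, theta2 and relative azimuth).  Returns a degree
    grid with columns ``psi_cdf`` and ``phi_cdf``.

    This is the independent equilibrium reference the BD sampler is tested
    against; it assumes rigid arm axes (the stiff 180-degree arm terms leave
    only ~2 degrees of wobble, negligible at the hinge distribution width).
    """
    if topology is None:
        topology = build_igg()
    terms = {}
    labels = topology.labels
    for a in topology.angles:
        key = (labels[a.bead_i], labels[a.bead_j], labels[a.bead_k])
        terms[key] = a
    t_s1 = terms[("S", "H", "A1")]
    t_s2 = terms[("S", "H", "A1p")]
    t_12 = terms[("A1", "H", "A1p")]
    beta = 1.0 / kbt(temperature)

    th = np.linspace(0.0, math.pi, n_theta)
    dphi = np.linspace(0.0, math.pi, n_dphi)  # symmetric in +-dphi
    grid_deg = np.linspace(0.0, 180.0, 721)
    edges = np.concatenate((grid_deg - 0.125, [180.125]))

    def harm(theta, term):
        return 0.5 * term.xi * (theta - math.radians(term.theta_eq)) ** 2

    w1 = np.sin(th) * np.exp(-beta * harm(th, t_s1))
    w2 = np.sin(th) * np.exp(-beta * harm(th, t_s2))
    c1, s1 = np.cos(th), np.sin(th)

    psi_hist = np.zeros(len(grid_deg))
    phi_hist = np.zeros(len(grid_deg))
    for k, dp in enumerate(dphi):
        cpsi = np.clip(c1[:, None] * c1[None, :] +
                       s1[:, None] * s1[None, :] * math.cos(dp), -1, 1)
        psi = np.arccos(cpsi)
        w = (w1[:, None] * w2[None, :]) * np.exp(-beta * harm(psi, t_12))
        if k == 0 or k == len(dphi) - 1:
            w = w * 0.5  # trapezoid ends in the azimuth
        idx = np.clip(np.digitize(np.degrees(psi).ravel(), edges) - 1,
                      0, len(grid_deg) - 1)
        np.add.at(psi_hist, idx, w.ravel())
        th1_idx = np.clip(np.digitize(
            np.degrees(np.broadcast_to(th[:, None], w.shape)).ravel(),
            edges) - 1, 0, len(grid_deg) - 1)
        np.add.at(phi_hist, th1_idx, w.ravel())

    def to_cdf(h):
        c = np.cumsum(h)
        return c / c[-1]

    return pd.DataFrame({"angle": grid_deg, "psi_cdf": to_cdf(psi_hist),
                         "phi_cdf": to_cdf(phi_hist)})


def calibrate_angles(target_cdf_tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
                     initial: tuple[float, float] = (90.0, 1.0),
                     temperature: float = 293.15
                     ) -> tuple[float, float, float]:
    """Fit (theta_eq, xi) of a single hinge angle to a target CDF.

    ``target_cdf_tables`` is a two-column table (``angle`` in degrees,
    ``cdf``) or a mapping with one such table; the sup-distance between the
    single-angle Boltzmann CDF and the target is minimised.  Returns
    ``(theta_eq, xi, achieved_sup_distance)``.
    """
    if isinstance(target_cdf_tables, Mapping):
        if len(target_cdf_tables) != 1:
            raise ValueError("calibrate one angle table at a time")
        (table,) = target_cdf_tables.values()
    else:
        table = target_cdf_tables
    ang = np.asarray(table["angle"], dtype=float)
    target = np.asarray(table["cdf"], dtype=float)
    if np.any(np.diff(target) < -1e-9):
        raise ValueError("target CDF must be monotone non-decreasing")

    def objective(p):
        theta_eq, log_xi = p
        if not (1.0 < theta_eq < 179.9):
            return 10.0
        grid, cdf = boltzmann_angle_cdf(theta_eq, math.exp(log_xi),
                                        temperature)
        model = np.interp(ang, grid, cdf)
        return float(np.max(np.abs(model - target)))

    res = minimize(objective, x0=[initial[0], math.log(initial[1])],
                   method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
    theta_eq, log_xi = res.x
    return float(theta_eq), float(math.exp(log_xi)), float(res.fun)
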