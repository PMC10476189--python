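"""Unit system and physical constants.

Everything in the package uses one internal unit system:

================  =========================
quantity          unit
================  =========================
length            nm
time              us (microsecond)
energy            kcal/mol
temperature       K
force             kcal mol^-1 nm^-1
diffusion         nm^2 us^-1
rate constant     nm^3 us^-1
================  =========================

Viscosities are accepted in mPa*s (cP) at the API surface and converted
internally.  With these units the Stokes-Einstein-Sutherland diffusion
coefficient of a 5.1 nm sphere in water-like solvent at 20 C evaluates to
~42 nm^2/us, a convenient sanity anchor.
"""

from __future__ import annotations

import math

#: Boltzmann constant, kcal mol^-1 K^-1
KB = 0.0019872041

#: Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

#: 1 mPa*s expressed in kcal mol^-1 us nm^-3
MPAS_TO_INTERNAL = 1.43933e-4

#: multiply a rate in nm^3 us^-1 by this to get M^-1 s^-1
NM3_PER_US_TO_PER_M_PER_S = N_AVOGADRO * 1e-24 * 1e6


def kbt(temperature: float = 293.15) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB * temperature


def viscosity_internal(viscosity_mpas: float) -> float:
    """Convert a viscosity in mPa*s to internal units (kcal mol^-1 us nm^-3)."""
    return viscosity_mpas * MPAS_TO_INTERNAL


def stokes_diffusion(radius_nm: float, temperature: float = 293.15,
                     viscosity_mpas: float = 1.002) -> float:
    """Stokes-Einstein-Sutherland translational diffusion coefficient.

    D = k_B T / (6 pi eta a), returned in nm^2/us.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    eta = viscosity_internal(viscosity_mpas)
    return kbt(temperature) / (6.0 * math.pi * eta * radius_nm)


def hydrodynamic_radius(diffusion_nm2_us: float, temperature: float = 293.15,
                        viscosity_mpas: float = 1.002) -> float:
    """Invert Stokes-Einstein-Sutherland: a_H = k_B T / (6 pi eta D), in nm."""
    if diffusion_nm2_us <= 0:
        raise ValueError("diffusion coefficient must be positive")
    eta = viscosity_internal(viscosity_mpas)
    return kbt(temperature) / (6.0 * math.pi * eta * diffusion_nm2_us)
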