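"""Shear viscosity from periodic cosine-perturbation velocity profiles.

The analysis half of the periodic-perturbation NEMD method: an external
acceleration a_z(x) = A cos(k x) with k = 2 pi / L_x drives a stationary
velocity profile; at steady state the Navier-Stokes balance gives the
profile amplitude V = rho A / (eta k^2), so each fitted profile yields an
instantaneous inverse viscosity 1/eta = V k^2 / (rho A). The shear
viscosity is the reciprocal of the time-averaged inverse viscosity, with
its uncertainty from block averaging of the 1/eta series.

Unit conventions: A in nm ps^-2, V in nm/ps, L_x in nm, rho in kg m^-3;
the inverse viscosity is returned in SI (m s kg^-1) and eta in mPa s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensembles import block_average_error

__all__ = [
    "PeriodicPerturbation",
    "VelocityProfile",
    "ViscosityEstimate",
    "fit_profile_amplitude",
    "instantaneous_inverse_viscosity",
    "summarize_viscosity",
]

# (nm/ps) * nm^-2 / (nm ps^-2) = ps nm^-2 = 1e6 s m^-2
_PS_PER_NM2_TO_S_PER_M2 = 1e6


@dataclass(frozen=True)
class PeriodicPerturbation:
    """Cosine acceleration field a_z(x) = A cos(2 pi x / L_x)."""

    amplitude: float   # nm ps^-2
    box_length: float  # nm

    def __post_init__(self) -> None:
        if self.box_length <= 0:
            raise ValueError("box length must be positive")

    @property
    def wavenumber(self) -> float:
        """k = 2 pi / L_x in nm^-1."""
        return 2.0 * np.pi / self.box_length


@dataclass
class VelocityProfile:
    """Sampled v_z(x) profile with the fluid mass density."""

    x_positions: np.ndarray  # nm, within [0, Lx)
    vz_values: np.ndarray    # nm/ps
    rho: float               # kg m^-3

    def __post_init__(self) -> None:
        self.x_positions = np.asarray(self.x_positions, dtype=float)
        self.vz_values = np.asarray(self.vz_values, dtype=float)
        if self.x_positions.shape != self.vz_values.shape or self.x_positions.size < 8:
            raise ValueError("profile needs >= 8 matched (x, vz) samples")
        if self.rho <= 0:
            raise ValueError("density must be positive")


@dataclass
class ViscosityEstimate:
    eta: float           # mPa s
    inv_eta_mean: float  # m s kg^-1
    error: float         # mPa s
    block_sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def fit_profile_amplitude(profile: VelocityProfile,
                          perturbation: PeriodicPerturbation) -> float:
    """Least-squares amplitude V of v_z(x) = V cos(k x) (nm/ps).

    A single-basis linear projection: V = <vz, cos(kx)> / <cos^2(kx)>.
    An identically zero profile gives V = 0 (infinitely viscous limit).
    """
    c = np.cos(perturbation.wavenumber * profile.x_positions)
    denom = float(c @ c)
    if denom == 0:
        raise ValueError("degenerate sampling: cos(kx) vanishes at all points")
    return float(profile.vz_values @ c / denom)


def instantaneous_inverse_viscosity(V: float,
                                    perturbation: PeriodicPerturbation,
                                    rho: float) -> float:
    """Inverse shear viscosity 1/eta = V k^2 / (rho A) in m s kg^-1."""
    if perturbation.amplitude == 0:
        raise ValueError("perturbation amplitude must be non-zero")
    if rho <= 0:
        raise ValueError("density must be positive")
    k = perturbation.wavenumber
    return (V * k ** 2 / (rho * perturbation.amplitude)) * _PS_PER_NM2_TO_S_PER_M2


def summarize_viscosity(inv_eta_series: np.ndarray) -> ViscosityEstimate:
    """Shear viscosity (mPa s) from a series of inverse viscosities.

    eta = 1 / mean(1/eta); the block-averaged standard error of the mean
    inverse viscosity is propagated through the reciprocal,
    sigma_eta = sigma_m / m^2.
    """
    series = np.asarray(inv_eta_series, dtype=float)
    if series.size < 4:
        raise ValueError("need at least 4 inverse-viscosity samples")
    block = block_average_error(series)
    if block.mean <= 0:
        raise ValueError("non-positive mean inverse viscosity")
    eta_mpas = 1000.0 / block.mean  # 1/(m s kg^-1) = Pa s -> mPa s
    err_mpas = 1000.0 * block.error / block.mean ** 2
    return ViscosityEstimate(float(eta_mpas), float(block.mean),
                             float(err_mpas), block.block_sizes)
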