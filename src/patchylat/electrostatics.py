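"""Screened electrostatics of charged dipolar nanoparticles.

Two like-charged particles bearing permanent dipoles interact, in an
electrolyte, through a screened (Yukawa-type) potential with three
terms — charge–charge, charge–dipole, and dipole–dipole — each damped by
exp(-kappa*r) and corrected by finite-size factors C0 and C1 that depend
on the particle radius ``a`` and the inverse Debye length ``kappa``:

    C0 = exp(kappa*a) / (1 + kappa*a)
    C1 = 3*exp(kappa*a) / (2 + 2*kappa*a + (kappa*a)^2 + (1 + kappa*a)/eps)

When lateral bonding constrains both dipoles to lie normal to a 2D
lattice plane (theta_i = theta_j = 90 deg), the charge–dipole term and
the longitudinal part of the dipole–dipole term vanish, leaving the
reduced form

    U(r, dphi) = k_e q^2 exp(-kappa r) C0^2 / r
               + k_e mu^2 cos(dphi) (1 + kappa r) exp(-kappa r) C1^2 / r^3

with k_e = 1/(4 pi eps0 eps).  cos(dphi) = +1 for parallel (p4) packing
and -1 for antiparallel (p42_1 2) packing, so the dipolar term is
repulsive in the former and attractive in the latter — the thermodynamic
origin of antiparallel lattice selection in solution.

Inputs are in bench units (nm, debye, elementary charges, mol/L);
energies are returned in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .units import (
    DEBYE,
    EPS0,
    E_CHARGE,
    K_BOLTZMANN,
    N_AVOGADRO,
    NM,
    joule_to_kcal_per_mol,
    kcal_per_mol_to_kbt,
)

__all__ = [
    "PatchyParticleModel",
    "Electrolyte",
    "PairConfiguration",
    "EnergyLandscape",
    "debye_kappa",
    "geometry_factors",
    "pair_energy_full",
    "pair_energy_reduced",
    "symmetry_energy_gap",
    "dihedral_landscape",
]


@dataclass(frozen=True)
class PatchyParticleModel:
    """A charged dipolar sphere: net charge (e), dipole (D), radius (nm)."""

    net_charge: float = -16.0
    dipole_magnitude: float = 1200.0
    radius: float = 4.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("particle radius must be > 0")
        if self.dipole_magnitude < 0:
            raise ValueError("dipole magnitude must be >= 0")


@dataclass(frozen=True)
class Electrolyte:
    """Solvent/electrolyte state; kappa is derived from (eps, T, I) unless given.

    ``ionic_strength`` is the 1:1 salt concentration in mol/L.  An explicit
    ``kappa_nm`` (1/nm) overrides the derived value, which is how printed
    Debye lengths can be matched exactly.
    """

    relative_permittivity: float = 78.0
    temperature: float = 300.0
    ionic_strength: float = 0.020
    kappa_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.relative_permittivity <= 1:
            raise ValueError("relative permittivity must exceed 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")

    @property
    def kappa(self) -> float:
        """Inverse Debye screening length in 1/nm."""
        if self.kappa_nm is not None:
            return self.kappa_nm
        return debye_kappa(self)


def debye_kappa(solvent: Electrolyte) -> float:
    """Inverse Debye length kappa (1/nm) of a symmetric 1:1 electrolyte.

    kappa^2 = 2 e^2 N_A (1000 I) / (eps0 eps k_B T); at I = 20 mM,
    eps = 78, T = 300 K this gives kappa^-1 = 2.1508 nm.
    """
    num = 2.0 * E_CHARGE**2 * N_AVOGADRO * (1000.0 * solvent.ionic_strength)
    den = EPS0 * solvent.relative_permittivity * K_BOLTZMANN * solvent.temperature
    return float(np.sqrt(num / den)) * NM


def geometry_factors(solvent: Electrolyte, particle: PatchyParticleModel) -> tuple[float, float]:
    """Finite-size screening factors (C0, C1) for a particle of radius a."""
    ka = solvent.kappa * particle.radius
    eps = solvent.relative_permittivity
    c0 = np.exp(ka) / (1.0 + ka)
    c1 = 3.0 * np.exp(ka) / (2.0 + 2.0 * ka + ka**2 + (1.0 + ka) / eps)
    return float(c0), float(c1)


@dataclass(frozen=True)
class PairConfiguration:
    """Relative geometry of a particle pair.

    ``theta_i``/``theta_j`` are the angles between each dipole axis and
    the center-center vector r_ij; ``dphi`` is the dihedral angle between
    the dipoles about r_ij.  Degrees throughout; separation in nm.
    """

    separation: float
    theta_i: float = 90.0
    theta_j: float = 90.0
    dphi: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.separation) or self.separation <= 0:
            raise ValueError("separation must be finite and > 0")
        for ang in (self.theta_i, self.theta_j, self.dphi):
            if not np.isfinite(ang):
                raise ValueError("angles must be finite")


def _ke(eps: float) -> float:
    return 1.0 / (4.0 * np.pi * EPS0 * eps)


def pair_energy_full(
    cfg: PairConfiguration,
    particle_i: PatchyParticleModel,
    particle_j: PatchyParticleModel,
    solvent: Electrolyte,
) -> float:
    """Full three-term screened pair potential, in kcal/mol.

    The dipole–dipole term has a longitudinal part weighted by
    cos(theta_i) cos(theta_j) [2 + kr + (kr)^2] and a transverse part
    weighted by sin(theta_i) sin(theta_j) cos(dphi) [1 + kr].
    """
    eps = solvent.relative_permittivity
    kappa = solvent.kappa  # 1/nm
    r = cfg.separation  # nm
    kr = kappa * r
    r_m = r * NM
    qi = particle_i.net_charge * E_CHARGE
    qj = particle_j.net_charge * E_CHARGE
    mi = particle_i.dipole_magnitude * DEBYE
    mj = particle_j.dipole_magnitude * DEBYE
    c0_i, c1_i = geometry_factors(solvent, particle_i)
    c0_j, c1_j = geometry_factors(solvent, particle_j)
    ti = np.deg2rad(cfg.theta_i)
    tj = np.deg2rad(cfg.theta_j)
    dphi = np.deg2rad(cfg.dphi)
    ke = _ke(eps)
    damp = np.exp(-kr)

    u_qq = ke * qi * qj / r_m * damp * c0_i * c0_j
    u_qmu = (
        ke
        / r_m**2
        * damp
        * (qi * mj * np.cos(tj) * c0_i * c1_j + qj * mi * np.cos(ti) * c0_j * c1_i)
    )
    u_mumu = (
        ke
        * mi
        * mj
        / r_m**3
        * (
            np.cos(ti) * np.cos(tj) * (2.0 + kr + kr**2)
            + np.sin(ti) * np.sin(tj) * np.cos(dphi) * (1.0 + kr)
        )
        * damp
        * c1_i
        * c1_j
    )
    total = u_qq + u_qmu + u_mumu
    if not np.isfinite(total):
        raise ValueError("non-finite pair energy; check inputs")
    return joule_to_kcal_per_mol(total)


def pair_energy_reduced(
    r: float,
    dphi: float,
    particle: PatchyParticleModel,
    solvent: Electrolyte,
) -> float:
    """Reduced lattice-constrained pair potential (dipoles normal to the
    plane, theta = 90 deg), in kcal/mol.

    ``r`` in nm, ``dphi`` in degrees (0 = parallel/p4, 180 =
    antiparallel/p42_1 2).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be > 0")
    eps = solvent.relative_permittivity
    kappa = solvent.kappa
    kr = kappa * r
    r_m = r * NM
    q = particle.net_charge * E_CHARGE
    mu = particle.dipole_magnitude * DEBYE
    c0, c1 = geometry_factors(solvent, particle)
    ke = _ke(eps)
    damp = np.exp(-kr)
    u = (
        ke * q * q / r_m * damp * c0**2
        + ke * mu * mu / r_m**3 * np.cos(np.deg2rad(dphi)) * (1.0 + kr) * damp * c1**2
    )
    return joule_to_kcal_per_mol(u)


def symmetry_energy_gap(
    r: float, particle: PatchyParticleModel, solvent: Electrolyte
) -> float:
    """U(parallel) - U(antiparallel) at separation r (nm), in kcal/mol.

    The charge term cancels, so the gap is purely dipolar:
    2 k_e mu^2 (1 + kr) exp(-kr) C1^2 / r^3.  Positive values favour the
    antiparallel (p42_1 2) arrangement.
    """
    return pair_energy_reduced(r, 0.0, particle, solvent) - pair_energy_reduced(
        r, 180.0, particle, solvent
    )


@dataclass
class EnergyLandscape:
    """Tabulated pair energies over (separation, dihedral) grids."""

    r_values: np.ndarray  # nm
    dphi_values: np.ndarray  # degrees
    energies_kcal: np.ndarray  # shape (n_r, n_dphi)
    temperature: float = 300.0

    @property
    def energies_kbt(self) -> np.ndarray:
        return kcal_per_mol_to_kbt(self.energies_kcal, self.temperature)

    def to_frame(self):
        """Long-format DataFrame with columns r_nm, dphi_deg, U_kcal, U_kBT."""
        import pandas as pd

        rr, pp = np.meshgrid(self.r_values, self.dphi_values, indexing="ij")
        return pd.DataFrame(
            {
                "r_nm": rr.ravel(),
                "dphi_deg": pp.ravel(),
                "U_kcal_mol": self.energies_kcal.ravel(),
                "U_kBT": self.energies_kbt.ravel(),
            }
        )


def dihedral_landscape(
    r_values: Sequence[float],
    dphi_values: Sequence[float],
    particle: PatchyParticleModel,
    solvent: Electrolyte,
) -> EnergyLandscape:
    """Tabulate the reduced potential over separation and dihedral grids.

    For every separation the energy decreases monotonically from
    dphi = 0 toward dphi = 180 deg — the funnel that steers a newly
    attaching monomer into antiparallel registry.
    """
    r_values = np.asarray(r_values, dtype=float)
    dphi_values = np.asarray(dphi_values, dtype=float)
    if r_values.size == 0 or dphi_values.size == 0:
        raise ValueError("landscape grids must be non-empty")
    energies = np.empty((r_values.size, dphi_values.size))
    for k, dphi in enumerate(dphi_values):
        energies[:, k] = pair_energy_reduced(r_values, dphi, particle, solvent)
    return EnergyLandscape(
        r_values=r_values,
        dphi_values=dphi_values,
        energies_kcal=energies,
        temperature=solvent.temperature,
    )
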