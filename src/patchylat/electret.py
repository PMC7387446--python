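"""Analytic electret and piezoelectric estimates for polar 2D lattices.

A p4-symmetric crystal carries one permanent dipole mu per unit cell,
all pointing the same way — a 2D electret.  Treating the crystal as a
uniform dipole sheet of surface density mu/A immersed in a medium of
relative permittivity eps, the electrostatic potential step across the
sheet is

    dV = (mu / A) / (eps0 * eps),

independent of the slab thickness.  The bulk polarization density

    rho_mu = mu / (A * t)

does depend on the slab thickness t and quantifies the electret
strength per unit volume.  Because the lattice spacing (hence A) is
mechanically tunable through the rotating-squares conformation,
voltage and polarization density couple to in-plane strain — the
crystal is piezoelectric.  A checkerboard (p42_1 2) lattice has equal
up and down dipole densities and therefore zero net sheet density.

Sign convention: the dipole vector points from the negative C-terminal
face to the positive N-terminal face, and the reported membrane voltage
for an N-terminus-up lattice (orientation +1) is negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .units import DEBYE, EPS0, E_CHARGE, NM
from .lattice import conformation_geometry

__all__ = [
    "PolarizedSlab",
    "polarization_density",
    "membrane_voltage",
    "piezo_curve",
    "bound_charge",
]


@dataclass(frozen=True)
class PolarizedSlab:
    """One dipole of ``dipole_per_site`` (D) per cell of area (nm^2) in a
    slab of the given thickness (nm).

    The default thickness, 4.5 nm, is the approximate monomer height
    (half the 9.5-nm tail-to-tail dimer); it only affects the volumetric
    polarization density, never the sheet voltage.
    """

    dipole_per_site: float = 1200.0
    cell_area: float = 100.0
    slab_thickness: float = 4.5
    relative_permittivity: float = 78.0
    orientation: int = 1

    def __post_init__(self) -> None:
        if self.cell_area <= 0 or self.slab_thickness <= 0:
            raise ValueError("cell area and slab thickness must be > 0")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")


def polarization_density(slab: PolarizedSlab) -> float:
    """Volumetric polarization density rho_mu = mu/(A*t), in C/m^2."""
    mu_cm = slab.dipole_per_site * DEBYE  # C·m
    vol_m3 = slab.cell_area * NM**2 * slab.slab_thickness * NM
    return mu_cm / vol_m3


def membrane_voltage(
    mu_debye: float, area_nm2: float, eps: float = 78.0, orientation: int = 1
) -> float:
    """Potential step (mV) across a uniform dipole sheet.

    ``mu_debye`` per lattice site over ``area_nm2`` per site; ``eps`` is
    the relative permittivity of the surrounding medium.  Independent of
    slab thickness.  With orientation +1 (N-terminus up, dipole along
    +z) the reported voltage is negative.
    """
    if area_nm2 <= 0:
        raise ValueError("cell area must be > 0")
    if orientation not in (-1, 1):
        raise ValueError("orientation must be +1 or -1")
    sheet_density = mu_debye * DEBYE / (area_nm2 * NM**2)  # C/m
    dv_volt = -orientation * sheet_density / (EPS0 * eps)
    return dv_volt * 1e3


def checkerboard_voltage(mu_debye: float, area_nm2: float, eps: float = 78.0) -> float:
    """Net sheet voltage of an antiparallel checkerboard lattice (mV).

    Half the sites point up and half down: the two sublattice sheets
    cancel exactly.
    """
    up = membrane_voltage(mu_debye, 2.0 * area_nm2, eps, orientation=1)
    down = membrane_voltage(mu_debye, 2.0 * area_nm2, eps, orientation=-1)
    return up + down


def piezo_curve(
    edge_length: float,
    theta_values: Sequence[float],
    mu_debye: float = 1200.0,
    eps: float = 78.0,
    slab_thickness: float = 4.5,
    orientation: int = 1,
) -> pd.DataFrame:
    """Voltage-conformation (piezoelectric) response of a polar lattice.

    Sweeps the rotating-squares opening angle and reports, per
    conformation: spacing d (nm), cell area A (nm^2), area ratio,
    polarization density rho_mu (C/m^2), and sheet voltage dV (mV).
    |dV| decreases strictly as the lattice opens (A grows).
    """
    rows = []
    for theta in theta_values:
        d, area, ratio = conformation_geometry(edge_length, theta)
        slab = PolarizedSlab(
            dipole_per_site=mu_debye,
            cell_area=area,
            slab_thickness=slab_thickness,
            relative_permittivity=eps,
            orientation=orientation,
        )
        rows.append(
            {
                "theta_deg": float(theta),
                "d_nm": d,
                "A_nm2": area,
                "A_over_A0": ratio,
                "rho_mu_C_m2": polarization_density(slab),
                "dV_mV": membrane_voltage(mu_debye, area, eps, orientation),
            }
        )
    return pd.DataFrame(rows)


def bound_charge(rho_mu: float, total_area_nm2: float) -> float:
    """Bound surface charge (in elementary charges) separated by a slab of
    polarization density ``rho_mu`` (C/m^2) over ``total_area_nm2``.

    The surface bound-charge density of a uniformly polarized slab equals
    the polarization density, so Q = rho_mu * area.
    """
    if rho_mu < 0 or total_area_nm2 <= 0:
        raise ValueError("inputs must be positive")
    return rho_mu * total_area_nm2 * NM**2 / E_CHARGE
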