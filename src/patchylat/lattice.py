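"""Rotating-squares lattice geometry and plane-group dipole patterns.

The 2D crystals are corner-hinged arrays of rigid squares (edge L) whose
correlated counter-rotations open or close the lattice — an auxetic
mechanism with Poisson ratio -1.  An opening angle theta in [0, 45] deg
sets the lattice spacing

    d = L (cos theta + sin theta)

so the unit-cell area A = d^2 relative to the closed state A0 = L^2 is
(cos theta + sin theta)^2, ranging from 1 (closed) to 2 (fully open).

Two plane-group symmetries are supported for the out-of-plane dipole
pattern: p4 (all dipoles parallel, a polar crystal) and p42_1 2
(checkerboard up/down, nonpolar).  Nearest-neighbour sums of the reduced
screened pair potential quantify how much the antiparallel arrangement
is favoured as the lattice grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .electrostatics import Electrolyte, PatchyParticleModel, pair_energy_reduced

__all__ = [
    "LatticeConformation",
    "LatticeSites",
    "conformation_geometry",
    "generate_sites",
    "site_interaction_energy",
    "lattice_energy_per_monomer",
    "symmetry_preference_curve",
]

_SYMMETRIES = ("p4", "p4212")


def conformation_geometry(edge_length: float, opening_angle: float) -> tuple[float, float, float]:
    """Spacing d (nm), cell area A (nm^2), and area ratio A/A0 for a
    rotating-squares lattice of edge ``edge_length`` (nm) opened by
    ``opening_angle`` degrees.
    """
    if not 0.0 <= opening_angle <= 45.0:
        raise ValueError("opening angle must lie in [0, 45] degrees")
    if edge_length <= 0:
        raise ValueError("edge length must be > 0")
    t = np.deg2rad(opening_angle)
    d = edge_length * (np.cos(t) + np.sin(t))
    return float(d), float(d**2), float((np.cos(t) + np.sin(t)) ** 2)


@dataclass(frozen=True)
class LatticeConformation:
    """A rotating-squares lattice state.

    ``hinge_scale`` exposes the conventional hinge angle alpha as an
    affine alias of the opening angle (alpha = hinge_scale * theta,
    default 2); geometry is always computed from theta directly.
    """

    edge_length: float  # nm
    opening_angle: float  # degrees, in [0, 45]
    symmetry: str = "p4212"
    hinge_scale: float = 2.0

    def __post_init__(self) -> None:
        conformation_geometry(self.edge_length, self.opening_angle)  # validates
        if self.symmetry not in _SYMMETRIES:
            raise ValueError(f"symmetry must be one of {_SYMMETRIES}")

    @property
    def hinge_angle(self) -> float:
        return self.hinge_scale * self.opening_angle

    @property
    def spacing_nm(self) -> float:
        return conformation_geometry(self.edge_length, self.opening_angle)[0]

    @property
    def cell_area_nm2(self) -> float:
        return conformation_geometry(self.edge_length, self.opening_angle)[1]

    @property
    def area_ratio(self) -> float:
        return conformation_geometry(self.edge_length, self.opening_angle)[2]


@dataclass
class LatticeSites:
    """Site positions (nm), alternating in-plane rotations, and
    out-of-plane dipole signs of a finite crystal patch."""

    positions: np.ndarray  # (n, 2) nm
    in_plane_rotation: np.ndarray  # (n,) degrees, +/- theta checkerboard
    dipole_sign: np.ndarray  # (n,) +1 / -1
    spacing: float  # nm
    symmetry: str
    shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.positions)

    def is_interior(self) -> np.ndarray:
        """Mask of sites with a full shell of 4 nearest neighbours."""
        nx, ny = self.shape
        i = np.arange(len(self)) % nx
        j = np.arange(len(self)) // nx
        return (i > 0) & (i < nx - 1) & (j > 0) & (j < ny - 1)


def generate_sites(conformation: LatticeConformation, nx: int, ny: int) -> LatticeSites:
    """Square grid of nx*ny sites with spacing d.

    In-plane rotations alternate +theta / -theta on the two checkerboard
    sublattices.  Dipole signs are all +1 for p4; for p42_1 2 they follow
    the checkerboard: nearest neighbours antiparallel, diagonal
    neighbours parallel.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    d = conformation.spacing_nm
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    ii = ii.ravel()
    jj = jj.ravel()
    positions = np.column_stack([ii * d, jj * d]).astype(float)
    parity = (ii + jj) % 2
    rotations = np.where(parity == 0, conformation.opening_angle, -conformation.opening_angle)
    if conformation.symmetry == "p4":
        signs = np.ones(len(positions), dtype=int)
    else:
        signs = np.where(parity == 0, 1, -1)
    return LatticeSites(
        positions=positions,
        in_plane_rotation=rotations.astype(float),
        dipole_sign=signs,
        spacing=float(d),
        symmetry=conformation.symmetry,
        shape=(nx, ny),
    )


def _pair_terms(sites: LatticeSites, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Distances (nm) and dihedral angles (deg) for site pairs within cutoff."""
    pos = sites.positions
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu, ju = np.triu_indices(len(pos), k=1)
    keep = dist[iu, ju] <= cutoff + 1e-12
    iu, ju = iu[keep], ju[keep]
    dphi = np.where(sites.dipole_sign[iu] == sites.dipole_sign[ju], 0.0, 180.0)
    return dist[iu, ju], dphi


def site_interaction_energy(
    sites: LatticeSites,
    index: int,
    particle: PatchyParticleModel,
    solvent: Electrolyte,
    cutoff: float,
) -> float:
    """Total interaction energy (kcal/mol) of one site with all sites
    within ``cutoff`` (nm) — the attachment energy of a monomer joining
    the patch at that position."""
    pos = sites.positions
    diff = pos - pos[index]
    dist = np.sqrt((diff**2).sum(axis=-1))
    mask = (dist > 0) & (dist <= cutoff + 1e-12)
    total = 0.0
    for j in np.flatnonzero(mask):
        dphi = 0.0 if sites.dipole_sign[index] == sites.dipole_sign[j] else 180.0
        total += pair_energy_reduced(dist[j], dphi, particle, solvent)
    return total


def lattice_energy_per_monomer(
    sites: LatticeSites,
    particle: PatchyParticleModel,
    solvent: Electrolyte,
    cutoff: float,
) -> float:
    """Pairwise lattice energy per monomer (kcal/mol).

    Sums the reduced pair potential over all site pairs within ``cutoff``
    and divides by the number of sites, i.e. every pair is shared
    half-and-half between its two members.  Charge–charge repulsion is
    included, so absolute values are meaningful; it cancels exactly in
    p4 - p42_1 2 differences.
    """
    if cutoff < sites.spacing:
        raise ValueError("cutoff must be at least the lattice spacing")
    if len(sites) == 1:
        return 0.0
    dist, dphi = _pair_terms(sites, cutoff)
    total = sum(
        pair_energy_reduced(r, p, particle, solvent) for r, p in zip(dist, dphi)
    )
    return total / len(sites)


def symmetry_preference_curve(
    d_values: Sequence[float],
    particle: PatchyParticleModel,
    solvent: Electrolyte,
    neighbours: int = 4,
) -> pd.DataFrame:
    """Energy preference for antiparallel packing versus lattice spacing.

    For each spacing d, an interior monomer surrounded by its 4 nearest
    neighbours gains Delta E = E(p4) - E(p42_1 2) = ``neighbours`` times
    the single-pair parallel/antiparallel gap at separation d (the
    charge term cancels).  Returns a DataFrame with columns ``d_nm`` and
    ``dE_kcal_mol``; entries are positive and decrease with d in the
    screened regime.
    """
    d_values = np.asarray(d_values, dtype=float)
    if np.any(d_values <= 0):
        raise ValueError("spacings must be > 0")
    gaps = [
        neighbours
        * (
            pair_energy_reduced(d, 0.0, particle, solvent)
            - pair_energy_reduced(d, 180.0, particle, solvent)
        )
        for d in d_values
    ]
    return pd.DataFrame({"d_nm": d_values, "dE_kcal_mol": gaps})
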