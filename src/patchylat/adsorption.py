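"""Random-adsorption null model for second-layer lattice occupancy.

Monomers adsorbing onto a crystalline monolayer occupy discrete lattice
sites.  If adsorption were random — no energetic preference for sites
next to already-adsorbed neighbours — sites would be occupied
independently with probability theta (the observed coverage), and the
expected fraction of *isolated* occupied sites (no occupied nearest
neighbour) on the interior of a square lattice would be

    f_iso = theta * (1 - theta)^z

with z = 4 for a von Neumann neighbourhood (z = 8 for Moore).  Observed
isolated-monomer coverages far below this null indicate cooperative,
bond-mediated attachment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OccupancyField",
    "random_occupancy",
    "isolated_coverage",
    "expected_isolated_coverage",
    "isolation_ratio",
]

_NEIGHBORHOODS = {"von_neumann": 4, "moore": 8}


@dataclass
class OccupancyField:
    """Boolean occupancy grid with its neighbourhood convention."""

    occupied: np.ndarray
    neighborhood: str = "von_neumann"
    periodic: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.occupied.ndim != 2:
            raise ValueError("occupancy grid must be 2D")
        if self.neighborhood not in _NEIGHBORHOODS:
            raise ValueError(f"neighborhood must be one of {tuple(_NEIGHBORHOODS)}")

    @property
    def coverage(self) -> float:
        return float(self.occupied.mean())

    @property
    def z(self) -> int:
        return _NEIGHBORHOODS[self.neighborhood]


def random_occupancy(
    n_x: int,
    n_y: int,
    theta: float,
    seed: int,
    neighborhood: str = "von_neumann",
    periodic: bool = False,
) -> OccupancyField:
    """Occupy each of n_x * n_y sites independently with probability theta."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    if n_x < 1 or n_y < 1:
        raise ValueError("grid dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    grid = rng.random((n_y, n_x)) < theta
    return OccupancyField(grid, neighborhood=neighborhood, periodic=periodic, seed=seed)


def _neighbor_count(occ: np.ndarray, neighborhood: str, periodic: bool) -> np.ndarray:
    occ_i = occ.astype(int)
    shifts = [(0, 1), (0, -1), (1, 0), (-1, 0)]
    if neighborhood == "moore":
        shifts += [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    counts = np.zeros_like(occ_i)
    for dy, dx in shifts:
        if periodic:
            counts += np.roll(np.roll(occ_i, dy, axis=0), dx, axis=1)
        else:
            shifted = np.zeros_like(occ_i)
            src_y = slice(max(0, -dy), occ.shape[0] - max(0, dy))
            dst_y = slice(max(0, dy), occ.shape[0] - max(0, -dy))
            src_x = slice(max(0, -dx), occ.shape[1] - max(0, dx))
            dst_x = slice(max(0, dx), occ.shape[1] - max(0, -dx))
            shifted[dst_y, dst_x] = occ_i[src_y, src_x]
            counts += shifted
    return counts


def isolated_coverage(field: OccupancyField) -> float:
    """Fraction of all sites that are occupied with zero occupied neighbours.

    Non-periodic fields count only neighbours that exist, so edge sites
    need fewer empty surroundings to qualify as isolated.
    """
    counts = _neighbor_count(field.occupied, field.neighborhood, field.periodic)
    isolated = field.occupied & (counts == 0)
    return float(isolated.mean())


def expected_isolated_coverage(theta: float, z: int = 4) -> float:
    """Closed-form isolated fraction theta*(1-theta)^z for independent
    occupancy with z interior neighbours."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    return theta * (1.0 - theta) ** z


def isolation_ratio(expected: float, observed: float) -> float:
    """Fold difference between the random-adsorption expectation and the
    observed isolated coverage; large values signal cooperative growth."""
    if observed <= 0:
        raise ValueError("observed coverage must be > 0")
    return expected / observed
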