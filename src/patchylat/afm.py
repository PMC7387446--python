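"""Simulated AFM topographs of atomic models with a rigid tip.

The probe is a hard sphere of radius R (apex) capped by a truncated
cone of half-angle beta opening upward.  The cone flank rises from the
circle where it crosses the apex sphere — lateral radius
``R cos(beta)`` at height ``R sin(beta)`` above the sphere center
``z_tip`` — so the tip cross-section at and below the apex-center
height is the sphere alone.  The support plane z = 0 is impenetrable
and atoms are points unless given per-atom radii (which inflate the
effective tip radius for that atom).

For each raster node the recorded height is ``z_tip* - R`` floored at 0,
where ``z_tip*`` is the lowest apex height at which the number of atoms
strictly inside the tip volume does not exceed ``overlap_threshold``
(the tip descends from above; a nonzero threshold lets the tip ignore
that many atoms, emulating compliant disordered loops).  The resulting
image is the grayscale dilation of the atom set by the reflected tip,
which reproduces tip-convolution artifacts: features appear broadened
by up to the apex radius plus the cone flare.

The scanner inverts the contact condition in closed form per atom:

* apex sphere: first contact at ``z_a + sqrt(R_eff^2 - rho^2)`` for
  lateral offset rho < R_eff;
* cone flank: first contact at
  ``z_a - R_eff sin(beta) - max(0, rho - R_eff cos(beta)) / tan(beta)``
  for rho inside the cone's maximal (truncated) footprint.

A brute-force oracle (:func:`dilation_oracle`) recovers the same image
by bisecting the boolean overlap predicate itself, providing an
algebra-free cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structures import AtomCollection

__all__ = [
    "TipModel",
    "ScanGrid",
    "HeightMap",
    "tip_overlap_count",
    "scan_topograph",
    "dilation_oracle",
    "average_topograph",
    "write_heightmap",
    "read_heightmap",
]


@dataclass(frozen=True)
class TipModel:
    """Sphere-apex/truncated-cone tip.  Lengths in Å, angle in degrees.

    ``z_cutoff`` is the cone truncation height above the apex-sphere
    center; the default (60 Å) is taller than any single-layer protein
    scene, so truncation never matters there.
    """

    apex_radius: float = 10.0
    cone_half_angle: float = 20.0
    z_cutoff: float = 60.0
    overlap_threshold: int = 0

    def __post_init__(self) -> None:
        if self.apex_radius <= 0:
            raise ValueError("apex_radius must be > 0")
        if not 0.0 < self.cone_half_angle < 90.0:
            raise ValueError("cone_half_angle must lie in (0, 90) degrees")
        if self.z_cutoff < self.apex_radius:
            raise ValueError("z_cutoff must be at least the apex radius")
        if self.overlap_threshold < 0:
            raise ValueError("overlap_threshold must be >= 0")


@dataclass(frozen=True)
class ScanGrid:
    """Raster window [x_min, x_max] x [y_min, y_max] sampled every ``step`` Å.

    Nodes sit at x_min + i*step inclusive of both edges when the extent
    is commensurate with the step.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    step: float = 0.50

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("scan window must have positive extent")

    @property
    def x_values(self) -> np.ndarray:
        n = int(np.floor((self.x_max - self.x_min) / self.step + 1e-9)) + 1
        return self.x_min + self.step * np.arange(n)

    @property
    def y_values(self) -> np.ndarray:
        n = int(np.floor((self.y_max - self.y_min) / self.step + 1e-9)) + 1
        return self.y_min + self.step * np.arange(n)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) = (len(y), len(x))."""
        return len(self.y_values), len(self.x_values)


@dataclass
class HeightMap:
    """A rasterized topograph: heights in Å, row index along y."""

    values: np.ndarray
    grid: ScanGrid
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("height array shape does not match the grid")
        if np.any(self.values < 0):
            raise ValueError("heights must be >= 0")


def _heavy_point_data(atoms: AtomCollection) -> tuple[np.ndarray, np.ndarray]:
    heavy = atoms.heavy()
    return heavy.coords, heavy.radii


def _overlaps(
    tip: TipModel,
    rho: np.ndarray,
    z_atom: np.ndarray,
    z_tip: np.ndarray,
    r_atom: np.ndarray,
) -> np.ndarray:
    """Strict-interior membership of atom centers in the tip volume.

    Broadcasts over any common shape.  Tangency does not count as
    overlap, which makes the first-contact height an attained infimum.
    """
    r_eff = tip.apex_radius + r_atom
    beta = np.deg2rad(tip.cone_half_angle)
    dz = z_atom - z_tip
    in_sphere = rho**2 + dz**2 < r_eff**2
    join_z = r_eff * np.sin(beta)  # sphere/cone crossing circle, above z_tip
    cone_radius = r_eff * np.cos(beta) + (dz - join_z) * np.tan(beta)
    in_cone = (dz > join_z) & (dz < tip.z_cutoff) & (rho < cone_radius)
    return in_sphere | in_cone


def tip_overlap_count(tip: TipModel, tip_position, atoms: AtomCollection) -> int:
    """Number of heavy atoms strictly inside the tip at ``tip_position``
    = (x, y, z_tip) in Å."""
    x, y, z_tip = tip_position
    coords, radii = _heavy_point_data(atoms)
    if len(coords) == 0:
        return 0
    rho = np.hypot(coords[:, 0] - x, coords[:, 1] - y)
    return int(np.sum(_overlaps(tip, rho, coords[:, 2], np.float64(z_tip), radii)))


def _contact_heights(
    tip: TipModel, rho: np.ndarray, z_atom: np.ndarray, r_atom: np.ndarray
) -> np.ndarray:
    """Closed-form first-contact z_tip per (node, atom) pair; -inf when the
    descending tip can never touch the atom at that lateral offset."""
    r_eff = tip.apex_radius + r_atom
    beta = np.deg2rad(tip.cone_half_angle)
    sin_b, cos_b, tan_b = np.sin(beta), np.cos(beta), np.tan(beta)

    with np.errstate(invalid="ignore"):
        u_sphere = z_atom + np.sqrt(r_eff**2 - rho**2)
    u_sphere = np.where(rho < r_eff, u_sphere, -np.inf)

    rho_max = r_eff * cos_b + (tip.z_cutoff - r_eff * sin_b) * tan_b
    u_cone = z_atom - r_eff * sin_b - np.maximum(0.0, rho - r_eff * cos_b) / tan_b
    u_cone = np.where(rho < rho_max, u_cone, -np.inf)

    return np.maximum(u_sphere, u_cone)


def _heights_from_contacts(contacts: np.ndarray, tip: TipModel) -> np.ndarray:
    """Per-node recorded height from the (nodes, atoms) contact matrix,
    honouring the overlap threshold: the tip settles at the (k+1)-th
    highest first-contact height, ignoring the k most obstructive atoms."""
    n_nodes, n_atoms = contacts.shape
    k = tip.overlap_threshold
    if n_atoms <= k:
        return np.zeros(n_nodes)
    part = np.sort(contacts, axis=1)
    z_settle = part[:, n_atoms - 1 - k]
    return np.maximum(0.0, z_settle - tip.apex_radius)


def scan_topograph(atoms: AtomCollection, tip: TipModel, grid: ScanGrid) -> HeightMap:
    """Raster-scan the structure and return the simulated topograph.

    Atoms should be grounded (support plane at z = 0); hydrogens are
    excluded.  An empty structure yields an all-zero map with a warning.
    """
    coords, radii = _heavy_point_data(atoms)
    ny, nx = grid.shape
    if len(coords) == 0:
        warnings.warn("scanning an empty structure: returning a flat map")
        return HeightMap(np.zeros((ny, nx)), grid, provenance="scan:empty")
    xs = grid.x_values
    ys = grid.y_values
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    rho = np.hypot(
        nodes[:, 0:1] - coords[None, :, 0], nodes[:, 1:2] - coords[None, :, 1]
    )
    contacts = _contact_heights(tip, rho, coords[None, :, 2], radii[None, :])
    heights = _heights_from_contacts(contacts, tip).reshape(ny, nx)
    return HeightMap(
        heights,
        grid,
        provenance=(
            f"scan:R={tip.apex_radius},beta={tip.cone_half_angle},"
            f"zcut={tip.z_cutoff},thr={tip.overlap_threshold}"
        ),
    )


def dilation_oracle(
    atoms: AtomCollection, tip: TipModel, grid: ScanGrid, tol: float = 1e-12
) -> HeightMap:
    """Brute-force reference image via bisection on the overlap predicate.

    For every (node, atom) pair the first-contact apex height is located
    by bisecting the boolean strict-interior test between a height known
    to overlap and one known to clear; no contact algebra is reused from
    :func:`scan_topograph`.  The per-node height is then the same
    order-statistic reduction of the per-atom contacts.
    """
    coords, radii = _heavy_point_data(atoms)
    ny, nx = grid.shape
    if len(coords) == 0:
        return HeightMap(np.zeros((ny, nx)), grid, provenance="oracle:empty")
    xs, ys = grid.x_values, grid.y_values
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    rho = np.hypot(
        nodes[:, 0:1] - coords[None, :, 0], nodes[:, 1:2] - coords[None, :, 1]
    )
    z_atom = np.broadcast_to(coords[None, :, 2], rho.shape)
    r_atom = np.broadcast_to(radii[None, :], rho.shape)
    r_eff = tip.apex_radius + r_atom

    # A tip this high clears the atom through both the sphere and the cone.
    hi = z_atom + r_eff + 1.0
    # Candidate interior points: apex centered on the atom, else the atom
    # near the truncated top of the cone.
    lo_apex = z_atom.copy()
    lo_cone = z_atom - tip.z_cutoff + 1e-9
    apex_ok = _overlaps(tip, rho, z_atom, lo_apex, r_atom)
    cone_ok = _overlaps(tip, rho, z_atom, lo_cone, r_atom)
    lo = np.where(apex_ok, lo_apex, lo_cone)
    touchable = apex_ok | cone_ok

    lo = np.where(touchable, lo, 0.0)
    hi_work = np.where(touchable, hi, 1.0)
    for _ in range(64):
        mid = 0.5 * (lo + hi_work)
        inside = _overlaps(tip, rho, z_atom, mid, r_atom)
        lo = np.where(inside, mid, lo)
        hi_work = np.where(inside, hi_work, mid)
        if np.max(hi_work - lo) < tol:
            break
    contacts = np.where(touchable, 0.5 * (lo + hi_work), -np.inf)
    heights = _heights_from_contacts(contacts, tip).reshape(ny, nx)
    return HeightMap(heights, grid, provenance="oracle:bisection")


def average_topograph(hmap: HeightMap, cell_x: float, cell_y: float) -> HeightMap:
    """Average a periodic topograph over its unit cells.

    ``cell_x``/``cell_y`` (Å) must be integer multiples of the grid step
    and divide the map dimensions exactly; the result is a single
    cell-sized map equal to the mean over all cells.
    """
    step = hmap.grid.step
    ncx = cell_x / step
    ncy = cell_y / step
    if abs(ncx - round(ncx)) > 1e-9 or abs(ncy - round(ncy)) > 1e-9:
        raise ValueError("cell dimensions must be integer multiples of the grid step")
    ncx, ncy = int(round(ncx)), int(round(ncy))
    ny, nx = hmap.values.shape
    if nx % ncx != 0 or ny % ncy != 0:
        raise ValueError("cell does not tile the map an integer number of times")
    tiles = hmap.values.reshape(ny // ncy, ncy, nx // ncx, ncx)
    cell = tiles.mean(axis=(0, 2))
    sub = ScanGrid(
        x_min=hmap.grid.x_min,
        x_max=hmap.grid.x_min + (ncx - 1) * step if ncx > 1 else hmap.grid.x_min + step / 2,
        y_min=hmap.grid.y_min,
        y_max=hmap.grid.y_min + (ncy - 1) * step if ncy > 1 else hmap.grid.y_min + step / 2,
        step=step,
    )
    return HeightMap(cell, sub, provenance=hmap.provenance + "|cell-averaged")


_FORMATS = ("tsv", "ascii-matrix", "tiff")


def write_heightmap(hmap: HeightMap, path, fmt: str = "tsv") -> None:
    """Export a topograph; heights are written in nm.

    ``tsv``/``ascii-matrix`` are plain-text matrices with ``#`` header
    lines carrying the lateral extents in nm (importable by common SPM
    software such as Gwyddion).  ``tiff`` writes a 16-bit image plus a
    ``<path>.scale.txt`` sidecar recording the linear height scaling.
    """
    if fmt not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}")
    values_nm = hmap.values / 10.0
    width_nm = (hmap.grid.x_max - hmap.grid.x_min) / 10.0
    height_nm = (hmap.grid.y_max - hmap.grid.y_min) / 10.0
    if fmt in ("tsv", "ascii-matrix"):
        header = (
            f"Channel: simulated topography ({hmap.provenance})\n"
            f"Width: {width_nm:.6g} nm\n"
            f"Height: {height_nm:.6g} nm\n"
            f"Value units: nm"
        )
        delim = "\t" if fmt == "tsv" else " "
        np.savetxt(path, values_nm, fmt="%.17g", delimiter=delim, header=header)
    else:
        import tifffile

        vmin = float(values_nm.min())
        vmax = float(values_nm.max())
        scale = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
        quantized = np.round((values_nm - vmin) / scale).astype(np.uint16)
        tifffile.imwrite(str(path), quantized)
        with open(str(path) + ".scale.txt", "w") as fh:
            fh.write(
                "linear height scaling: value_nm = offset_nm + scale_nm * pixel\n"
                f"offset_nm: {vmin!r}\nscale_nm: {scale!r}\n"
                f"provenance: {hmap.provenance}\n"
            )


def read_heightmap(path, grid: Optional[ScanGrid] = None) -> np.ndarray:
    """Read back a text-format height map; returns heights in Å."""
    values_nm = np.loadtxt(path)
    return np.atleast_2d(values_nm) * 10.0
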