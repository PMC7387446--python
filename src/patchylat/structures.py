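"""Atomic models: PDB I/O, frame normalization, macrodipoles, and fixtures.

The sample frame convention is right-handed with the support (mica) plane
at z = 0 and the sample occupying z >= 0.  Structures are "grounded" by
recentering the xy centroid at the origin and translating along +z until
the lowest C-alpha atom sits exactly on the support plane; structures
without C-alpha atoms (e.g. synthetic particles) fall back to the
all-atom minimum, which is recorded in ``frame_note``.

Macrodipole moments are computed from per-atom partial charges, excluding
hydrogens, and reported in debye (1 e·Å = 4.8032 D).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .units import EA_TO_DEBYE

__all__ = [
    "AtomCollection",
    "SyntheticParticleSpec",
    "read_structure",
    "write_structure",
    "ground_structure",
    "macrodipole",
    "assign_formal_charges",
    "make_synthetic_particle",
    "tile_lattice",
]


@dataclass
class AtomCollection:
    """An ordered set of atoms with optional charges and radii.

    Coordinates are in Å.  ``partial_charges`` (elementary charges) is
    ``None`` until a charge scheme has been assigned; ``radii`` default to
    zero, i.e. point atoms.
    """

    coords: np.ndarray
    elements: np.ndarray
    is_hydrogen: np.ndarray
    is_calpha: np.ndarray
    partial_charges: Optional[np.ndarray] = None
    radii: Optional[np.ndarray] = None
    atom_names: Optional[np.ndarray] = None
    res_names: Optional[np.ndarray] = None
    chain_ids: Optional[np.ndarray] = None
    frame_note: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom positions must be finite")
        n = len(self.coords)
        self.elements = np.asarray(self.elements, dtype="U4")
        self.is_hydrogen = np.asarray(self.is_hydrogen, dtype=bool)
        self.is_calpha = np.asarray(self.is_calpha, dtype=bool)
        if self.radii is None:
            self.radii = np.zeros(n)
        else:
            self.radii = np.asarray(self.radii, dtype=float)
            if np.any(self.radii < 0):
                raise ValueError("atom radii must be >= 0")
        for arr in (self.elements, self.is_hydrogen, self.is_calpha, self.radii):
            if len(arr) != n:
                raise ValueError("per-atom arrays must match coords length")
        if self.partial_charges is not None:
            self.partial_charges = np.asarray(self.partial_charges, dtype=float)
            if len(self.partial_charges) != n:
                raise ValueError("partial_charges must match coords length")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def heavy(self) -> "AtomCollection":
        """Return the heavy-atom (non-hydrogen) subset."""
        return self.subset(~self.is_hydrogen)

    def subset(self, mask: np.ndarray) -> "AtomCollection":
        sel = np.asarray(mask)
        return AtomCollection(
            coords=self.coords[sel],
            elements=self.elements[sel],
            is_hydrogen=self.is_hydrogen[sel],
            is_calpha=self.is_calpha[sel],
            partial_charges=None if self.partial_charges is None else self.partial_charges[sel],
            radii=self.radii[sel],
            atom_names=None if self.atom_names is None else self.atom_names[sel],
            res_names=None if self.res_names is None else self.res_names[sel],
            chain_ids=None if self.chain_ids is None else self.chain_ids[sel],
            frame_note=self.frame_note,
        )

    def translated(self, shift) -> "AtomCollection":
        return replace(self, coords=self.coords + np.asarray(shift, dtype=float))


@dataclass(frozen=True)
class SyntheticParticleSpec:
    """Geometry of the C4-symmetric dummy particle used as a test sample.

    The particle mimics a squat, four-fold symmetric protein: a flat,
    uniformly charged square plate on top and four legs at the bottom
    corners leaving a central dip between them.  Charges are placed on
    the top plate (at z = ``height``) and on the four leg feet (z = 0),
    so the macrodipole is exactly ``top_charge * height`` e·Å along z.

    Dimensions in Å, charges in elementary charges.
    """

    height: float = 45.0
    top_width: float = 60.0
    leg_length: float = 15.0
    leg_spacing: float = 30.0
    top_charge: float = -8.0
    bottom_charge: float = 8.0
    atoms_per_feature: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("height", "top_width", "leg_length", "leg_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.atoms_per_feature < 4:
            raise ValueError("atoms_per_feature must be >= 4")
        if self.leg_length >= self.height:
            raise ValueError("leg_length must be smaller than the particle height")


def read_structure(path, model_index: int = 1) -> AtomCollection:
    """Read a (possibly multi-model) PDB file into an :class:`AtomCollection`.

    ``model_index`` is 1-based, matching PDB MODEL records.  Hydrogens are
    retained but flagged; downstream imaging and dipole operations filter
    them out themselves.
    """
    pdb = bpdb.PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError(f"no atoms found in {path}")
    if not 1 <= model_index <= n_models:
        raise IndexError(
            f"model_index {model_index} out of range (file has {n_models} model(s))"
        )
    atoms = pdb.get_structure(model=model_index)
    if atoms.array_length() == 0:
        raise ValueError(f"model {model_index} of {path} contains no atoms")
    elements = np.char.capitalize(atoms.element)
    is_h = elements == "H"
    is_ca = (atoms.atom_name == "CA") & (elements == "C")
    return AtomCollection(
        coords=atoms.coord,
        elements=elements,
        is_hydrogen=is_h,
        is_calpha=is_ca,
        radii=np.zeros(atoms.array_length()),
        atom_names=atoms.atom_name.copy(),
        res_names=atoms.res_name.copy(),
        chain_ids=atoms.chain_id.copy(),
        frame_note="as-read",
    )


def write_structure(atoms: AtomCollection, path) -> None:
    """Write the collection to a single-model PDB file."""
    n = atoms.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(atoms.coords, dtype=np.float32)
    arr.element = atoms.elements
    arr.atom_name = atoms.atom_names if atoms.atom_names is not None else atoms.elements
    arr.res_name = atoms.res_names if atoms.res_names is not None else np.full(n, "UNK")
    arr.chain_id = atoms.chain_ids if atoms.chain_ids is not None else np.full(n, "A")
    arr.res_id = np.arange(1, n + 1)
    arr.hetero = np.full(n, True)
    pdb = bpdb.PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def ground_structure(atoms: AtomCollection) -> AtomCollection:
    """Recenter at (x=0, y=0) and rest the structure on the z = 0 plane.

    The vertical reference is the minimum z over C-alpha atoms; if the
    collection has none, the all-atom minimum is used and noted in
    ``frame_note``.
    """
    if atoms.n_atoms == 0:
        raise ValueError("cannot ground an empty collection")
    centroid = atoms.coords.mean(axis=0)
    if np.any(atoms.is_calpha):
        z_ref = atoms.coords[atoms.is_calpha, 2].min()
        note = "grounded:calpha"
    else:
        z_ref = atoms.coords[:, 2].min()
        note = "grounded:all-atom"
    shifted = atoms.coords + np.array([-centroid[0], -centroid[1], -z_ref])
    return replace(atoms, coords=shifted, frame_note=note)


def macrodipole(atoms: AtomCollection) -> np.ndarray:
    """Macrodipole moment vector in debye.

    Sums q_i * r_i over heavy atoms about the |q|-weighted charge
    centroid (the choice of origin is immaterial for net-neutral
    collections).  Hydrogens are excluded from the sum.

    Raises if any included atom lacks a partial charge.
    """
    if atoms.n_atoms == 0:
        raise ValueError("empty collection has no dipole")
    if atoms.partial_charges is None:
        raise ValueError("partial charges have not been assigned")
    heavy = atoms.heavy()
    q = heavy.partial_charges
    if np.any(~np.isfinite(q)):
        raise ValueError("some heavy atoms have non-finite partial charges")
    w = np.abs(q)
    if w.sum() == 0:
        return np.zeros(3)
    origin = (w[:, None] * heavy.coords).sum(axis=0) / w.sum()
    mu_ea = (q[:, None] * (heavy.coords - origin)).sum(axis=0)  # e·Å
    return mu_ea * EA_TO_DEBYE


# Side-chain charge-center atoms for the integer formal-charge scheme at pH 7.
_SIDECHAIN_CHARGES = {
    ("ASP", "CG"): -1.0,
    ("GLU", "CD"): -1.0,
    ("LYS", "NZ"): +1.0,
    ("ARG", "CZ"): +1.0,
}


def assign_formal_charges(atoms: AtomCollection, termini: bool = True) -> AtomCollection:
    """Assign integer formal charges at pH 7 to a protein structure.

    Asp/Glu carry -1 and Lys/Arg +1, placed on their side-chain charge
    centers; His is neutral.  With ``termini``, the first backbone N of
    each chain gets +1 and the last backbone C gets -1.  All other atoms
    get zero.  This coarse scheme approximates a force-field charge set
    only at the level of the overall charge anisotropy.
    """
    if atoms.atom_names is None or atoms.res_names is None:
        raise ValueError("atom and residue names are required for charge assignment")
    q = np.zeros(atoms.n_atoms)
    for i in range(atoms.n_atoms):
        key = (str(atoms.res_names[i]).upper(), str(atoms.atom_names[i]).upper())
        if key in _SIDECHAIN_CHARGES:
            q[i] = _SIDECHAIN_CHARGES[key]
    if termini and atoms.chain_ids is not None:
        for chain in np.unique(atoms.chain_ids):
            idx = np.flatnonzero(atoms.chain_ids == chain)
            n_idx = [i for i in idx if str(atoms.atom_names[i]).upper() == "N"]
            c_idx = [i for i in idx if str(atoms.atom_names[i]).upper() == "C"]
            if n_idx:
                q[n_idx[0]] += 1.0
            if c_idx:
                q[c_idx[-1]] -= 1.0
    return replace(atoms, partial_charges=q)


def make_synthetic_particle(spec: SyntheticParticleSpec = SyntheticParticleSpec()) -> AtomCollection:
    """Build the C4-symmetric dummy particle described by ``spec``.

    The output is deterministic for a given spec, already grounded
    (legs at z = 0), made of point carbon atoms, and carries partial
    charges on the top plate and the leg feet.
    """
    k = max(2, int(round(np.sqrt(spec.atoms_per_feature))))
    lin = np.linspace(-spec.top_width / 2.0, spec.top_width / 2.0, k)
    gx, gy = np.meshgrid(lin, lin)
    top = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, spec.height)])

    n_leg = max(2, spec.atoms_per_feature // 4)
    zs = np.linspace(0.0, spec.leg_length, n_leg)
    half = spec.leg_spacing / 2.0
    legs = []
    for sx, sy in ((half, half), (half, -half), (-half, -half), (-half, half)):
        legs.append(np.column_stack([np.full(n_leg, sx), np.full(n_leg, sy), zs]))
    legs = np.vstack(legs)

    coords = np.vstack([top, legs])
    n = len(coords)
    q = np.zeros(n)
    q[: len(top)] = spec.top_charge / len(top)
    foot = np.flatnonzero(np.isclose(coords[len(top):, 2], 0.0)) + len(top)
    q[foot] = spec.bottom_charge / len(foot)
    return AtomCollection(
        coords=coords,
        elements=np.full(n, "C"),
        is_hydrogen=np.zeros(n, dtype=bool),
        is_calpha=np.zeros(n, dtype=bool),
        partial_charges=q,
        radii=np.zeros(n),
        frame_note="synthetic:c4-particle",
    )


def _rot_z(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# 180-degree rotation about the x axis; flips a copy upside down.
_FLIP_X = np.diag([1.0, -1.0, -1.0])


def tile_lattice(unit: AtomCollection, conformation, nx: int, ny: int) -> AtomCollection:
    """Tile ``unit`` into an nx-by-ny crystal patch.

    Sites form a square grid with the conformation's lattice spacing;
    in-plane rotations alternate +theta / -theta in a checkerboard, per
    the rotating-squares construction.  For p42(1)2 symmetry, copies on
    the odd checkerboard sublattice are additionally flipped upside down
    (180-degree rotation about x through the copy's bounding mid-height),
    giving the antiparallel up/down dipole arrangement; p4 leaves all
    copies parallel.  Each copy stays rigid.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    if unit.n_atoms == 0:
        raise ValueError("cannot tile an empty unit")
    d_ang = conformation.spacing_nm * 10.0  # nm -> Å
    theta = conformation.opening_angle
    centroid = unit.coords.mean(axis=0)
    z_mid = 0.5 * (unit.coords[:, 2].min() + unit.coords[:, 2].max())
    pieces = []
    charges = [] if unit.partial_charges is not None else None
    for j in range(ny):
        for i in range(nx):
            odd = (i + j) % 2 == 1
            rot = _rot_z(-theta if odd else theta)
            local = (unit.coords - centroid) @ rot.T
            if conformation.symmetry == "p4212" and odd:
                local = local @ _FLIP_X.T
            pos = local + centroid
            if conformation.symmetry == "p4212" and odd:
                # restore original vertical placement after the flip
                pos[:, 2] += z_mid - 0.5 * (pos[:, 2].min() + pos[:, 2].max())
            pos[:, 0] += i * d_ang
            pos[:, 1] += j * d_ang
            pieces.append(pos)
            if charges is not None:
                charges.append(unit.partial_charges)
    n_copies = nx * ny
    return AtomCollection(
        coords=np.vstack(pieces),
        elements=np.tile(unit.elements, n_copies),
        is_hydrogen=np.tile(unit.is_hydrogen, n_copies),
        is_calpha=np.tile(unit.is_calpha, n_copies),
        partial_charges=None if charges is None else np.concatenate(charges),
        radii=np.tile(unit.radii, n_copies),
        frame_note=f"tiled:{conformation.symmetry}:{nx}x{ny}",
    )
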