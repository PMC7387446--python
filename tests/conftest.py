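import numpy as np
import pytest

from patchylat import (
    AtomCollection,
    Electrolyte,
    PatchyParticleModel,
    make_synthetic_particle,
)


@pytest.fixture
def particle():
    """Solution-assembly particle: q = -16 e, mu = 1200 D, a = 4 nm."""
    return PatchyParticleModel(net_charge=-16.0, dipole_magnitude=1200.0, radius=4.0)


@pytest.fixture
def solvent():
    """eps = 78, T = 300 K, with the printed Debye length 2.1508 nm."""
    return Electrolyte(relative_permittivity=78.0, temperature=300.0,
                       ionic_strength=0.020, kappa_nm=1.0 / 2.1508)


@pytest.fixture
def synthetic_particle():
    return make_synthetic_particle()


def _pdb_line(serial, name, res, chain, resid, x, y, z, element):
    return (
        f"ATOM  {serial:>5d}  {name:<3s} {res:>3s} {chain}{resid:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def make_pdb_text(atoms, models=1):
    """atoms: list of (name, res, x, y, z, element)."""
    lines = []
    for m in range(1, models + 1):
        if models > 1:
            lines.append(f"MODEL     {m:>4d}")
        for i, (name, res, x, y, z, elem) in enumerate(atoms, start=1):
            # shift later models so the test can tell them apart
            lines.append(_pdb_line(i, name, res, "A", i, x + 10.0 * (m - 1), y, z, elem))
        if models > 1:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_factory(tmp_path):
    def write(atoms, models=1, name="fixture.pdb"):
        path = tmp_path / name
        path.write_text(make_pdb_text(atoms, models=models))
        return path

    return write


def random_scene(seed, n_max=50, window=30.0, z_max=20.0):
    """Random point-atom scene inside a window x window Å box."""
    rng = np.random.default_rng(seed)
    n = rng.integers(1, n_max + 1)
    coords = np.column_stack(
        [
            rng.uniform(-window / 2, window / 2, n),
            rng.uniform(-window / 2, window / 2, n),
            rng.uniform(0.0, z_max, n),
        ]
    )
    return AtomCollection(
        coords=coords,
        elements=np.full(n, "C"),
        is_hydrogen=np.zeros(n, dtype=bool),
        is_calpha=np.zeros(n, dtype=bool),
    )
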