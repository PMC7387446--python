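import numpy as np
import pytest
import scipy.ndimage as ndi

from patchylat import (
    AtomCollection,
    HeightMap,
    ScanGrid,
    TipModel,
    average_topograph,
    dilation_oracle,
    read_heightmap,
    scan_topograph,
    tip_overlap_count,
    write_heightmap,
)
from conftest import random_scene


def point_atoms(coords):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return AtomCollection(
        coords=coords,
        elements=np.full(n, "C"),
        is_hydrogen=np.zeros(n, dtype=bool),
        is_calpha=np.zeros(n, dtype=bool),
    )


TIP = TipModel(apex_radius=10.0, cone_half_angle=20.0)


class TestOverlapCount:
    def test_atom_at_sphere_center(self):
        atoms = point_atoms([[0, 0, 5]])
        assert tip_overlap_count(TIP, (0, 0, 5), atoms) == 1

    def test_atom_just_outside_sphere_below_cone(self):
        atoms = point_atoms([[0, 0, 0]])
        assert tip_overlap_count(TIP, (0, 0, 20.001), atoms) == 0

    def test_tangent_lateral_offset_not_counted(self):
        atoms = point_atoms([[10.0, 0, 5.0]])
        assert tip_overlap_count(TIP, (0, 0, 5.0), atoms) == 0

    def test_cone_flank_overlap_beyond_sphere(self):
        # atom 15 Å to the side, high up: inside the cone but not the sphere
        atoms = point_atoms([[15.0, 0.0, 30.0]])
        assert tip_overlap_count(TIP, (0, 0, 5.0), atoms) == 1

    def test_hydrogens_ignored(self):
        atoms = AtomCollection(
            coords=np.array([[0.0, 0.0, 5.0]]),
            elements=np.array(["H"]),
            is_hydrogen=np.array([True]),
            is_calpha=np.array([False]),
        )
        assert tip_overlap_count(TIP, (0, 0, 5), atoms) == 0


class TestScanTopograph:
    def test_bare_support_is_flat(self):
        atoms = point_atoms([[100.0, 100.0, 5.0]])  # far outside the window
        grid = ScanGrid(-5, 5, -5, 5, 0.5)
        hmap = scan_topograph(atoms, TIP, grid)
        assert np.all(hmap.values == 0.0)

    @pytest.mark.parametrize("rho,expected", [(0.0, 10.0), (6.0, 8.0), (8.0, 6.0)])
    def test_single_atom_spherical_cap(self, rho, expected):
        # apparent height max(0, h + sqrt(R^2 - rho^2) - R) for a point atom at h
        atoms = point_atoms([[0.0, 0.0, 10.0]])
        grid = ScanGrid(-10, 10, -10, 10, 0.5)
        hmap = scan_topograph(atoms, TIP, grid)
        iy = np.argmin(np.abs(grid.y_values))
        ix = np.argmin(np.abs(grid.x_values - rho))
        assert hmap.values[iy, ix] == pytest.approx(expected, abs=1e-9)

    def test_threshold_ignores_single_atom(self):
        atoms = point_atoms([[0.0, 0.0, 10.0]])
        tip = TipModel(overlap_threshold=1)
        grid = ScanGrid(-5, 5, -5, 5, 0.5)
        assert np.all(scan_topograph(atoms, tip, grid).values == 0.0)

    def test_threshold_equals_scan_without_limiting_atom(self):
        # two atoms stacked at the same xy: the upper one is the limiting
        # contact at every node, so threshold 1 must reproduce the scan of
        # the lower atom alone
        atoms = point_atoms([[0.0, 0.0, 15.0], [0.0, 0.0, 5.0]])
        grid = ScanGrid(-8, 8, -8, 8, 0.5)
        thresholded = scan_topograph(atoms, TipModel(overlap_threshold=1), grid)
        reduced = scan_topograph(point_atoms([[0.0, 0.0, 5.0]]), TIP, grid)
        np.testing.assert_allclose(thresholded.values, reduced.values, atol=1e-9)

    def test_empty_structure_warns_and_flat(self):
        empty = point_atoms(np.empty((0, 3)))
        grid = ScanGrid(-5, 5, -5, 5, 0.5)
        with pytest.warns(UserWarning):
            hmap = scan_topograph(empty, TIP, grid)
        assert np.all(hmap.values == 0.0)

    def test_far_apart_atoms_pointwise_max(self):
        a = point_atoms([[-10.0, 0.0, 8.0]])
        b = point_atoms([[10.0, 0.0, 12.0]])
        both = point_atoms([[-10.0, 0.0, 8.0], [10.0, 0.0, 12.0]])
        grid = ScanGrid(-15, 15, -15, 15, 0.5)
        im_a = scan_topograph(a, TIP, grid).values
        im_b = scan_topograph(b, TIP, grid).values
        im_ab = scan_topograph(both, TIP, grid).values
        np.testing.assert_allclose(im_ab, np.maximum(im_a, im_b), atol=1e-9)


class TestScanProperties:
    def test_dilation_never_erodes(self):
        # at the node nearest each atom the recorded height is at least the
        # atom height (minus the sub-pixel sphere sagitta of the offset)
        atoms = random_scene(11)
        grid = ScanGrid(-15, 15, -15, 15, 0.5)
        hmap = scan_topograph(atoms, TIP, grid)
        xs, ys = grid.x_values, grid.y_values
        for x, y, z in atoms.coords:
            ix = np.argmin(np.abs(xs - x))
            iy = np.argmin(np.abs(ys - y))
            rho2 = (xs[ix] - x) ** 2 + (ys[iy] - y) ** 2  # <= 2*(step/2)^2
            sagitta = TIP.apex_radius - np.sqrt(TIP.apex_radius**2 - rho2)
            assert hmap.values[iy, ix] >= z - sagitta - 1e-9

    def test_translation_equivariance_one_pixel(self):
        atoms = random_scene(12)
        grid = ScanGrid(-20, 20, -20, 20, 0.5)
        base = scan_topograph(atoms, TIP, grid).values
        shifted = scan_topograph(atoms.translated([0.5, 0.0, 0.0]), TIP, grid).values
        np.testing.assert_allclose(shifted[:, 1:], base[:, :-1], atol=1e-9)

    def test_monotone_in_tip_radius(self):
        atoms = random_scene(13)
        grid = ScanGrid(-15, 15, -15, 15, 1.0)
        small = scan_topograph(atoms, TipModel(apex_radius=5.0), grid).values
        large = scan_topograph(atoms, TipModel(apex_radius=15.0, z_cutoff=60.0), grid).values
        assert np.all(large >= small - 1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bisection_oracle(self, seed):
        atoms = random_scene(seed)
        grid = ScanGrid(-15, 15, -15, 15, 0.5)
        fast = scan_topograph(atoms, TIP, grid)
        slow = dilation_oracle(atoms, TIP, grid)
        assert np.max(np.abs(fast.values - slow.values)) <= 1e-9

    def test_matches_scipy_grey_dilation_on_grid_atoms(self):
        # atoms snapped to grid nodes: the scan equals grayscale dilation of
        # the sparse height image by the reflected tip profile
        rng = np.random.default_rng(21)
        step = 0.5
        grid = ScanGrid(-15, 15, -15, 15, step)
        xs, ys = grid.x_values, grid.y_values
        img = np.full((len(ys), len(xs)), -1e6)
        coords = []
        for _ in range(25):
            ix = rng.integers(10, len(xs) - 10)
            iy = rng.integers(10, len(ys) - 10)
            z = rng.uniform(0, 15)
            img[iy, ix] = max(img[iy, ix], z)
            coords.append([xs[ix], ys[iy], z])
        atoms = point_atoms(coords)

        beta = np.deg2rad(TIP.cone_half_angle)
        R = TIP.apex_radius
        reach = R * np.cos(beta) + (TIP.z_cutoff - R * np.sin(beta)) * np.tan(beta)
        m = int(np.ceil(reach / step))
        off = np.arange(-m, m + 1) * step
        ox, oy = np.meshgrid(off, off)
        rho = np.hypot(ox, oy)
        with np.errstate(invalid="ignore"):
            s_sphere = np.where(rho < R, np.sqrt(np.maximum(R**2 - rho**2, 0.0)), -np.inf)
        s_cone = np.where(
            rho < reach,
            -R * np.sin(beta) - np.maximum(0.0, rho - R * np.cos(beta)) / np.tan(beta),
            -np.inf,
        )
        structure = np.maximum(s_sphere, s_cone) - R
        dilated = ndi.grey_dilation(img, structure=structure, mode="constant", cval=-1e6)
        expected = np.maximum(dilated, 0.0)
        hmap = scan_topograph(atoms, TIP, grid)
        np.testing.assert_allclose(hmap.values, expected, atol=1e-9)


class TestAverageTopograph:
    def grid(self, n, step=0.5):
        return ScanGrid(0.0, (n - 1) * step, 0.0, (n - 1) * step, step)

    def test_periodic_map_returns_single_cell(self):
        cell = np.arange(16.0).reshape(4, 4)
        values = np.tile(cell, (3, 3))
        hmap = HeightMap(values, self.grid(12))
        out = average_topograph(hmap, 2.0, 2.0)
        np.testing.assert_allclose(out.values, cell, atol=1e-12)

    def test_two_cells_average(self):
        values = np.hstack([np.full((2, 2), 1.0), np.full((2, 2), 3.0)])
        hmap = HeightMap(values, ScanGrid(0, 1.5, 0, 0.5, 0.5))
        out = average_topograph(hmap, 1.0, 1.0)
        np.testing.assert_allclose(out.values, np.full((2, 2), 2.0))

    def test_full_extent_identity(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 10, (6, 6))
        hmap = HeightMap(values, self.grid(6))
        out = average_topograph(hmap, 3.0, 3.0)
        np.testing.assert_allclose(out.values, values)

    def test_incommensurate_cell_rejected(self):
        hmap = HeightMap(np.zeros((4, 4)), self.grid(4))
        with pytest.raises(ValueError):
            average_topograph(hmap, 0.7, 0.5)


class TestHeightmapIO:
    def make_map(self):
        rng = np.random.default_rng(9)
        grid = ScanGrid(-5, 5, -5, 5, 0.5)
        return HeightMap(rng.uniform(0, 30, grid.shape), grid, provenance="test")

    def test_tsv_roundtrip_to_float_precision(self, tmp_path):
        hmap = self.make_map()
        path = tmp_path / "map.tsv"
        write_heightmap(hmap, path, fmt="tsv")
        back = read_heightmap(path)
        # one unit conversion each way: exact up to 1 ulp
        np.testing.assert_allclose(back, hmap.values, rtol=1e-15, atol=0)

    def test_values_written_in_nm(self, tmp_path):
        grid = ScanGrid(0, 1, 0, 1, 0.5)
        hmap = HeightMap(np.full(grid.shape, 10.0), grid)  # 10 Å
        path = tmp_path / "map.tsv"
        write_heightmap(hmap, path, fmt="tsv")
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert float(body[0].split("\t")[0]) == 1.0

    def test_ascii_matrix_has_extent_header(self, tmp_path):
        hmap = self.make_map()
        path = tmp_path / "map.txt"
        write_heightmap(hmap, path, fmt="ascii-matrix")
        text = path.read_text()
        assert "Width: 1 nm" in text and "Value units: nm" in text
        np.testing.assert_allclose(read_heightmap(path), hmap.values, rtol=1e-15, atol=0)

    def test_tiff_constant_map(self, tmp_path):
        import tifffile

        grid = ScanGrid(0, 2, 0, 2, 0.5)
        hmap = HeightMap(np.full(grid.shape, 7.0), grid)
        path = tmp_path / "map.tiff"
        write_heightmap(hmap, path, fmt="tiff")
        img = tifffile.imread(str(path))
        assert img.dtype == np.uint16
        assert np.all(img == img.flat[0])
        assert (tmp_path / "map.tiff.scale.txt").exists()
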