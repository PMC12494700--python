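"""Grid construction, the eight potential channels and the truth mask."""

import numpy as np
import pytest

import geneopocket as gp
from geneopocket.channels import (
    HB_OFFSET,
    distance_channel,
    hb_acceptor_channel,
    hb_donor_channel,
    inverse_distance_channel,
)
from geneopocket.errors import EmptyTruthError, GridTooLargeError, InvalidFieldError
from geneopocket.structure_io import ParameterizedAtom


def make_atom(coords, element="C", radius=1.5, mass=12.0, charge=0.0,
              lipo=0.0, polar=0, role="none", eps=1.0, rmin=1.9,
              hydrogens=(), antecedent=None):
    return ParameterizedAtom(
        coords=np.asarray(coords, dtype=float), element=element,
        vdw_radius=radius, mass=mass, charge=charge, lipo_coeff=lipo,
        polar=polar, hb_role=role, hb_eps=eps, hb_rmin=rmin,
        donor_hydrogens=[np.asarray(h, dtype=float) for h in hydrogens],
        antecedent=None if antecedent is None else np.asarray(antecedent, float))


def centered_grid(n=9, spacing=1.0):
    """Cubic grid whose voxel centers sit on integer coordinates."""
    half = n * spacing / 2.0
    return gp.VoxelGrid(origin=np.array([-half] * 3), spacing=spacing,
                        dims=(n, n, n))


def center_index(grid, point):
    return tuple(int(round((p - o) / grid.spacing - 0.5))
                 for p, o in zip(point, grid.origin))


class TestBuildGrid:
    def test_single_atom_dims_and_origin(self):
        grid = gp.build_grid([make_atom([0, 0, 0], radius=1.5)],
                             spacing=1.0, padding=2.5)
        assert grid.dims == (8, 8, 8)
        np.testing.assert_allclose(grid.origin, [-4, -4, -4])

    def test_zero_padding(self):
        grid = gp.build_grid([make_atom([0, 0, 0], radius=1.0)],
                             spacing=1.0, padding=0.0)
        assert grid.dims == (2, 2, 2)

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            gp.build_grid([make_atom([0, 0, 0])], spacing=0.0)

    def test_voxel_cap(self):
        with pytest.raises(GridTooLargeError):
            gp.build_grid([make_atom([0, 0, 0])], spacing=0.1, padding=50.0,
                          max_voxels=1000)


class TestDistanceChannel:
    def test_signed_distance_values(self):
        grid = centered_grid()
        field = distance_channel([make_atom([0, 0, 0], radius=1.5)], grid)
        assert field[center_index(grid, (3, 0, 0))] == pytest.approx(1.5)
        assert field[center_index(grid, (0, 0, 0))] == pytest.approx(-1.5)

    def test_nearest_atom_selection(self):
        grid = centered_grid(21)
        atoms = [make_atom([0, 0, 0], radius=1.0),
                 make_atom([10, 0, 0], radius=1.0)]
        field = distance_channel(atoms, grid)
        assert field[center_index(grid, (1, 0, 0))] == pytest.approx(0.0)

    def test_empty_space_mask_derivation(self, shell_stack):
        assert shell_stack.empty_space_mask.dtype == bool
        assert shell_stack.empty_space_mask.any()
        assert not shell_stack.empty_space_mask.all()


class TestInverseDistanceChannels:
    def test_mass_over_distance(self):
        grid = centered_grid()
        field = inverse_distance_channel([make_atom([2, 0, 0], mass=12.0)],
                                         grid, "mass")
        assert field[center_index(grid, (0, 0, 0))] == pytest.approx(6.0)

    def test_signed_charge(self):
        grid = centered_grid()
        field = inverse_distance_channel([make_atom([2, 0, 0], charge=-0.4)],
                                         grid, "charge")
        assert field[center_index(grid, (0, 0, 0))] == pytest.approx(-0.2)

    def test_lipophilic_sign_split(self):
        grid = centered_grid()
        atom = make_atom([2, 0, 0], lipo=+1.0)
        phi4 = inverse_distance_channel([atom], grid, "lipo_neg")
        phi5 = inverse_distance_channel([atom], grid, "lipo_pos")
        assert phi4[center_index(grid, (0, 0, 0))] == 0.0
        assert phi5[center_index(grid, (0, 0, 0))] == pytest.approx(0.5)

    def test_cutoff_excludes_far_atoms(self):
        grid = centered_grid()
        field = inverse_distance_channel([make_atom([2, 0, 0], mass=12.0)],
                                         grid, "mass", cutoff=1.5)
        assert field[center_index(grid, (0, 0, 0))] == 0.0

    def test_distance_clamped_inside_atom(self):
        grid = centered_grid()
        field = inverse_distance_channel([make_atom([0, 0, 0], mass=1.0)],
                                         grid, "mass")
        # at the atom center d clamps to spacing/2
        assert field[center_index(grid, (0, 0, 0))] == pytest.approx(2.0)

    def test_superposition_is_exact(self):
        grid = centered_grid(11)
        rng = np.random.default_rng(0)
        set_a = [make_atom(rng.uniform(-3, 3, 3), mass=rng.uniform(1, 16))
                 for _ in range(5)]
        set_b = [make_atom(rng.uniform(-3, 3, 3), mass=rng.uniform(1, 16))
                 for _ in range(4)]
        fa = inverse_distance_channel(set_a, grid, "mass")
        fb = inverse_distance_channel(set_b, grid, "mass")
        fab = inverse_distance_channel(set_a + set_b, grid, "mass")
        # exact up to float summation order (per-atom accumulation)
        np.testing.assert_allclose(fab, fa + fb, rtol=1e-13, atol=1e-13)

    def test_cutoff_convergence_bound(self, shell_structure):
        grid = gp.build_grid(shell_structure.protein_atoms, padding=2.0)
        f20 = inverse_distance_channel(shell_structure.protein_atoms, grid,
                                       "mass", cutoff=20.0)
        f40 = inverse_distance_channel(shell_structure.protein_atoms, grid,
                                       "mass", cutoff=40.0)
        bound = sum(a.mass for a in shell_structure.protein_atoms) / 20.0
        assert np.all(f20 >= 0) and np.all(f40 >= 0)
        assert np.max(np.abs(f40 - f20)) < bound


class TestHBChannels:
    def test_acceptor_stationary_maximum(self):
        # -(R^6 - 2 R^4) peaks at R = sqrt(4/3) with value 32/27
        rmin = 1.9
        d_star = rmin / (np.sqrt(4.0 / 3.0) - HB_OFFSET)
        grid = gp.VoxelGrid(origin=np.array([d_star - 0.5, -0.5, -0.5]),
                            spacing=1.0, dims=(1, 1, 1))
        atom = make_atom([0, 0, 0], role="acceptor", eps=1.0, rmin=rmin)
        field = hb_acceptor_channel([atom], grid, cutoff=20.0)
        assert field[0, 0, 0] == pytest.approx(32.0 / 27.0, rel=1e-9)

    def test_acceptor_root(self):
        rmin = 1.9
        d_zero = rmin / (np.sqrt(2.0) - HB_OFFSET)
        grid = gp.VoxelGrid(origin=np.array([d_zero - 0.5, -0.5, -0.5]),
                            spacing=1.0, dims=(1, 1, 1))
        atom = make_atom([0, 0, 0], role="acceptor", eps=1.0, rmin=rmin)
        field = hb_acceptor_channel([atom], grid, cutoff=20.0)
        assert field[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_no_acceptors_gives_zero(self):
        grid = centered_grid()
        field = hb_acceptor_channel([make_atom([0, 0, 0])], grid)
        np.testing.assert_array_equal(field, 0.0)

    def test_donor_collinear_equals_radial(self):
        # antecedent -> D -> H -> x all on the +x axis
        d_probe = 3.0
        probe = np.array([d_probe, 0.0, 0.0])
        grid = gp.VoxelGrid(origin=probe - 0.5, spacing=1.0, dims=(1, 1, 1))
        donor = make_atom([0, 0, 0], role="donor", hydrogens=[[1.0, 0, 0]],
                          antecedent=[-1.4, 0, 0])
        acceptor_style = make_atom([0, 0, 0], role="acceptor")
        f_donor = hb_donor_channel([donor], grid, cutoff=20.0)
        f_radial = hb_acceptor_channel([acceptor_style], grid, cutoff=20.0)
        assert f_donor[0, 0, 0] == pytest.approx(f_radial[0, 0, 0], rel=1e-9)

    def test_donor_perpendicular_is_zero(self):
        probe = np.array([1.0, 3.0, 0.0])  # perpendicular to D->H at H
        grid = gp.VoxelGrid(origin=probe - 0.5, spacing=1.0, dims=(1, 1, 1))
        donor = make_atom([0, 0, 0], role="donor", hydrogens=[[1.0, 0, 0]])
        field = hb_donor_channel([donor], grid, cutoff=20.0)
        assert field[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_no_donors_gives_zero(self):
        grid = centered_grid()
        field = hb_donor_channel([make_atom([0, 0, 0])], grid)
        np.testing.assert_array_equal(field, 0.0)


class TestNormalization:
    def _stack(self, field):
        grid = gp.VoxelGrid(origin=np.zeros(3), spacing=1.0, dims=field.shape)
        fields = np.stack([field] * 8)
        return gp.ChannelStack(grid=grid, fields=fields,
                               empty_space_mask=np.ones(field.shape, bool))

    def test_affine_rescale(self):
        field = np.array([[[-2.0, 6.0, 2.0]]])
        out = gp.normalize_channels(self._stack(field))
        np.testing.assert_allclose(out.fields[0], [[[0.0, 1.0, 0.5]]])

    def test_constant_maps_to_half(self):
        out = gp.normalize_channels(self._stack(np.full((2, 2, 2), 7.0)))
        np.testing.assert_array_equal(out.fields[0], 0.5)

    def test_unit_interval_unchanged(self):
        field = np.array([[[0.0, 0.25, 1.0]]])
        out = gp.normalize_channels(self._stack(field))
        np.testing.assert_allclose(out.fields[0], field)

    def test_orientation_flip(self):
        field = np.array([[[0.0, 1.0]]])
        out = gp.normalize_channels(self._stack(field),
                                    flips=(True,) + (False,) * 7)
        np.testing.assert_allclose(out.fields[0], [[[1.0, 0.0]]])
        np.testing.assert_allclose(out.fields[1], field)

    def test_nan_rejected(self):
        field = np.full((2, 2, 2), np.nan)
        with pytest.raises(InvalidFieldError):
            gp.normalize_channels(self._stack(field))


def _sampling_oracle(atom_coords, radius, grid, n=25):
    """Exhaustive point sampling of the sphere-box overlap decision."""
    out = np.zeros(grid.dims, dtype=bool)
    t = np.linspace(0, 1, n)
    for idx in np.ndindex(grid.dims):
        lo = grid.origin + np.array(idx) * grid.spacing
        pts = lo + np.stack(np.meshgrid(t, t, t, indexing="ij"),
                            axis=-1).reshape(-1, 3) * grid.spacing
        d2 = np.sum((pts - atom_coords) ** 2, axis=1)
        if (d2 < radius ** 2).any():
            out[idx] = True
    return out


class TestTruthMask:
    def test_sphere_in_unit_voxel_matches_sampling_oracle(self):
        grid = centered_grid(5)
        atom = make_atom([0, 0, 0], radius=1.5)
        mask = gp.ligand_truth_mask([atom], grid)
        oracle = _sampling_oracle(atom.coords, 1.5, grid)
        np.testing.assert_array_equal(mask.values, oracle)
        # a 1.5 Å sphere centered in a 1 Å voxel reaches every one of the
        # 26 neighbors but only touches the next face layer tangentially
        assert mask.count == 27

    def test_random_spheres_match_sampling_oracle(self):
        rng = np.random.default_rng(5)
        grid = centered_grid(6)
        for _ in range(5):
            atom = make_atom(rng.uniform(-1.5, 1.5, 3),
                             radius=rng.uniform(0.4, 1.8))
            mask = gp.ligand_truth_mask([atom], grid)
            oracle = _sampling_oracle(atom.coords, atom.vdw_radius, grid, n=41)
            # the finite sampling oracle can only under-report overlap
            assert np.all(oracle <= mask.values)
            assert (mask.values ^ oracle).sum() <= 2

    def test_ligand_outside_grid(self):
        grid = centered_grid(3)
        with pytest.raises(EmptyTruthError):
            gp.ligand_truth_mask([make_atom([50, 0, 0], radius=1.0)], grid)

    def test_zero_radius_on_corner_owns_single_voxel(self):
        grid = gp.VoxelGrid(origin=np.zeros(3), spacing=1.0, dims=(2, 2, 2))
        mask = gp.ligand_truth_mask([make_atom([1.0, 1.0, 1.0], radius=0.0)],
                                    grid)
        assert mask.count == 1
        assert mask.values[1, 1, 1]

    def test_hydrogens_ignored(self):
        grid = centered_grid(5)
        h = make_atom([0, 0, 0], element="H", radius=1.2)
        with pytest.raises(EmptyTruthError):
            gp.ligand_truth_mask([h], grid)


class TestEquivariance:
    def test_translation_by_voxel_multiples_is_exact(self, shell_structure):
        atoms = shell_structure.protein_atoms
        stack = gp.compute_channels(atoms, normalize=False, padding=3.0)
        shifted = []
        for a in atoms:
            b = make_atom(a.coords + np.array([3.0, -2.0, 5.0]), a.element,
                          a.vdw_radius, a.mass, a.charge, a.lipo_coeff,
                          a.polar, a.hb_role, a.hb_eps, a.hb_rmin,
                          [h + np.array([3.0, -2.0, 5.0])
                           for h in a.donor_hydrogens],
                          None if a.antecedent is None
                          else a.antecedent + np.array([3.0, -2.0, 5.0]))
            shifted.append(b)
        stack2 = gp.compute_channels(shifted, normalize=False, padding=3.0)
        assert stack.grid.dims == stack2.grid.dims
        np.testing.assert_allclose(stack2.grid.origin - stack.grid.origin,
                                   [3.0, -2.0, 5.0], atol=1e-12)
        # identical up to rounding of the shifted coordinates; the HB
        # channels reach ~1e4 inside atoms, hence the relative tolerance
        np.testing.assert_allclose(stack2.fields, stack.fields,
                                   rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rotation_about_z_permutes_fields(self, shell_structure, k):
        # point rotation (x, y) -> (-y, x), k times, about the grid center
        atoms = shell_structure.protein_atoms
        n = 36
        half = n / 2.0
        grid = gp.VoxelGrid(origin=np.array([-half] * 3), spacing=1.0,
                            dims=(n, n, n))
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        mat = np.linalg.matrix_power(rot, k)

        def rotate_atom(a):
            return make_atom(mat @ a.coords, a.element, a.vdw_radius, a.mass,
                             a.charge, a.lipo_coeff, a.polar, a.hb_role,
                             a.hb_eps, a.hb_rmin,
                             [mat @ h for h in a.donor_hydrogens],
                             None if a.antecedent is None
                             else mat @ a.antecedent)

        base = gp.compute_channels(atoms, grid=grid, normalize=False)
        rotated = gp.compute_channels([rotate_atom(a) for a in atoms],
                                      grid=grid, normalize=False)
        expected = np.stack([np.rot90(f, k=k, axes=(0, 1))
                             for f in base.fields])
        np.testing.assert_allclose(rotated.fields, expected,
                                   rtol=1e-10, atol=1e-10)


def test_channel_sign_invariants(shell_structure):
    stack = gp.compute_channels(shell_structure, normalize=False)
    assert np.all(stack.fields[1] >= 0)   # gravitational
    assert np.all(stack.fields[3] <= 0)   # lipophilic sums negative coeffs
    assert np.all(stack.fields[4] >= 0)   # hydrophilic sums positive coeffs
    assert np.all(stack.fields[5] >= 0)   # polar indicator


def test_stack_round_trip(tmp_path, shell_structure):
    stack = gp.compute_channels(shell_structure)
    truth = gp.ligand_truth_mask(shell_structure.ligand_atoms, stack.grid)
    path = tmp_path / "stack.npz"
    gp.save_stack(path, stack, truth,
                  ligand_coords=shell_structure.ligand_heavy_coords)
    stack2, truth2, lig = gp.load_stack(path)
    np.testing.assert_array_equal(stack2.fields, stack.fields)
    np.testing.assert_array_equal(truth2.values, truth.values)
    assert stack2.normalized
    assert lig.shape[1] == 3
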