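import numpy as np
import pytest

from molray.fixtures import make_sphere_cluster, single_atom_system
from molray.model import Atom, MoleculeSystem, assign_radii
from molray.surface import (
    ScalarGrid,
    build_sas_field,
    compute_ses,
    exterior_distance_transform,
    mesh_area,
    sas_signed_value,
    ses_level_field,
)

SPHERE_AREA = 4 * np.pi * 1.7**2  # 36.3168... for the vdW carbon radius


def brute_force_edt(inside: np.ndarray, spacing: float) -> np.ndarray:
    """All-pairs nearest-exterior-node distance (the independent oracle)."""
    dims = inside.shape
    ext = np.argwhere(~inside)
    out = np.zeros(dims)
    for idx in np.argwhere(inside):
        d2 = ((ext - idx) ** 2).sum(axis=1)
        out[tuple(idx)] = np.sqrt(float(d2.min())) * spacing
    return out


class TestSASField:
    def test_value_at_center(self, carbon):
        # f(center) = 0 - 1.7 - 1.4
        v = sas_signed_value(carbon, np.zeros(3), probe_radius=1.4)
        assert v[0] == pytest.approx(-3.1)

    def test_zero_on_accessible_sphere(self, carbon):
        p = np.array([3.1, 0.0, 0.0])
        assert sas_signed_value(carbon, p, probe_radius=1.4)[0] == pytest.approx(0.0)

    def test_positive_far_away(self, carbon):
        p = np.array([10.0, 0.0, 0.0])
        assert sas_signed_value(carbon, p, probe_radius=1.4)[0] == pytest.approx(6.9)

    def test_grid_signs_match_exact_field(self, carbon):
        grid = build_sas_field(carbon, probe_radius=1.4, spacing=0.5)
        nx, ny, nz = grid.dims
        idx = np.stack(np.meshgrid(*(np.arange(d) for d in grid.dims), indexing="ij"), -1)
        pts = grid.origin + idx.reshape(-1, 3) * grid.spacing
        exact = sas_signed_value(carbon, pts, probe_radius=1.4)
        assert np.array_equal(grid.values.reshape(-1) < 0, exact < 0)

    def test_empty_system_rejected(self):
        with pytest.raises(ValueError):
            build_sas_field(MoleculeSystem(atoms=[]))


class TestEDT:
    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        dims = rng.integers(4, 13, size=3)
        inside = rng.random(tuple(dims)) < 0.5
        inside[0, 0, 0] = False  # guarantee at least one exterior node
        spacing = float(rng.uniform(0.2, 1.0))
        got = exterior_distance_transform(inside, spacing)
        want = brute_force_edt(inside, spacing)
        assert np.max(np.abs(got - want)) == 0.0

    def test_exterior_nodes_zero(self):
        inside = np.zeros((4, 4, 4), dtype=bool)
        inside[1:3, 1:3, 1:3] = True
        d = exterior_distance_transform(inside, 1.0)
        assert (d[~inside] == 0).all()


class TestSESLevelField:
    def test_single_sphere_closed_form(self, carbon):
        # closed form: h(p) = |p - c| - r for nodes inside the accessible
        # sphere of a single atom
        grid = build_sas_field(carbon, probe_radius=1.4, spacing=0.3)
        level = ses_level_field(grid, probe_radius=1.4)
        idx = np.stack(np.meshgrid(*(np.arange(d) for d in grid.dims), indexing="ij"), -1)
        pts = grid.origin + idx.reshape(-1, 3) * grid.spacing
        r = np.linalg.norm(pts, axis=1)
        inside = grid.values.reshape(-1) < 0
        h = level.values.reshape(-1)
        np.testing.assert_allclose(h[inside], (r - 1.7)[inside], atol=0.12)

    def test_center_value(self, carbon):
        grid = build_sas_field(carbon, probe_radius=1.4, spacing=0.3)
        level = ses_level_field(grid, probe_radius=1.4)
        center_idx = np.round((np.zeros(3) - grid.origin) / grid.spacing).astype(int)
        node = grid.origin + center_idx * grid.spacing
        # closed form h = |p - c| - r evaluated at the node nearest the center
        expected = np.linalg.norm(node) - 1.7
        assert expected == pytest.approx(1.4 - 3.1, abs=2 * grid.spacing)
        assert level.values[tuple(center_idx)] == pytest.approx(expected, abs=0.12)

    def test_exterior_nodes_plus_probe(self, carbon):
        grid = build_sas_field(carbon, probe_radius=1.4, spacing=0.4)
        level = ses_level_field(grid, probe_radius=1.4)
        ext = grid.values >= 0
        assert (level.values[ext] == 1.4).all()

    def test_node_mode_matches_spec_formula(self, carbon):
        grid = build_sas_field(carbon, probe_radius=1.4, spacing=0.4)
        level = ses_level_field(grid, probe_radius=1.4, boundary="nodes")
        edt = exterior_distance_transform(grid.values < 0, grid.spacing)
        np.testing.assert_array_equal(level.values, 1.4 - edt)


class TestComputeSES:
    def test_single_atom_area(self, carbon):
        mesh = compute_ses(carbon, probe_radius=1.4, spacing=0.3)
        assert mesh_area(mesh) == pytest.approx(SPHERE_AREA, rel=0.03)

    def test_two_distant_atoms_additive(self):
        atoms = [
            Atom(index=0, name="C", element="C", position=np.zeros(3)),
            Atom(index=1, name="C", element="C", position=np.array([20.0, 0, 0])),
        ]
        sys = assign_radii(MoleculeSystem(atoms=atoms))
        mesh = compute_ses(sys, probe_radius=1.4, spacing=0.3)
        assert mesh_area(mesh) == pytest.approx(2 * SPHERE_AREA, rel=0.03)

    def test_probe_zero_gives_vdw_surface(self, carbon):
        mesh = compute_ses(carbon, probe_radius=0.0, spacing=0.3)
        assert mesh_area(mesh) == pytest.approx(SPHERE_AREA, rel=0.03)

    def test_area_converges_with_spacing(self, carbon):
        areas = [
            mesh_area(compute_ses(carbon, probe_radius=1.4, spacing=s))
            for s in (0.6, 0.4, 0.3, 0.2)
        ]
        errors = [abs(a - SPHERE_AREA) for a in areas]
        # monotone within 10% noise allowance
        for e_coarse, e_fine in zip(errors, errors[1:]):
            assert e_fine <= e_coarse * 1.1

    def test_encloses_vdw_union(self):
        sys = make_sphere_cluster(8, box=10.0, min_sep=3.0, seed=2)
        grid = build_sas_field(sys, probe_radius=1.4, spacing=0.4)
        level = ses_level_field(grid, probe_radius=1.4)
        for atom in sys.atoms:
            idx = np.round((atom.position - grid.origin) / grid.spacing).astype(int)
            assert level.values[tuple(idx)] < 0
        # far nodes (>= r_i + 2 * probe from every atom) are positive
        idxs = np.stack(np.meshgrid(*(np.arange(d) for d in grid.dims), indexing="ij"), -1)
        pts = grid.origin + idxs.reshape(-1, 3) * grid.spacing
        coords = sys.coordinates
        radii = np.array([a.vdw_radius for a in sys.atoms])
        d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
        far = (d >= radii[None, :] + 2 * 1.4).all(axis=1)
        assert (level.values.reshape(-1)[far] > 0).all()

    def test_atom_order_invariance(self):
        sys = make_sphere_cluster(6, box=8.0, min_sep=3.0, seed=5)
        mesh = compute_ses(sys, spacing=0.4)
        atoms = list(reversed(sys.atoms))
        for k, a in enumerate(atoms):
            a.index = k
        sys2 = MoleculeSystem(atoms=atoms)
        mesh2 = compute_ses(sys2, spacing=0.4)
        assert mesh.n_vertices == mesh2.n_vertices

        def row_sorted(v):
            v = v.round(9)
            return v[np.lexsort((v[:, 2], v[:, 1], v[:, 0]))]

        np.testing.assert_allclose(row_sorted(mesh.vertices), row_sorted(mesh2.vertices))

    def test_vertex_colors_from_nearest_atom(self, carbon):
        colors = np.array([[10, 20, 30, 255]], dtype=np.uint8)
        mesh = compute_ses(carbon, spacing=0.4, atom_colors=colors)
        assert (mesh.vertex_colors == colors[0]).all()
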