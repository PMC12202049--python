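"""Discrete Solvent Excluded Surface.

Pipeline: (1) sample the signed solvent-accessible field
``f(p) = min_i(|p - c_i| - r_i) - r_probe`` on a regular grid (negative
strictly inside the solvent-accessible volume); (2) take the exact Euclidean
distance transform from every node to the nearest exterior node (f >= 0) and
form the level field ``h(p) = r_probe - EDT(p)``, whose zero level set is the
SES; (3) extract the mesh with marching cubes.  For a single atom this
construction reduces to the van der Waals sphere, which anchors the analytic
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .marching_cubes import Mesh, marching_cubes, mesh_area
from .model import MoleculeSystem, Selection

__all__ = [
    "ScalarGrid",
    "build_sas_field",
    "sas_signed_value",
    "ses_level_field",
    "compute_ses",
    "marching_cubes",
    "mesh_area",
    "Mesh",
]


@dataclass
class ScalarGrid:
    """Regular isotropic 3-D scalar field."""

    origin: np.ndarray  # (3,) Angstrom, position of node (0, 0, 0)
    spacing: float  # Angstrom, isotropic
    values: np.ndarray  # (nx, ny, nz) float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid must be 3-D with at least 2 nodes per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def node_position(self, ix: int, iy: int, iz: int) -> np.ndarray:
        return self.origin + self.spacing * np.array([ix, iy, iz], dtype=float)


def sas_signed_value(system: MoleculeSystem, points: np.ndarray, probe_radius: float = 1.4) -> np.ndarray:
    """Exact signed SAS field ``min_i(|p - c_i| - r_i) - r_probe`` at arbitrary points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    centers = system.coordinates
    radii = np.array([a.vdw_radius for a in system.atoms])
    d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2) - radii[None, :]
    return d.min(axis=1) - probe_radius


def build_sas_field(
    system: MoleculeSystem,
    probe_radius: float = 1.4,
    spacing: float = 0.4,
) -> ScalarGrid:
    """Sample the signed SAS field on a grid covering the padded bounding box.

    The grid pads the atom bounding box by ``max(r_i) + probe + 2 * spacing``.
    Each atom stamps only its local neighborhood, so the cost is
    O(n_atoms * k) in stamped nodes rather than O(n_atoms * n_nodes); nodes
    outside every stamp keep a positive fill value (their sign — exterior —
    is what the downstream distance transform consumes).
    """
    if system.n_atoms == 0:
        raise ValueError("cannot build a SAS field for an empty system")
    radii = np.array([a.vdw_radius for a in system.atoms])
    if np.any(radii <= 0):
        raise ValueError("vdW radii not assigned; call assign_radii first")
    coords = system.coordinates
    pad = float(radii.max()) + probe_radius + 2.0 * spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)

    # margin beyond each atom's accessible sphere; nodes farther than this
    # from every atom get the (positive) fill value
    margin = 4.0 * spacing
    fill = margin
    values = np.full(tuple(dims), fill)

    for center, r in zip(coords, radii):
        reach = r + probe_radius + margin
        i_lo = np.maximum(np.floor((center - reach - lo) / spacing).astype(int), 0)
        i_hi = np.minimum(np.ceil((center + reach - lo) / spacing).astype(int) + 1, dims)
        if np.any(i_lo >= i_hi):
            continue
        ax = [lo[k] + spacing * np.arange(i_lo[k], i_hi[k]) - center[k] for k in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        local = np.sqrt(d2) - r - probe_radius
        region = values[i_lo[0] : i_hi[0], i_lo[1] : i_hi[1], i_lo[2] : i_hi[2]]
        np.minimum(region, local, out=region)

    return ScalarGrid(origin=lo, spacing=spacing, values=values)


def exterior_distance_transform(inside: np.ndarray, spacing: float) -> np.ndarray:
    """Exact Euclidean distance from every node to the nearest exterior node.

    ``inside`` marks nodes with f < 0; exterior nodes get distance 0.  The
    transform is computed in index space (exact separable squared-distance
    algorithm via :func:`scipy.ndimage.distance_transform_edt`) and scaled by
    ``spacing`` so it is bit-comparable with a brute-force oracle doing the
    same arithmetic.
    """
    return ndimage.distance_transform_edt(inside, sampling=1.0) * spacing


def _boundary_crossings(sas: ScalarGrid) -> np.ndarray:
    """Sub-voxel points where the SAS field changes sign along grid edges.

    The crossing position on each edge is found by linear interpolation of
    the node values; the result samples the continuous f = 0 surface with
    O(spacing^2) error.
    """
    values = sas.values
    pts = []
    for axis in range(3):
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[axis] = slice(0, values.shape[axis] - 1)
        sl1[axis] = slice(1, values.shape[axis])
        v0 = values[tuple(sl0)]
        v1 = values[tuple(sl1)]
        crossed = (v0 < 0) != (v1 < 0)
        idx = np.argwhere(crossed)
        if len(idx) == 0:
            continue
        t = -v0[crossed] / (v1[crossed] - v0[crossed])
        pos = idx.astype(float)
        pos[:, axis] += t
        pts.append(pos)
    if not pts:
        return np.empty((0, 3))
    return np.concatenate(pts) * sas.spacing + sas.origin


def ses_level_field(
    sas: ScalarGrid,
    probe_radius: float = 1.4,
    boundary: str = "interpolated",
) -> ScalarGrid:
    """Level field ``h = r_probe - EDT``; h = 0 on the SES, h < 0 inside.

    ``boundary`` selects how the exterior set is sampled:

    - ``"interpolated"`` (default): distance from each interior node to the
      nearest sub-voxel crossing of the f = 0 surface.  Exterior nodes get
      h = +r_probe.  Eliminates the O(spacing) outward bias of node
      sampling, which matters at the stated area tolerances.
    - ``"nodes"``: distance to the nearest exterior *node* (the exact
      separable transform of :func:`exterior_distance_transform`).
    """
    inside = sas.values < 0.0
    if boundary == "nodes":
        edt = exterior_distance_transform(inside, sas.spacing)
        return ScalarGrid(
            origin=sas.origin.copy(), spacing=sas.spacing, values=probe_radius - edt
        )
    if boundary != "interpolated":
        raise ValueError(f"unknown boundary mode {boundary!r}")
    values = np.full(sas.values.shape, probe_radius, dtype=float)
    pts = _boundary_crossings(sas)
    if len(pts) == 0:
        # no sign change: field entirely one-sided
        if inside.any():
            values[:] = -probe_radius
        return ScalarGrid(origin=sas.origin.copy(), spacing=sas.spacing, values=values)
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    idx = np.argwhere(inside)
    coords = idx * sas.spacing + sas.origin
    dist, _ = tree.query(coords, workers=-1)
    values[inside] = probe_radius - dist
    return ScalarGrid(origin=sas.origin.copy(), spacing=sas.spacing, values=values)


def compute_ses(
    system: MoleculeSystem,
    probe_radius: float = 1.4,
    spacing: float = 0.4,
    selection: Selection | None = None,
    atom_colors: np.ndarray | None = None,
) -> Mesh:
    """Solvent Excluded Surface mesh in model coordinates.

    If ``atom_colors`` (n_atoms x 4, uint8) is given, each vertex is colored
    by its nearest atom.
    """
    if selection is not None and len(selection) < system.n_atoms:
        sub_atoms = [system.atoms[i] for i in selection]
        sub = MoleculeSystem(
            atoms=[
                type(a)(
                    index=k,
                    name=a.name,
                    element=a.element,
                    position=a.position.copy(),
                    vdw_radius=a.vdw_radius,
                    covalent_radius=a.covalent_radius,
                    chain_id=a.chain_id,
                    residue_name=a.residue_name,
                    residue_seq=a.residue_seq,
                )
                for k, a in enumerate(sub_atoms)
            ]
        )
        if atom_colors is not None:
            atom_colors = atom_colors[list(selection)]
        system = sub
    if system.n_atoms == 0:
        raise ValueError("cannot compute SES for an empty selection")

    sas = build_sas_field(system, probe_radius=probe_radius, spacing=spacing)
    if probe_radius == 0.0:
        # probe of zero: SES degenerates to the van der Waals surface, which
        # is the zero set of the SAS field itself
        level = sas
    else:
        level = ses_level_field(sas, probe_radius=probe_radius)
    mesh = marching_cubes(level, iso=0.0)
    if atom_colors is not None and mesh.n_vertices:
        from scipy.spatial import cKDTree

        tree = cKDTree(system.coordinates)
        _, nearest = tree.query(mesh.vertices)
        mesh.vertex_colors = np.asarray(atom_colors, dtype=np.uint8)[nearest]
    return mesh
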