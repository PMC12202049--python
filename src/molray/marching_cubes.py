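"""Self-contained marching cubes on a regular scalar grid.

The 256-entry case table is constructed once at import time from first
principles rather than transcribed: for each sign configuration the cut
edges are linked into closed polygons by pairing, on every cube face, the
cut edges that bound each maximal run of inside corners along the face
perimeter.  Because opposite faces traverse their shared edge in opposite
directions, the directed chords chain into disjoint cycles; each cycle is
fan-triangulated.  This is the standard table-free derivation of the
asymptotic-decider-free case table and is deterministic.

Vertices on shared cell edges are deduplicated globally, so the mesh is
watertight for fields without boundary crossings.  Vertex normals are the
normalized central-difference gradient of the field (pointing toward
increasing field values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Mesh", "marching_cubes", "mesh_area"]

# Cube corner offsets (classic ordering) and the 12 edges as corner pairs.
_CORNERS = np.array(
    [
        (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
    ],
    dtype=int,
)
_EDGES = [
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
]
# Faces as corner cycles, oriented counterclockwise seen from outside the cube.
_FACES = [
    (0, 3, 2, 1),  # z = 0
    (4, 5, 6, 7),  # z = 1
    (0, 1, 5, 4),  # y = 0
    (2, 3, 7, 6),  # y = 1
    (0, 4, 7, 3),  # x = 0
    (1, 2, 6, 5),  # x = 1
]

_EDGE_INDEX = {frozenset(e): i for i, e in enumerate(_EDGES)}


def _build_case(inside: tuple[bool, ...]) -> list[tuple[int, int, int]]:
    """Triangles (as local edge-index triples) for one corner configuration."""
    # Directed chords: walking each face perimeter, every maximal run of
    # inside corners contributes one chord from its entering to its exiting
    # cut edge.
    succ: dict[int, int] = {}
    for face in _FACES:
        for s in range(4):
            a, b = face[s], face[(s + 1) % 4]
            if inside[b] and not inside[a]:
                # entering the inside region through edge (a, b)
                e_in = _EDGE_INDEX[frozenset((a, b))]
                t = (s + 1) % 4
                while inside[face[(t + 1) % 4]]:
                    t = (t + 1) % 4
                c, d = face[t], face[(t + 1) % 4]
                e_out = _EDGE_INDEX[frozenset((c, d))]
                succ[e_in] = e_out
    # Chain chords into cycles; each cut edge has exactly one in and one out.
    triangles: list[tuple[int, int, int]] = []
    remaining = set(succ)
    while remaining:
        start = min(remaining)
        cycle = [start]
        remaining.discard(start)
        nxt = succ[start]
        while nxt != start:
            cycle.append(nxt)
            remaining.discard(nxt)
            nxt = succ[nxt]
        for k in range(1, len(cycle) - 1):
            triangles.append((cycle[0], cycle[k], cycle[k + 1]))
    return triangles


def _build_table() -> list[list[tuple[int, int, int]]]:
    table = []
    for case in range(256):
        inside = tuple(bool(case >> v & 1) for v in range(8))
        table.append(_build_case(inside))
    return table


_CASE_TABLE = _build_table()


@dataclass
class Mesh:
    """Triangle mesh with unit per-vertex normals and optional RGBA colors."""

    vertices: np.ndarray  # (n, 3) float
    normals: np.ndarray  # (n, 3) float, unit length
    triangles: np.ndarray  # (m, 3) int
    vertex_colors: np.ndarray | None = None  # (n, 4) uint8

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @staticmethod
    def empty() -> "Mesh":
        return Mesh(np.zeros((0, 3)), np.zeros((0, 3)), np.zeros((0, 3), dtype=int))


def mesh_area(mesh: Mesh) -> float:
    """Total surface area as the sum of triangle areas."""
    if mesh.n_triangles == 0:
        return 0.0
    v = mesh.vertices
    t = mesh.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def _gradient_normals(values: np.ndarray, verts_idx: np.ndarray, spacing: float) -> np.ndarray:
    """Central-difference gradient trilinearly interpolated at vertex positions.

    ``verts_idx`` holds vertex positions in fractional grid-index coordinates.
    """
    gx, gy, gz = np.gradient(values, spacing)
    grads = np.stack([gx, gy, gz], axis=-1)
    nx, ny, nz = values.shape
    ijk = np.floor(verts_idx).astype(int)
    ijk = np.clip(ijk, 0, [nx - 2, ny - 2, nz - 2])
    frac = verts_idx - ijk
    out = np.zeros((len(verts_idx), 3))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                out += w[:, None] * grads[ijk[:, 0] + dx, ijk[:, 1] + dy, ijk[:, 2] + dz]
    norms = np.linalg.norm(out, axis=1)
    norms[norms == 0] = 1.0
    return out / norms[:, None]


def marching_cubes(grid, iso: float = 0.0) -> Mesh:
    """Extract the ``iso`` level set of a :class:`~molray.surface.ScalarGrid`.

    Returns an empty mesh for an all-positive or all-negative field.  Edge
    vertices are placed by linear interpolation of the node values; shared
    edge vertices are merged so the mesh is watertight away from the grid
    boundary.
    """
    values = np.asarray(grid.values, dtype=float)
    nx, ny, nz = values.shape
    spacing = float(grid.spacing)
    origin = np.asarray(grid.origin, dtype=float)
    inside = values < iso
    if not inside.any() or inside.all():
        return Mesh.empty()

    # case index per cell
    case = np.zeros((nx - 1, ny - 1, nz - 1), dtype=np.uint16)
    for v, (cx, cy, cz) in enumerate(_CORNERS):
        case |= (
            inside[cx : nx - 1 + cx, cy : ny - 1 + cy, cz : nz - 1 + cz].astype(np.uint16) << v
        )

    # global edge vertices: edge key = axis * n_nodes + flat base-node index
    n_nodes = nx * ny * nz
    strides = np.array([ny * nz, nz, 1])

    def node_flat(ix, iy, iz):
        return ix * strides[0] + iy * strides[1] + iz

    edge_keys: list[np.ndarray] = []
    edge_verts: list[np.ndarray] = []
    axes_shift = [np.array([1, 0, 0]), np.array([0, 1, 0]), np.array([0, 0, 1])]
    for axis, shift in enumerate(axes_shift):
        sl0 = tuple(slice(0, dim - s) for dim, s in zip((nx, ny, nz), shift))
        sl1 = tuple(slice(s, dim) for dim, s in zip((nx, ny, nz), shift))
        v0 = values[sl0]
        v1 = values[sl1]
        crossed = (v0 < iso) != (v1 < iso)
        idx = np.argwhere(crossed)
        if len(idx) == 0:
            edge_keys.append(np.empty(0, dtype=np.int64))
            edge_verts.append(np.empty((0, 3)))
            continue
        a = v0[crossed]
        b = v1[crossed]
        t = (iso - a) / (b - a)
        pos = idx.astype(float)
        pos[:, axis] += t
        edge_keys.append(axis * n_nodes + node_flat(idx[:, 0], idx[:, 1], idx[:, 2]))
        edge_verts.append(pos)

    all_keys = np.concatenate(edge_keys)
    all_pos = np.concatenate(edge_verts)
    order = np.argsort(all_keys)
    sorted_keys = all_keys[order]
    verts_idx = all_pos[order]  # fractional grid-index coordinates

    # local edge -> (axis, base-node offset) for a cell at (i, j, k)
    local_edge_spec = []
    for a, b in _EDGES:
        ca, cb = _CORNERS[a], _CORNERS[b]
        diff = cb - ca
        if diff.sum() < 0 or (diff < 0).any():
            ca, cb = cb, ca
            diff = -diff
        axis = int(np.argmax(diff != 0))
        local_edge_spec.append((axis, ca))

    tris: list[np.ndarray] = []
    cell_idx = np.argwhere((case != 0) & (case != 255))
    if len(cell_idx) == 0:
        return Mesh.empty()
    cell_cases = case[cell_idx[:, 0], cell_idx[:, 1], cell_idx[:, 2]]

    def edge_key_for(cells: np.ndarray, local_edge: int) -> np.ndarray:
        axis, base = local_edge_spec[local_edge]
        bx = cells[:, 0] + base[0]
        by = cells[:, 1] + base[1]
        bz = cells[:, 2] + base[2]
        return axis * n_nodes + node_flat(bx, by, bz)

    for c in np.unique(cell_cases):
        case_tris = _CASE_TABLE[int(c)]
        if not case_tris:
            continue
        cells = cell_idx[cell_cases == c]
        for e0, e1, e2 in case_tris:
            k0 = np.searchsorted(sorted_keys, edge_key_for(cells, e0))
            k1 = np.searchsorted(sorted_keys, edge_key_for(cells, e1))
            k2 = np.searchsorted(sorted_keys, edge_key_for(cells, e2))
            tris.append(np.stack([k0, k1, k2], axis=1))

    triangles = np.concatenate(tris) if tris else np.zeros((0, 3), dtype=int)
    vertices = origin + verts_idx * spacing
    normals = _gradient_normals(values, verts_idx, spacing)
    return Mesh(vertices=vertices, normals=normals, triangles=triangles)
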