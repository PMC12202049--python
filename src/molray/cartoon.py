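"""Cartoon ribbon mesh: spline sweep of class-dependent cross-sections.

Each chain's alpha-carbon trace is interpolated with a centripetal
Catmull-Rom spline; a rotation-minimizing frame (double-reflection method)
is propagated along the samples and a cross-section is swept and stitched
into a closed triangle mesh:

- coil: circular tube, radius 0.3 A
- helix: elliptic ribbon, 1.1 x 0.25 A
- sheet: rectangular ribbon, 1.1 x 0.25 A, ending in a 1.6 A-wide
  arrowhead over the last residue of each sheet run

Chains with fewer than two CA atoms are skipped with a warning.
"""

from __future__ import annotations

import logging

import numpy as np

from .marching_cubes import Mesh
from .model import MoleculeSystem
from .secondary import COIL, HELIX, SHEET, SecondaryStructure, assign_secondary_structure

logger = logging.getLogger(__name__)

__all__ = ["build_cartoon"]

_RING = 12  # points per cross-section


def _catmull_rom_chain(points: np.ndarray, samples_per_segment: int) -> np.ndarray:
    """Centripetal Catmull-Rom curve through all points (endpoints included)."""
    n = len(points)
    ext = np.vstack(
        [2 * points[0] - points[1], points, 2 * points[-1] - points[-2]]
    )
    out = []
    for seg in range(n - 1):
        p0, p1, p2, p3 = ext[seg : seg + 4]
        # centripetal knots
        t0 = 0.0
        t1 = t0 + max(np.linalg.norm(p1 - p0), 1e-8) ** 0.5
        t2 = t1 + max(np.linalg.norm(p2 - p1), 1e-8) ** 0.5
        t3 = t2 + max(np.linalg.norm(p3 - p2), 1e-8) ** 0.5
        last = seg == n - 2
        ts = np.linspace(t1, t2, samples_per_segment, endpoint=False)
        if last:
            ts = np.append(ts, t2)
        for t in ts:
            a1 = (t1 - t) / (t1 - t0) * p0 + (t - t0) / (t1 - t0) * p1
            a2 = (t2 - t) / (t2 - t1) * p1 + (t - t1) / (t2 - t1) * p2
            a3 = (t3 - t) / (t3 - t2) * p2 + (t - t2) / (t3 - t2) * p3
            b1 = (t2 - t) / (t2 - t0) * a1 + (t - t0) / (t2 - t0) * a2
            b2 = (t3 - t) / (t3 - t1) * a2 + (t - t1) / (t3 - t1) * a3
            c = (t2 - t) / (t2 - t1) * b1 + (t - t1) / (t2 - t1) * b2
            out.append(c)
    return np.array(out)


def _tangents(curve: np.ndarray) -> np.ndarray:
    t = np.gradient(curve, axis=0)
    norms = np.linalg.norm(t, axis=1)
    norms[norms == 0] = 1.0
    return t / norms[:, None]


def _rmf_frames(curve: np.ndarray, tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing normal/binormal along the curve (double reflection)."""
    m = len(curve)
    normals = np.zeros((m, 3))
    # initial normal: any unit vector perpendicular to the first tangent
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0]) if abs(t0[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    n0 = np.cross(t0, ref)
    n0 /= np.linalg.norm(n0)
    normals[0] = n0
    for i in range(m - 1):
        v1 = curve[i + 1] - curve[i]
        c1 = float(v1 @ v1)
        if c1 < 1e-14:
            normals[i + 1] = normals[i]
            continue
        rL = normals[i] - (2.0 / c1) * (v1 @ normals[i]) * v1
        tL = tangents[i] - (2.0 / c1) * (v1 @ tangents[i]) * v1
        v2 = tangents[i + 1] - tL
        c2 = float(v2 @ v2)
        n_next = rL if c2 < 1e-14 else rL - (2.0 / c2) * (v2 @ rL) * v2
        n_next -= (n_next @ tangents[i + 1]) * tangents[i + 1]
        n_next /= np.linalg.norm(n_next)
        normals[i + 1] = n_next
    binormals = np.cross(tangents, normals)
    return normals, binormals


def _section_offsets(width: float, height: float, rectangular: bool) -> np.ndarray:
    """(RING, 2) local cross-section coordinates (half-axes width/height)."""
    theta = np.linspace(0, 2 * np.pi, _RING, endpoint=False)
    x = np.cos(theta)
    y = np.sin(theta)
    if rectangular:
        scale = 1.0 / np.maximum(np.abs(x) / max(width, 1e-9), np.abs(y) / max(height, 1e-9))
        return np.stack([x * scale, y * scale], axis=1)
    return np.stack([x * width, y * height], axis=1)


def build_cartoon(
    system: MoleculeSystem,
    subdivisions_per_residue: int = 8,
    ss: SecondaryStructure | None = None,
    atom_colors: np.ndarray | None = None,
) -> Mesh:
    """Cartoon mesh over all chains with at least two CA atoms."""
    if subdivisions_per_residue < 1:
        raise ValueError("subdivisions_per_residue must be >= 1")
    if ss is None:
        ss = assign_secondary_structure(system)
    first_atom: dict[tuple[str, int], int] = {}
    for a in system.atoms:
        first_atom.setdefault((a.chain_id, a.residue_seq), a.index)

    all_verts: list[np.ndarray] = []
    all_tris: list[np.ndarray] = []
    all_cols: list[np.ndarray] = []
    base = 0

    for chain in system.chain_ids():
        ca = system.ca_atoms(chain)
        if len(ca) < 2:
            if ca:
                logger.warning("chain %s has < 2 CA atoms; skipped by cartoon", chain)
            continue
        pts = np.array([a.position for a in ca])
        n_res = len(ca)
        sub = subdivisions_per_residue
        curve = _catmull_rom_chain(pts, sub)
        tangents = _tangents(curve)
        normals, binormals = _rmf_frames(curve, tangents)
        m = len(curve)

        classes = [ss.of(chain, a.residue_seq) for a in ca]
        # arrowhead flags: last residue of each sheet run
        arrow = [
            classes[k] == SHEET and (k + 1 == n_res or classes[k + 1] != SHEET)
            for k in range(n_res)
        ]

        def res_halfsize(k: int) -> tuple[float, float, bool]:
            c = classes[min(k, n_res - 1)]
            if c == HELIX:
                return 0.55, 0.125, False
            if c == SHEET:
                return 0.55, 0.125, True
            return 0.3, 0.3, False

        verts = np.empty((m, _RING, 3))
        cols = np.empty((m, _RING, 4), dtype=np.uint8) if atom_colors is not None else None
        for i in range(m):
            u = i / sub  # residue-parameter in [0, n_res - 1]
            k = min(int(np.floor(u)), n_res - 2)
            frac = u - k
            w0, h0, rect0 = res_halfsize(k)
            w1, h1, rect1 = res_halfsize(k + 1)
            w = (1 - frac) * w0 + frac * w1
            h = (1 - frac) * h0 + frac * h1
            rect = rect0 or rect1
            if arrow[k + 1] and classes[min(k, n_res - 1)] == SHEET:
                # taper from full arrow width down to a point over the last
                # residue of the sheet run
                w = (1 - frac) * 0.8 + frac * 0.05
                h = 0.125
                rect = True
            offs = _section_offsets(w, h, rect)
            verts[i] = (
                curve[i]
                + offs[:, 0:1] * normals[i][None, :]
                + offs[:, 1:2] * binormals[i][None, :]
            )
            if cols is not None:
                res_atom = ca[min(int(round(u)), n_res - 1)]
                cols[i] = atom_colors[first_atom[(chain, res_atom.residue_seq)]]

        tris = []
        for i in range(m - 1):
            for j in range(_RING):
                a = i * _RING + j
                b = i * _RING + (j + 1) % _RING
                c = (i + 1) * _RING + j
                d = (i + 1) * _RING + (j + 1) % _RING
                tris.append((a, b, c))
                tris.append((b, d, c))
        flat_verts = verts.reshape(-1, 3)
        # end caps: center fan
        cap0 = len(flat_verts)
        cap1 = cap0 + 1
        flat_verts = np.vstack([flat_verts, curve[0], curve[-1]])
        for j in range(_RING):
            tris.append((cap0, (j + 1) % _RING, j))
            last0 = (m - 1) * _RING
            tris.append((cap1, last0 + j, last0 + (j + 1) % _RING))

        all_verts.append(flat_verts)
        all_tris.append(np.array(tris, dtype=int) + base)
        if cols is not None:
            flat_cols = cols.reshape(-1, 4)
            cap_col = np.vstack([flat_cols[0], flat_cols[-1]])
            all_cols.append(np.vstack([flat_cols, cap_col]))
        base += len(flat_verts)

    if not all_verts:
        return Mesh.empty()
    vertices = np.vstack(all_verts)
    triangles = np.vstack(all_tris)
    normals = _vertex_normals(vertices, triangles)
    colors = np.vstack(all_cols) if all_cols else None
    return Mesh(vertices=vertices, normals=normals, triangles=triangles, vertex_colors=colors)


def _vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    normals = np.zeros_like(vertices)
    v0 = vertices[triangles[:, 0]]
    face_n = np.cross(vertices[triangles[:, 1]] - v0, vertices[triangles[:, 2]] - v0)
    for col in range(3):
        np.add.at(normals, triangles[:, col], face_n)
    lens = np.linalg.norm(normals, axis=1)
    degenerate = lens < 1e-12
    normals[degenerate] = (0.0, 0.0, 1.0)
    lens[degenerate] = 1.0
    return normals / lens[:, None]
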