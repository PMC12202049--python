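"""Wavefront OBJ export/import for triangle meshes (v/vn/f records)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_obj", "read_obj"]


def write_obj(mesh, path: str | Path) -> None:
    """Write a triangle mesh with per-vertex normals; 1-based indices.

    An empty mesh produces a valid file containing only the header comment.
    NaN/inf vertices are rejected.
    """
    verts = np.asarray(mesh.vertices, dtype=float).reshape(-1, 3)
    normals = np.asarray(mesh.normals, dtype=float).reshape(-1, 3)
    tris = np.asarray(mesh.triangles, dtype=int).reshape(-1, 3)
    if verts.size and not np.all(np.isfinite(verts)):
        raise ValueError("mesh contains non-finite vertices")
    lines = ["# molray triangle mesh"]
    for v in verts:
        lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    for n in normals:
        lines.append(f"vn {n[0]:.6f} {n[1]:.6f} {n[2]:.6f}")
    for t in tris:
        a, b, c = t + 1
        lines.append(f"f {a}//{a} {b}//{b} {c}//{c}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_obj(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimal OBJ reader returning (vertices, normals, triangles)."""
    verts, normals, tris = [], [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "vn":
            normals.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            tris.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return (
        np.array(verts, dtype=float).reshape(-1, 3),
        np.array(normals, dtype=float).reshape(-1, 3),
        np.array(tris, dtype=int).reshape(-1, 3),
    )
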