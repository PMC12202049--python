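"""Renderable geometry builders: implicit primitive lists and color schemes.

Representations backed by implicit primitives (van der Waals, solvent
accessible surface, sticks, ball-and-sticks) produce sphere/cylinder lists
that the ray-caster evaluates analytically per pixel; mesh representations
(SES, cartoon) are built elsewhere and attached to the same Scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .marching_cubes import Mesh
from .model import MoleculeSystem, Selection
from .periodic import COLOR_FALLBACK, ELEMENT_COLORS, normalize_element

__all__ = [
    "SpherePrim",
    "CylinderPrim",
    "Label",
    "Scene",
    "build_vdw",
    "build_sas_spheres",
    "build_sticks",
    "build_ball_and_stick",
    "assign_colors",
    "CHAIN_PALETTE",
]

RGBA = tuple[int, int, int, int]

# deterministic 10-color palette cycled by chain order of first appearance
CHAIN_PALETTE: tuple[RGBA, ...] = (
    (102, 194, 165, 255),
    (252, 141, 98, 255),
    (141, 160, 203, 255),
    (231, 138, 195, 255),
    (166, 216, 84, 255),
    (255, 217, 47, 255),
    (229, 196, 148, 255),
    (179, 179, 179, 255),
    (27, 158, 119, 255),
    (217, 95, 2, 255),
)


@dataclass
class SpherePrim:
    center: np.ndarray
    radius: float
    color: RGBA
    atom_ref: int = -1
    union_group: int = -1  # spheres sharing a group render only their union boundary

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class CylinderPrim:
    """Open cylinder between two points; color split at the midpoint."""

    end_a: np.ndarray
    end_b: np.ndarray
    radius: float
    color_a: RGBA
    color_b: RGBA
    atom_refs: tuple[int, int] = (-1, -1)

    def __post_init__(self) -> None:
        self.end_a = np.asarray(self.end_a, dtype=float).reshape(3)
        self.end_b = np.asarray(self.end_b, dtype=float).reshape(3)
        if np.linalg.norm(self.end_b - self.end_a) == 0:
            raise ValueError("cylinder endpoints coincide")
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")


@dataclass
class Label:
    """Measurement annotation anchored in model space."""

    anchor: np.ndarray
    text: str

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float).reshape(3)


@dataclass
class Scene:
    spheres: list[SpherePrim] = field(default_factory=list)
    cylinders: list[CylinderPrim] = field(default_factory=list)
    meshes: list[Mesh] = field(default_factory=list)
    labels: list[Label] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (self.spheres or self.cylinders or self.meshes)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounds of all renderable geometry."""
        los, his = [], []
        for s in self.spheres:
            los.append(s.center - s.radius)
            his.append(s.center + s.radius)
        for c in self.cylinders:
            lo = np.minimum(c.end_a, c.end_b) - c.radius
            hi = np.maximum(c.end_a, c.end_b) + c.radius
            los.append(lo)
            his.append(hi)
        for m in self.meshes:
            if m.n_vertices:
                los.append(m.vertices.min(axis=0))
                his.append(m.vertices.max(axis=0))
        if not los:
            raise ValueError("scene is empty")
        return np.min(los, axis=0), np.max(his, axis=0)


def assign_colors(
    system: MoleculeSystem,
    scheme: str = "element",
    uniform: RGBA | None = None,
) -> np.ndarray:
    """Per-atom RGBA colors, shape (n_atoms, 4) uint8.

    ``scheme`` is one of ``element`` (CPK-style table, pink fallback),
    ``chain`` (10-color palette cycled by chain first appearance) or
    ``uniform`` (requires ``uniform=(r, g, b, a)``).
    """
    n = system.n_atoms
    out = np.empty((n, 4), dtype=np.uint8)
    if scheme == "uniform":
        if uniform is None:
            raise ValueError("uniform scheme requires a color")
        out[:] = uniform
    elif scheme == "element":
        for k, a in enumerate(system.atoms):
            out[k] = ELEMENT_COLORS.get(normalize_element(a.element), COLOR_FALLBACK)
    elif scheme == "chain":
        order = {cid: i for i, cid in enumerate(system.chain_ids())}
        for k, a in enumerate(system.atoms):
            out[k] = CHAIN_PALETTE[order[a.chain_id] % len(CHAIN_PALETTE)]
    else:
        raise ValueError(f"unknown color scheme {scheme!r}")
    return out


def _as_rgba(row: np.ndarray) -> RGBA:
    return (int(row[0]), int(row[1]), int(row[2]), int(row[3]))


def build_vdw(
    system: MoleculeSystem,
    selection: Selection | None = None,
    scale: float = 1.0,
    colors: np.ndarray | None = None,
) -> list[SpherePrim]:
    """One sphere per selected atom with radius ``scale * vdw_radius``."""
    sel = selection if selection is not None else Selection.all_of(system)
    cols = colors if colors is not None else assign_colors(system)
    return [
        SpherePrim(
            center=system.atoms[i].position.copy(),
            radius=scale * system.atoms[i].vdw_radius,
            color=_as_rgba(cols[i]),
            atom_ref=i,
        )
        for i in sel
    ]


def build_sas_spheres(
    system: MoleculeSystem,
    selection: Selection | None = None,
    probe: float = 1.4,
    colors: np.ndarray | None = None,
    union_group: int = 0,
) -> list[SpherePrim]:
    """Probe-inflated spheres sharing one union group (only the union
    boundary is shaded by the renderer)."""
    sel = selection if selection is not None else Selection.all_of(system)
    cols = colors if colors is not None else assign_colors(system)
    return [
        SpherePrim(
            center=system.atoms[i].position.copy(),
            radius=system.atoms[i].vdw_radius + probe,
            color=_as_rgba(cols[i]),
            atom_ref=i,
            union_group=union_group,
        )
        for i in sel
    ]


def build_sticks(
    system: MoleculeSystem,
    selection: Selection | None = None,
    radius: float = 0.15,
    colors: np.ndarray | None = None,
) -> tuple[list[CylinderPrim], list[SpherePrim]]:
    """Bond cylinders plus cap spheres.

    A cylinder is emitted for every bond whose two endpoints are both
    selected; every selected atom gets a cap sphere of the stick radius
    (isolated atoms included, so they stay visible).
    """
    sel = selection if selection is not None else Selection.all_of(system)
    sel_set = set(sel)
    cols = colors if colors is not None else assign_colors(system)
    cylinders = [
        CylinderPrim(
            end_a=system.atoms[b.i].position.copy(),
            end_b=system.atoms[b.j].position.copy(),
            radius=radius,
            color_a=_as_rgba(cols[b.i]),
            color_b=_as_rgba(cols[b.j]),
            atom_refs=(b.i, b.j),
        )
        for b in system.bonds
        if b.i in sel_set and b.j in sel_set
    ]
    caps = [
        SpherePrim(
            center=system.atoms[i].position.copy(),
            radius=radius,
            color=_as_rgba(cols[i]),
            atom_ref=i,
        )
        for i in sel
    ]
    return cylinders, caps


def build_ball_and_stick(
    system: MoleculeSystem,
    selection: Selection | None = None,
    ball_scale: float = 0.3,
    stick_radius: float = 0.15,
    colors: np.ndarray | None = None,
) -> tuple[list[SpherePrim], list[CylinderPrim]]:
    """Scaled vdW spheres plus bond cylinders."""
    spheres = build_vdw(system, selection, scale=ball_scale, colors=colors)
    cylinders, _ = build_sticks(system, selection, radius=stick_radius, colors=colors)
    return spheres, cylinders
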