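"""In-memory molecular data model.

A :class:`MoleculeSystem` stores a flat atom table, an explicit bond list and
one or more coordinate frames (trajectory snapshots).  All coordinates are in
Angstrom; atom indices are 0-based and unique within a system.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .periodic import (
    COVALENT_FALLBACK,
    COVALENT_RADII,
    VDW_FALLBACK,
    VDW_RADII,
    normalize_element,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Bond",
    "MoleculeSystem",
    "Selection",
    "assign_radii",
    "perceive_bonds",
    "set_active_frame",
]


@dataclass
class Atom:
    """One atom: identity, position and per-atom annotations."""

    index: int
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom (active-frame coordinates)
    vdw_radius: float = 0.0
    covalent_radius: float = 0.0
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = " "
    chain_id: str = "A"
    residue_name: str = "UNK"
    residue_seq: int = 1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.index}: non-finite position")


@dataclass(frozen=True, order=True)
class Bond:
    """Undirected bond stored with i < j."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if not self.i < self.j:
            raise ValueError(f"bond indices must satisfy i < j, got ({self.i}, {self.j})")


@dataclass
class MoleculeSystem:
    """Atoms + bonds + trajectory frames.

    ``frames[active_frame]`` holds the coordinates all geometry is built
    from; ``Atom.position`` views are refreshed whenever the active frame
    changes.
    """

    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    frames: list[np.ndarray] = field(default_factory=list)
    active_frame: int = 0
    # secondary-structure metadata from file records: (kind, chain, start, end)
    ss_records: list[tuple[str, str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if not self.frames:
            coords = np.array([a.position for a in self.atoms], dtype=float).reshape(n, 3)
            self.frames = [coords]
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(f"frame {k} has shape {f.shape}, expected ({n}, 3)")
        if not 0 <= self.active_frame < len(self.frames):
            raise IndexError(f"active_frame {self.active_frame} out of range")
        seen = set()
        for b in self.bonds:
            if b.i >= n or b.j >= n:
                raise ValueError(f"bond ({b.i}, {b.j}) references missing atom")
            if (b.i, b.j) in seen:
                raise ValueError(f"duplicate bond ({b.i}, {b.j})")
            seen.add((b.i, b.j))
        self._sync_positions()

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def coordinates(self) -> np.ndarray:
        """Active-frame coordinates, shape (n_atoms, 3)."""
        return self.frames[self.active_frame]

    def _sync_positions(self) -> None:
        coords = self.frames[self.active_frame]
        for atom, row in zip(self.atoms, coords):
            atom.position = row

    # -- hierarchy helpers -------------------------------------------------

    def chain_ids(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def ca_atoms(self, chain_id: str | None = None) -> list[Atom]:
        """Alpha carbons (name CA, element C or CA-only pseudo atoms), file order."""
        out = []
        for a in self.atoms:
            if a.name.strip() != "CA":
                continue
            if normalize_element(a.element) == "CA":
                continue  # calcium ion, not an alpha carbon
            if chain_id is not None and a.chain_id != chain_id:
                continue
            out.append(a)
        return out


@dataclass(frozen=True)
class Selection:
    """Ordered, duplicate-free set of atom indices into one system."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection contains duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __contains__(self, idx: int) -> bool:
        return idx in set(self.indices)

    @staticmethod
    def all_of(system: MoleculeSystem) -> "Selection":
        return Selection(tuple(range(system.n_atoms)))


# ---------------------------------------------------------------------------
# operations


def assign_radii(
    system: MoleculeSystem,
    vdw_table: dict[str, float] | None = None,
    covalent_table: dict[str, float] | None = None,
) -> MoleculeSystem:
    """Assign van der Waals and covalent radii from element symbols, in place.

    Unknown elements receive the documented fallbacks (1.50 / 0.76 A) and a
    warning is logged once per unknown element.  Idempotent.
    """
    vdw = VDW_RADII if vdw_table is None else vdw_table
    cov = COVALENT_RADII if covalent_table is None else covalent_table
    warned: set[str] = set()
    for atom in system.atoms:
        el = normalize_element(atom.element)
        if el not in vdw and el not in warned:
            logger.warning("unknown element %r: using fallback radii", atom.element)
            warned.add(el)
        atom.vdw_radius = vdw.get(el, VDW_FALLBACK)
        atom.covalent_radius = cov.get(el, COVALENT_FALLBACK)
    return system


def perceive_bonds(
    system: MoleculeSystem,
    tol: float = 0.4,
    min_dist: float = 0.4,
) -> list[Bond]:
    """Distance-based bond perception on the active frame.

    A pair (i, j) is bonded iff ``min_dist < |pi - pj| < cov_i + cov_j + tol``.
    Uses a k-d tree so cost is near-linear in atom count.  The returned list
    is sorted (i < j, lexicographic) and therefore independent of atom input
    order up to index relabeling.
    """
    n = system.n_atoms
    if n < 2:
        return []
    radii = np.array([a.covalent_radius for a in system.atoms])
    if np.any(radii <= 0):
        raise ValueError("covalent radii not assigned; call assign_radii first")
    coords = system.coordinates
    cutoff = 2.0 * float(radii.max()) + tol
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    bonds: list[Bond] = []
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        limit = radii[pairs[:, 0]] + radii[pairs[:, 1]] + tol
        keep = (d > min_dist) & (d < limit)
        for i, j in pairs[keep]:
            i, j = int(i), int(j)
            bonds.append(Bond(min(i, j), max(i, j)))
    bonds.sort()
    return bonds


def set_active_frame(system: MoleculeSystem, k: int) -> MoleculeSystem:
    """Make frame ``k`` the source of all downstream geometry (in place)."""
    if not 0 <= k < system.n_frames:
        raise IndexError(f"frame {k} out of range [0, {system.n_frames})")
    system.active_frame = k
    system._sync_positions()
    return system


def transform_system(system: MoleculeSystem, rotation: np.ndarray, translation: np.ndarray) -> None:
    """Apply a rigid transform to every frame, in place."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if R.shape != (3, 3) or t.shape != (3,):
        raise ValueError("expected 3x3 rotation and 3-vector translation")
    if not math.isclose(abs(float(np.linalg.det(R))), 1.0, abs_tol=1e-6):
        raise ValueError("rotation matrix is not orthonormal")
    system.frames = [f @ R.T + t for f in system.frames]
    system._sync_positions()
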