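"""Deterministic synthetic-structure generators.

Every generator is a pure function of its arguments (and seed where one
exists), so tests never need downloaded data: ideal helices and extended
chains exercise the secondary-structure and cartoon code, sphere clusters
stress the surface and renderer, toy PDB texts exercise the parsers, and the
DCD writer provides a binary round-trip oracle.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .io.dcd import write_dcd
from .model import Atom, MoleculeSystem, assign_radii

__all__ = [
    "make_ideal_helix",
    "make_extended_chain",
    "make_perturbed_helix",
    "make_sphere_cluster",
    "make_toy_pdb_text",
    "write_synthetic_dcd",
    "single_atom_system",
    "water_system",
]

HELIX_RISE = 1.5  # Angstrom per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Angstrom


def _ca_system(positions: np.ndarray, chain_id: str = "A") -> MoleculeSystem:
    atoms = [
        Atom(
            index=k,
            name="CA",
            element="C",
            position=pos,
            chain_id=chain_id,
            residue_name="ALA",
            residue_seq=k + 1,
        )
        for k, pos in enumerate(positions)
    ]
    return assign_radii(MoleculeSystem(atoms=atoms))


def make_ideal_helix(
    n: int,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    radius: float = HELIX_RADIUS,
) -> MoleculeSystem:
    """CA-only helix: CA_k = (r cos(k t), r sin(k t), k rise)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n)
    ang = np.radians(twist) * k
    pos = np.stack([radius * np.cos(ang), radius * np.sin(ang), rise * k], axis=1)
    return _ca_system(pos)


def ideal_helix_ca_distance(
    step: int,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    radius: float = HELIX_RADIUS,
) -> float:
    """Closed-form |CA_k - CA_{k+step}| for the ideal helix generator."""
    ang = np.radians(twist) * step
    chord = 2.0 * radius * np.sin(ang / 2.0)
    return float(np.hypot(chord, rise * step))


def make_extended_chain(n: int, spacing: float = 3.8) -> MoleculeSystem:
    """Collinear CA atoms along x with the given spacing."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pos = np.zeros((n, 3))
    pos[:, 0] = spacing * np.arange(n)
    return _ca_system(pos)


def make_perturbed_helix(n: int, sigma: float = 0.3, seed: int = 0) -> MoleculeSystem:
    """Ideal helix plus seeded Gaussian jitter.

    Breaks the helix's translational self-similarity, which keeps the CE
    alignment search space small while remaining a plausible backbone.
    """
    base = make_ideal_helix(n)
    rng = np.random.default_rng(seed)
    pos = base.coordinates + rng.normal(scale=sigma, size=(n, 3))
    return _ca_system(pos)


def make_sphere_cluster(
    n: int,
    box: float = 30.0,
    min_sep: float = 3.0,
    seed: int = 0,
    max_tries: int = 20000,
) -> MoleculeSystem:
    """n carbon atoms in a cubic box with pairwise separation >= min_sep.

    Rejection sampling with a fixed seed; raises if placement fails within
    the retry budget.
    """
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} atoms with min_sep {min_sep} in box {box}"
            )
        tries += 1
        cand = rng.random(3) * box
        if all(np.linalg.norm(cand - q) >= min_sep for q in placed):
            placed.append(cand)
    atoms = [
        Atom(
            index=k,
            name="C",
            element="C",
            position=p,
            chain_id="A",
            residue_name="LIG",
            residue_seq=k + 1,
        )
        for k, p in enumerate(placed)
    ]
    return assign_radii(MoleculeSystem(atoms=atoms))


def single_atom_system(element: str = "C") -> MoleculeSystem:
    atom = Atom(index=0, name=element, element=element, position=np.zeros(3))
    return assign_radii(MoleculeSystem(atoms=[atom]))


def water_system() -> MoleculeSystem:
    """One water molecule with plausible O-H bond distances (0.96 A)."""
    atoms = [
        Atom(index=0, name="O", element="O", position=np.array([0.0, 0.0, 0.0]),
             residue_name="HOH", residue_seq=1),
        Atom(index=1, name="H1", element="H", position=np.array([0.96, 0.0, 0.0]),
             residue_name="HOH", residue_seq=1),
        Atom(index=2, name="H2", element="H", position=np.array([-0.24, 0.93, 0.0]),
             residue_name="HOH", residue_seq=1),
    ]
    return assign_radii(MoleculeSystem(atoms=atoms))


_TOY_PDB = {
    "minimal": """\
ATOM      1  N   MET A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  MET A   1      12.560   6.351  -6.508  1.00  0.00           C
ATOM      3  C   MET A   1      13.276   5.259  -5.717  1.00  0.00           C
END
""",
    "multimodel": """\
MODEL        1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   GLY A   1       1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       2.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       3.000   1.400   0.000  1.00  0.00           C
ENDMDL
END
""",
    "conect": """\
ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  H1  HOH A   1       0.960   0.000   0.000  1.00  0.00           H
CONECT    1    2
END
""",
    "helix_record": None,  # built programmatically below
    "malformed": """\
ATOM      1  N   MET A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  MET A   1      12.56x   6.351  -6.508  1.00  0.00           C
END
""",
}


def _helix_record_pdb() -> str:
    helix = make_ideal_helix(12)
    lines = ["HELIX    1   1 ALA A    2  ALA A   10  1                                   9"]
    for a in helix.atoms:
        x, y, z = a.position
        lines.append(
            f"ATOM  {a.index + 1:>5}  CA  ALA A{a.residue_seq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_pdb_text(kind: str) -> str:
    """Small PDB fixtures: minimal (3 atoms), multimodel (2 frames),
    conect (1 bond), helix_record (HELIX metadata), malformed (bad float)."""
    if kind == "helix_record":
        return _helix_record_pdb()
    try:
        return _TOY_PDB[kind]
    except KeyError:
        raise ValueError(f"unknown toy PDB kind {kind!r}") from None


def write_synthetic_dcd(frames: list[np.ndarray], path: str | Path, byteorder: str = "<") -> None:
    """Write frames in the CHARMM-style layout the DCD reader consumes."""
    Path(path).write_bytes(write_dcd(frames, byteorder=byteorder))
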