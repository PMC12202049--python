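"""Per-residue secondary-structure classes for the cartoon builder.

File HELIX/SHEET records take precedence when present; otherwise a
CA-geometry heuristic (P-SEA-like distance windows) classifies each residue
from the d(i, i+2), d(i, i+3) and d(i, i+4) alpha-carbon distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Atom, MoleculeSystem

__all__ = ["SecondaryStructure", "assign_secondary_structure"]

HELIX, SHEET, COIL = "helix", "sheet", "coil"


@dataclass
class SecondaryStructure:
    """Class per residue with a CA atom, keyed by (chain_id, residue_seq)."""

    classes: dict[tuple[str, int], str]

    def of(self, chain_id: str, residue_seq: int) -> str:
        return self.classes.get((chain_id, residue_seq), COIL)

    def counts(self) -> dict[str, int]:
        out = {HELIX: 0, SHEET: 0, COIL: 0}
        for v in self.classes.values():
            out[v] += 1
        return out


def _classify_geometry(ca: list[Atom]) -> list[str]:
    n = len(ca)
    if n < 5:
        return [COIL] * n
    pos = np.array([a.position for a in ca])

    def d(i: int, j: int) -> float:
        return float(np.linalg.norm(pos[i] - pos[j]))

    cls = [COIL] * n
    for i in range(n):
        if i + 4 >= n:
            continue
        d13 = d(i, i + 2)
        d14 = d(i, i + 3)
        d15 = d(i, i + 4)
        if 4.8 <= d13 <= 5.8 and 4.9 <= d14 <= 6.1 and 5.7 <= d15 <= 6.6:
            cls[i] = HELIX
        elif d13 >= 6.4 and d14 >= 9.0:
            cls[i] = SHEET
    # runs shorter than 3 residues revert to coil
    i = 0
    while i < n:
        j = i
        while j < n and cls[j] == cls[i]:
            j += 1
        if cls[i] != COIL and j - i < 3:
            for k in range(i, j):
                cls[k] = COIL
        i = j
    return cls


def assign_secondary_structure(system: MoleculeSystem) -> SecondaryStructure:
    """Secondary structure for every residue that has a CA atom."""
    classes: dict[tuple[str, int], str] = {}
    for chain in system.chain_ids():
        ca = system.ca_atoms(chain)
        if not ca:
            continue
        if system.ss_records:
            for a in ca:
                classes[(chain, a.residue_seq)] = COIL
            for kind, rec_chain, start, end in system.ss_records:
                if rec_chain != chain:
                    continue
                for a in ca:
                    if start <= a.residue_seq <= end:
                        classes[(chain, a.residue_seq)] = kind
        else:
            for a, c in zip(ca, _classify_geometry(ca)):
                classes[(chain, a.residue_seq)] = c
    return SecondaryStructure(classes)
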