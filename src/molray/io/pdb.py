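"""Fixed-column PDB reader.

Supports ATOM/HETATM, MODEL/ENDMDL multi-frame files, CONECT connectivity and
HELIX/SHEET secondary-structure records.  Element symbols are taken from
columns 77-78 when present, otherwise inferred from the atom name.
"""

from __future__ import annotations

import numpy as np

from ..model import Atom, Bond, MoleculeSystem
from ..periodic import TWO_LETTER_ELEMENTS, normalize_element

__all__ = ["read_pdb", "PDBParseError", "EmptyStructureError", "infer_element"]


class PDBParseError(ValueError):
    """Malformed PDB content; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class EmptyStructureError(PDBParseError):
    """File contained no ATOM/HETATM records."""


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name.

    Strategy: if the name occupies column 13 (first of the 4-char field) and
    its first two characters form a known two-letter element (FE, CL, ...)
    use that; otherwise take the first alphabetic character.
    """
    raw = atom_name
    stripped = raw.strip()
    if not stripped:
        return ""
    two = stripped[:2].upper()
    # Names starting in column 13 (no leading blank) signal two-letter elements
    # in standard PDB files; "1HB " style hydrogens start with a digit.
    if len(raw) >= 2 and raw[0] != " " and two.isalpha() and two in TWO_LETTER_ELEMENTS:
        return two.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _float(field: str, what: str, lineno: int) -> float:
    try:
        return float(field)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {field.strip()!r}", lineno) from None


def _int(field: str, what: str, lineno: int) -> int:
    try:
        return int(field)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {field.strip()!r}", lineno) from None


def read_pdb(text: str, keep_altlocs: tuple[str, ...] = (" ", "A")) -> MoleculeSystem:
    """Parse PDB text into a :class:`MoleculeSystem`.

    MODEL blocks become trajectory frames (the first model defines the atom
    table).  CONECT records become bonds; HELIX/SHEET records are retained as
    ``ss_records`` metadata.  Alternate locations outside ``keep_altlocs``
    are dropped.
    """
    atoms: list[Atom] = []
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    serial_to_index: dict[int, int] = {}
    bonds: set[tuple[int, int]] = set()
    ss_records: list[tuple[str, str, int, int]] = []
    n_models = 0
    first_model_done = False
    atoms_in_current = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            altloc = line[16] if len(line) > 16 else " "
            if altloc not in keep_altlocs:
                continue
            x = _float(line[30:38], "x", lineno)
            y = _float(line[38:46], "y", lineno)
            z = _float(line[46:54], "z", lineno)
            atoms_in_current += 1
            current.append((x, y, z))
            if first_model_done:
                continue
            serial_field = line[6:11].strip()
            serial = _int(serial_field, "serial", lineno) if serial_field else len(atoms) + 1
            name = line[12:16] if len(line) >= 16 else line[12:].ljust(4)
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = infer_element(name)
            occ_field = line[54:60].strip()
            bf_field = line[60:66].strip()
            atoms.append(
                Atom(
                    index=len(atoms),
                    name=name,
                    element=element,
                    position=np.array([x, y, z]),
                    occupancy=_float(occ_field, "occupancy", lineno) if occ_field else 1.0,
                    bfactor=_float(bf_field, "bfactor", lineno) if bf_field else 0.0,
                    altloc=altloc,
                    chain_id=line[21] if len(line) > 21 else "A",
                    residue_name=line[17:20].strip() or "UNK",
                    residue_seq=_int(line[22:26], "residue number", lineno)
                    if line[22:26].strip()
                    else 1,
                )
            )
            serial_to_index[serial] = len(atoms) - 1
        elif rec == "MODEL ":
            atoms_in_current = 0
            current = []
        elif rec == "ENDMDL":
            if atoms_in_current:
                if first_model_done and atoms_in_current != len(atoms):
                    raise PDBParseError(
                        f"model {n_models + 1} has {atoms_in_current} atoms, "
                        f"expected {len(atoms)}",
                        lineno,
                    )
                frames.append(current)
                n_models += 1
                first_model_done = True
            current = []
            atoms_in_current = 0
        elif rec == "CONECT":
            fields = [line[i : i + 5].strip() for i in range(6, min(len(line), 31), 5)]
            serials = [_int(f, "CONECT serial", lineno) for f in fields if f]
            if len(serials) >= 2:
                a = serial_to_index.get(serials[0])
                if a is not None:
                    for s in serials[1:]:
                        b = serial_to_index.get(s)
                        if b is not None and a != b:
                            bonds.add((min(a, b), max(a, b)))
        elif rec == "HELIX ":
            chain = line[19] if len(line) > 19 else " "
            start = _int(line[21:25], "HELIX start", lineno)
            end = _int(line[33:37], "HELIX end", lineno)
            ss_records.append(("helix", chain, start, end))
        elif rec == "SHEET ":
            chain = line[21] if len(line) > 21 else " "
            start = _int(line[22:26], "SHEET start", lineno)
            end = _int(line[33:37], "SHEET end", lineno)
            ss_records.append(("sheet", chain, start, end))

    if current:
        if first_model_done and atoms_in_current != len(atoms):
            raise PDBParseError(
                f"truncated final model ({atoms_in_current} of {len(atoms)} atoms)",
                lineno,
            )
        frames.append(current)
    if not atoms:
        raise EmptyStructureError("no ATOM/HETATM records found", 0)

    frame_arrays = [np.array(f, dtype=float) for f in frames if f]
    system = MoleculeSystem(
        atoms=atoms,
        bonds=sorted(Bond(i, j) for i, j in bonds),
        frames=frame_arrays,
        ss_records=ss_records,
    )
    return system
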