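"""Streaming mmCIF (PDBx) atom_site reader.

Only the ``_atom_site`` loop is interpreted; everything else is skipped in a
single pass, so memory use beyond coordinate storage is bounded even for
multi-million-atom files.  CIF quoting rules (single/double quotes,
``;``-delimited text fields) are honored for data rows.
"""

from __future__ import annotations

import re
from typing import Iterator

import numpy as np

from ..model import Atom, MoleculeSystem
from .pdb import infer_element

__all__ = ["read_mmcif", "MMCIFParseError"]


class MMCIFParseError(ValueError):
    pass


_QUOTED_RE = re.compile(
    r"""\s*(?:
        '(?P<sq>(?:[^']|'(?=\S))*)'(?=\s|$) |
        "(?P<dq>(?:[^"]|"(?=\S))*)"(?=\s|$) |
        (?P<bare>\S+)
    )""",
    re.VERBOSE,
)


def _tokenize_line(line: str) -> list[str]:
    # fast path: no quote characters anywhere
    if "'" not in line and '"' not in line:
        return line.split()
    out = []
    pos = 0
    while pos < len(line):
        m = _QUOTED_RE.match(line, pos)
        if m is None:
            break
        tok = m.group("sq")
        if tok is None:
            tok = m.group("dq")
        if tok is None:
            tok = m.group("bare")
        out.append(tok)
        pos = m.end()
    return out


def read_mmcif(text: str) -> MoleculeSystem:
    """Parse mmCIF text into a :class:`MoleculeSystem`.

    Frames are split on ``_atom_site.pdbx_PDB_model_num``; the first model
    defines the atom table.  Raises :class:`MMCIFParseError` if there is no
    atom_site loop or a mandatory column (Cartn_x/y/z, type_symbol) is
    missing.
    """
    lines = iter(enumerate(text.splitlines(), start=1))
    columns: list[str] | None = None

    for lineno, line in lines:
        if line.strip().lower() != "loop_":
            continue
        # gather item names of this loop
        names: list[str] = []
        body_started = False
        for lineno2, line2 in lines:
            stripped = line2.strip()
            if stripped.startswith("_"):
                names.append(stripped.split()[0])
            elif not stripped or stripped.startswith("#"):
                if names:
                    break
                continue
            else:
                body_started = True
                break
        if names and names[0].lower().startswith("_atom_site."):
            columns = [n.split(".", 1)[1] for n in names]
            first_body_line = (lineno2, line2) if body_started else None
            break
        # not the loop we want: keep scanning (body lines fall through)

    if columns is None:
        raise MMCIFParseError("no _atom_site loop found")

    def col(name: str, *alts: str, required: bool = False) -> int | None:
        for cand in (name, *alts):
            if cand in columns:
                return columns.index(cand)
        if required:
            raise MMCIFParseError(f"atom_site loop is missing mandatory column {name!r}")
        return None

    ix = col("Cartn_x", required=True)
    iy = col("Cartn_y", required=True)
    iz = col("Cartn_z", required=True)
    i_el = col("type_symbol", required=True)
    i_name = col("label_atom_id", "auth_atom_id")
    i_chain = col("label_asym_id", "auth_asym_id")
    i_res = col("label_comp_id", "auth_comp_id")
    i_seq = col("label_seq_id", "auth_seq_id")
    i_alt = col("label_alt_id")
    i_occ = col("occupancy")
    i_b = col("B_iso_or_equiv")
    i_model = col("pdbx_PDB_model_num")

    ncol = len(columns)
    atoms: list[Atom] = []
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    current_model: str | None = None
    first_model_done = False

    row: list[str] = []

    def finish_model() -> None:
        nonlocal current, first_model_done
        if not current:
            return
        if first_model_done and len(current) != len(atoms):
            raise MMCIFParseError(
                f"model has {len(current)} atoms, expected {len(atoms)}"
            )
        frames.append(current)
        first_model_done = True
        current = []

    def handle_row(row: list[str], lineno: int) -> None:
        nonlocal current_model
        if i_alt is not None and row[i_alt] not in (".", "?", "A"):
            return
        if i_model is not None:
            model = row[i_model]
            if current_model is None:
                current_model = model
            elif model != current_model:
                finish_model()
                current_model = model
        try:
            xyz = (float(row[ix]), float(row[iy]), float(row[iz]))
        except ValueError:
            raise MMCIFParseError(f"line {lineno}: malformed coordinate") from None
        current.append(xyz)
        if first_model_done:
            return
        element = row[i_el]
        name = row[i_name] if i_name is not None else element
        if element in (".", "?", ""):
            element = infer_element(name)
        seq_raw = row[i_seq] if i_seq is not None else "1"
        try:
            seq = int(seq_raw) if seq_raw not in (".", "?") else len(atoms) + 1
        except ValueError:
            raise MMCIFParseError(f"line {lineno}: malformed residue number {seq_raw!r}") from None
        atoms.append(
            Atom(
                index=len(atoms),
                name=name,
                element=element,
                position=np.array(xyz),
                occupancy=float(row[i_occ]) if i_occ is not None and row[i_occ] not in (".", "?") else 1.0,
                bfactor=float(row[i_b]) if i_b is not None and row[i_b] not in (".", "?") else 0.0,
                altloc=row[i_alt] if i_alt is not None and row[i_alt] not in (".", "?") else " ",
                chain_id=row[i_chain] if i_chain is not None else "A",
                residue_name=row[i_res] if i_res is not None else "UNK",
                residue_seq=seq,
            )
        )

    # stream the loop body (starting with the lookahead line, if any)
    def body_lines() -> Iterator[tuple[int, str]]:
        if first_body_line is not None:
            yield first_body_line
        yield from lines

    for lineno, line in body_lines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            if row:
                raise MMCIFParseError(f"line {lineno}: incomplete atom_site row")
            continue
        if stripped.startswith(("_", "loop_", "data_")):
            break
        if stripped.startswith(";"):
            raise MMCIFParseError(f"line {lineno}: text fields not supported in atom_site")
        for tok in _tokenize_line(stripped):
            row.append(tok)
            if len(row) == ncol:
                handle_row(row, lineno)
                row = []
    if row:
        raise MMCIFParseError("incomplete final atom_site row")

    finish_model()
    if not atoms:
        raise MMCIFParseError("atom_site loop contains no atoms")
    return MoleculeSystem(atoms=atoms, frames=[np.array(f, dtype=float) for f in frames])
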