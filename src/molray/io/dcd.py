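"""CHARMM/NAMD-style DCD trajectory reader and writer.

Layout handled: 84-byte ``CORD`` header block, title block, natoms block,
then per frame one Fortran record each for the x, y and z float32 arrays.
Endianness is auto-detected from the leading record marker.  Unit-cell
records and fixed-atom support are out of scope.
"""

from __future__ import annotations

import struct

import numpy as np

from ..model import MoleculeSystem

__all__ = ["read_dcd", "write_dcd", "DCDError"]

_HEADER_SIZE = 84


class DCDError(ValueError):
    pass


class _Cursor:
    def __init__(self, data: bytes, byteorder: str):
        self.data = data
        self.pos = 0
        self.bo = byteorder  # '<' or '>'

    def record(self, what: str) -> bytes:
        if self.pos + 4 > len(self.data):
            raise DCDError(f"truncated file: missing {what} record")
        (length,) = struct.unpack_from(self.bo + "i", self.data, self.pos)
        end = self.pos + 4 + length + 4
        if length < 0 or end > len(self.data):
            raise DCDError(f"truncated {what} record")
        payload = self.data[self.pos + 4 : self.pos + 4 + length]
        (trailer,) = struct.unpack_from(self.bo + "i", self.data, self.pos + 4 + length)
        if trailer != length:
            raise DCDError(f"corrupt {what} record (marker mismatch)")
        self.pos = end
        return payload

    @property
    def exhausted(self) -> bool:
        return self.pos >= len(self.data)


def _detect_byteorder(data: bytes) -> str:
    if len(data) < 4:
        raise DCDError("not a DCD file (too short)")
    for bo in ("<", ">"):
        (marker,) = struct.unpack_from(bo + "i", data, 0)
        if marker == _HEADER_SIZE:
            return bo
    raise DCDError("not a DCD file (bad leading record marker)")


def read_dcd(data: bytes, system: MoleculeSystem) -> MoleculeSystem:
    """Append the frames of a DCD byte string to ``system`` (in place).

    The per-frame atom count must match ``system.n_atoms``; a truncated
    frame raises :class:`DCDError` naming the frame index.
    """
    bo = _detect_byteorder(data)
    cur = _Cursor(data, bo)

    header = cur.record("header")
    if len(header) != _HEADER_SIZE or header[:4] != b"CORD":
        raise DCDError("not a DCD file (bad header block)")
    cur.record("title")
    natoms_payload = cur.record("natoms")
    if len(natoms_payload) != 4:
        raise DCDError("bad natoms record")
    (natoms,) = struct.unpack(bo + "i", natoms_payload)
    if natoms != system.n_atoms:
        raise DCDError(
            f"atom count mismatch: DCD has {natoms}, system has {system.n_atoms}"
        )

    dtype = np.dtype(bo + "f4")
    frames: list[np.ndarray] = []
    frame_idx = 0
    while not cur.exhausted:
        xyz = []
        for axis in "xyz":
            try:
                payload = cur.record(f"frame {frame_idx} {axis}")
            except DCDError as exc:
                raise DCDError(f"truncated frame {frame_idx}: {exc}") from None
            vals = np.frombuffer(payload, dtype=dtype)
            if len(vals) != natoms:
                raise DCDError(
                    f"frame {frame_idx}: {axis} record has {len(vals)} values, "
                    f"expected {natoms}"
                )
            xyz.append(vals.astype(np.float64))
        frames.append(np.stack(xyz, axis=1))
        frame_idx += 1

    system.frames = list(system.frames) + frames
    return system


def write_dcd(frames: list[np.ndarray], byteorder: str = "<") -> bytes:
    """Serialize coordinate frames as DCD bytes (inverse of :func:`read_dcd`)."""
    if byteorder not in ("<", ">"):
        raise ValueError("byteorder must be '<' or '>'")
    if not frames:
        raise DCDError("cannot write a DCD with no frames")
    arrs = [np.asarray(f, dtype=np.float64) for f in frames]
    natoms = arrs[0].shape[0]
    for k, a in enumerate(arrs):
        if a.shape != (natoms, 3):
            raise DCDError(f"frame {k} has shape {a.shape}, expected ({natoms}, 3)")

    bo = byteorder

    def record(payload: bytes) -> bytes:
        marker = struct.pack(bo + "i", len(payload))
        return marker + payload + marker

    icntrl = [0] * 20
    icntrl[0] = len(arrs)  # number of frames
    header = b"CORD" + struct.pack(bo + "20i", *icntrl)
    title = struct.pack(bo + "i", 1) + b"Created by molray".ljust(80)
    out = [record(header), record(title), record(struct.pack(bo + "i", natoms))]
    dtype = np.dtype(bo + "f4")
    for a in arrs:
        for axis in range(3):
            out.append(record(a[:, axis].astype(dtype).tobytes()))
    return b"".join(out)
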