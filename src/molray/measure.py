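"""Geometric measurements: distance, angle, dihedral."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Measurement", "measure_distance", "measure_angle", "measure_dihedral"]


@dataclass(frozen=True)
class Measurement:
    kind: str  # distance | angle | dihedral
    atom_indices: tuple[int, ...]
    value: float
    label: str

    def __post_init__(self) -> None:
        expected = {"distance": 2, "angle": 3, "dihedral": 4}[self.kind]
        if len(self.atom_indices) != expected:
            raise ValueError(f"{self.kind} needs {expected} atoms")
        if not np.isfinite(self.value):
            raise ValueError("measurement value must be finite")


def measure_distance(p1, p2) -> float:
    """Euclidean distance in Angstrom."""
    return float(np.linalg.norm(np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)))


def measure_angle(p1, p2, p3) -> float:
    """Angle at vertex p2, degrees in [0, 180]."""
    v1 = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    v2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate angle: coincident points")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral between planes (p1,p2,p3) and (p2,p3,p4).

    Degrees in (-180, 180]; sign by the right-hand rule about p2 -> p3
    (cis = 0, trans = 180; mirroring the points flips the sign).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) == 0:
        raise ValueError("degenerate dihedral: middle points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise ValueError("degenerate dihedral: collinear triple")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    # map -180 to +180 so the range is (-180, 180]
    return 180.0 if ang == -180.0 else ang
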