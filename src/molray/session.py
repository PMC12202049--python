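"""Versioned JSON session files: structures, representations, camera, render
settings and measurements round-trip losslessly through disk."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .camera import Camera
from .measure import Measurement
from .render import AASettings, FogSettings, OutlineSettings, RenderSettings, SSAOSettings

logger = logging.getLogger(__name__)

__all__ = ["Session", "StructureSpec", "save_session", "load_session", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class StructureSpec:
    """One structure in the scene: a file path or a PDB accession."""

    source: str  # path or 4-char accession
    is_accession: bool = False
    representation: str = "vdw"  # vdw | sas | sticks | ballstick | cartoon | ses
    color_scheme: str = "element"  # element | chain | uniform:#RRGGBB[AA]
    selection: str = "all"


@dataclass
class Session:
    structures: list[StructureSpec] = field(default_factory=list)
    camera: Camera | None = None
    settings: RenderSettings = field(default_factory=RenderSettings)
    measurements: list[Measurement] = field(default_factory=list)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return _session_to_dict(self) == _session_to_dict(other)


def _camera_to_dict(camera: Camera | None) -> dict | None:
    if camera is None:
        return None
    return {
        "position": [float(x) for x in camera.position],
        "orientation": [float(x) for x in camera.orientation],
        "vertical_fov": camera.vertical_fov,
        "near": camera.near,
        "far": camera.far,
        "mode": camera.mode,
        "target": None if camera.target is None else [float(x) for x in camera.target],
    }


def _camera_from_dict(d: dict | None) -> Camera | None:
    if d is None:
        return None
    return Camera(
        position=np.array(d["position"]),
        orientation=np.array(d["orientation"]),
        vertical_fov=d["vertical_fov"],
        near=d["near"],
        far=d["far"],
        mode=d["mode"],
        target=None if d.get("target") is None else np.array(d["target"]),
    )


def _settings_to_dict(s: RenderSettings) -> dict:
    d = asdict(s)
    if hasattr(s.background, "pixels"):
        raise ValueError("image backgrounds cannot be stored in a session file")
    d["background"] = list(s.background)
    return d


def _settings_from_dict(d: dict) -> RenderSettings:
    return RenderSettings(
        shading=d["shading"],
        ssao=SSAOSettings(**d["ssao"]),
        fog=FogSettings(**{**d["fog"], "color": tuple(d["fog"]["color"])}),
        outline=OutlineSettings(**{**d["outline"], "color": tuple(d["outline"]["color"])}),
        aa=AASettings(**d["aa"]),
        background=tuple(d["background"]),
        light_dir=tuple(d["light_dir"]),
    )


def _session_to_dict(session: Session) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "structures": [asdict(s) for s in session.structures],
        "camera": _camera_to_dict(session.camera),
        "settings": _settings_to_dict(session.settings),
        "measurements": [
            {
                "kind": m.kind,
                "atom_indices": list(m.atom_indices),
                "value": m.value,
                "label": m.label,
            }
            for m in session.measurements
        ],
    }


_KNOWN_KEYS = {"schema", "structures", "camera", "settings", "measurements"}


def save_session(session: Session, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_session_to_dict(session), indent=2) + "\n")


def load_session(path: str | Path) -> Session:
    """Load a session; unknown schema versions error, unknown keys warn."""
    data = json.loads(Path(path).read_text())
    schema = data.get("schema")
    if schema != SCHEMA_VERSION:
        raise ValueError(f"unsupported session schema {schema!r} (expected {SCHEMA_VERSION!r})")
    for key in data:
        if key not in _KNOWN_KEYS:
            logger.warning("ignoring unknown session key %r", key)
    return Session(
        structures=[StructureSpec(**s) for s in data.get("structures", [])],
        camera=_camera_from_dict(data.get("camera")),
        settings=_settings_from_dict(data["settings"]),
        measurements=[
            Measurement(
                kind=m["kind"],
                atom_indices=tuple(m["atom_indices"]),
                value=m["value"],
                label=m["label"],
            )
            for m in data.get("measurements", [])
        ],
    )
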