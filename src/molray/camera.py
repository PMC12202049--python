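"""Perspective cameras (trackball and free-fly) and per-pixel ray generation.

Conventions: right-handed world with +y up; in the camera frame -z is
forward and +y is up; pixel (0, 0) is the top-left corner and rays pass
through pixel centers.  Depth reported by the renderer is the eye-space
Euclidean distance along the (unit) ray direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Camera",
    "camera_rays",
    "trackball_update",
    "freefly_update",
    "look_at_quaternion",
    "quat_to_matrix",
]

WORLD_UP = np.array([0.0, 1.0, 0.0])


# -- quaternion helpers (w, x, y, z) ----------------------------------------


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    half = 0.5 * angle_rad
    return np.concatenate([[math.cos(half)], math.sin(half) * axis / n])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = quat_normalize(np.asarray(q, dtype=float))
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_from_matrix(m: np.ndarray) -> np.ndarray:
    t = np.trace(m)
    if t > 0:
        s = math.sqrt(t + 1.0) * 2
        q = np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    elif m[0, 0] > m[1, 1] and m[0, 0] > m[2, 2]:
        s = math.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2]) * 2
        q = np.array(
            [(m[2, 1] - m[1, 2]) / s, 0.25 * s, (m[0, 1] + m[1, 0]) / s, (m[0, 2] + m[2, 0]) / s]
        )
    elif m[1, 1] > m[2, 2]:
        s = math.sqrt(1.0 + m[1, 1] - m[0, 0] - m[2, 2]) * 2
        q = np.array(
            [(m[0, 2] - m[2, 0]) / s, (m[0, 1] + m[1, 0]) / s, 0.25 * s, (m[1, 2] + m[2, 1]) / s]
        )
    else:
        s = math.sqrt(1.0 + m[2, 2] - m[0, 0] - m[1, 1]) * 2
        q = np.array(
            [(m[1, 0] - m[0, 1]) / s, (m[0, 2] + m[2, 0]) / s, (m[1, 2] + m[2, 1]) / s, 0.25 * s]
        )
    return quat_normalize(q)


def look_at_quaternion(eye: np.ndarray, target: np.ndarray, up: np.ndarray = WORLD_UP) -> np.ndarray:
    forward = np.asarray(target, dtype=float) - np.asarray(eye, dtype=float)
    n = np.linalg.norm(forward)
    if n == 0:
        raise ValueError("eye and target coincide")
    forward /= n
    right = np.cross(forward, up)
    if np.linalg.norm(right) < 1e-9:
        # looking along up: fall back to a stable right vector
        right = np.cross(forward, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(right) < 1e-9:
            right = np.array([1.0, 0.0, 0.0])
    right /= np.linalg.norm(right)
    true_up = np.cross(right, forward)
    # columns: camera x, y, z in world coordinates (camera z = -forward)
    m = np.stack([right, true_up, -forward], axis=1)
    return quat_from_matrix(m)


# -- camera ------------------------------------------------------------------


@dataclass(frozen=True)
class Camera:
    position: np.ndarray
    orientation: np.ndarray  # unit quaternion (w, x, y, z)
    vertical_fov: float = 45.0  # degrees
    near: float = 0.1
    far: float = 1000.0
    mode: str = "trackball"  # or "freefly"
    target: np.ndarray | None = None  # trackball focus

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        object.__setattr__(
            self, "orientation", quat_normalize(np.asarray(self.orientation, dtype=float))
        )
        if self.target is not None:
            object.__setattr__(self, "target", np.asarray(self.target, dtype=float).reshape(3))
        if not 0 < self.near < self.far:
            raise ValueError("camera requires 0 < near < far")
        if not 0 < self.vertical_fov < 180:
            raise ValueError("vertical_fov must be in (0, 180) degrees")
        if self.mode not in ("trackball", "freefly"):
            raise ValueError(f"unknown camera mode {self.mode!r}")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix mapping camera-frame vectors to world."""
        return quat_to_matrix(self.orientation)

    @property
    def forward(self) -> np.ndarray:
        return self.rotation @ np.array([0.0, 0.0, -1.0])

    @property
    def up(self) -> np.ndarray:
        return self.rotation @ np.array([0.0, 1.0, 0.0])

    @property
    def right(self) -> np.ndarray:
        return self.rotation @ np.array([1.0, 0.0, 0.0])

    @staticmethod
    def looking_at(
        position,
        target,
        vertical_fov: float = 45.0,
        mode: str = "trackball",
        near: float = 0.1,
        far: float = 1000.0,
    ) -> "Camera":
        return Camera(
            position=np.asarray(position, dtype=float),
            orientation=look_at_quaternion(np.asarray(position, dtype=float), np.asarray(target, dtype=float)),
            vertical_fov=vertical_fov,
            near=near,
            far=far,
            mode=mode,
            target=np.asarray(target, dtype=float) if mode == "trackball" else None,
        )


def camera_ray_dirs_camframe(width: int, height: int, vertical_fov: float) -> np.ndarray:
    """Unit ray directions in the camera frame, shape (height, width, 3)."""
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be >= 1")
    tan_v = math.tan(math.radians(vertical_fov) / 2.0)
    aspect = width / height
    xs = (2.0 * (np.arange(width) + 0.5) / width - 1.0) * tan_v * aspect
    ys = (1.0 - 2.0 * (np.arange(height) + 0.5) / height) * tan_v
    dirs = np.empty((height, width, 3))
    dirs[:, :, 0] = xs[None, :]
    dirs[:, :, 1] = ys[:, None]
    dirs[:, :, 2] = -1.0
    dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
    return dirs


def camera_rays(camera: Camera, width: int, height: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel world-space rays: (origins, unit directions), shape (H, W, 3)."""
    dirs_cam = camera_ray_dirs_camframe(width, height, camera.vertical_fov)
    dirs_world = dirs_cam @ camera.rotation.T
    origins = np.broadcast_to(camera.position, dirs_world.shape).copy()
    return origins, dirs_world


_PITCH_LIMIT = math.radians(89.0)


def trackball_update(camera: Camera, d_yaw: float, d_pitch: float, d_zoom: float = 0.0) -> Camera:
    """Orbit the camera about its target.

    ``d_yaw``/``d_pitch`` are radians (yaw about world up, then pitch about
    camera right, clamped to +/-89 deg elevation); the target distance is
    multiplied by ``exp(d_zoom)``.
    """
    if camera.mode != "trackball" or camera.target is None:
        raise ValueError("trackball_update requires a trackball camera with a target")
    offset = camera.position - camera.target
    dist = float(np.linalg.norm(offset))
    if dist == 0:
        raise ValueError("camera position coincides with target")
    # yaw about world up
    yaw_m = quat_to_matrix(quat_from_axis_angle(WORLD_UP, d_yaw))
    offset = yaw_m @ offset
    # pitch about camera right, elevation clamped
    horiz = np.linalg.norm(offset - (offset @ WORLD_UP) * WORLD_UP)
    elevation = math.atan2(float(offset @ WORLD_UP), float(horiz))
    new_elevation = min(max(elevation + d_pitch, -_PITCH_LIMIT), _PITCH_LIMIT)
    applied_pitch = new_elevation - elevation
    right = np.cross(WORLD_UP, offset)
    if np.linalg.norm(right) > 1e-12:
        pitch_m = quat_to_matrix(quat_from_axis_angle(right, -applied_pitch))
        offset = pitch_m @ offset
    offset *= math.exp(d_zoom)
    position = camera.target + offset
    return replace(
        camera,
        position=position,
        orientation=look_at_quaternion(position, camera.target),
    )


def freefly_update(
    camera: Camera,
    move: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
    d_yaw: float = 0.0,
    d_pitch: float = 0.0,
) -> Camera:
    """First-person update: rotate (yaw about world up, pitch about camera
    right), then translate by ``move`` = (right, up, forward) in the rotated
    camera basis."""
    if camera.mode != "freefly":
        raise ValueError("freefly_update requires a freefly camera")
    q = camera.orientation
    q = quat_multiply(quat_from_axis_angle(WORLD_UP, d_yaw), q)
    right_world = quat_to_matrix(q) @ np.array([1.0, 0.0, 0.0])
    q = quat_multiply(quat_from_axis_angle(right_world, d_pitch), q)
    q = quat_normalize(q)
    rot = quat_to_matrix(q)
    mx, my, mz = np.asarray(move, dtype=float)
    delta = rot @ np.array([mx, my, -mz])
    return replace(camera, position=camera.position + delta, orientation=q)
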