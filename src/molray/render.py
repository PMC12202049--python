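"""Deterministic CPU deferred renderer.

Per-pixel rays are intersected analytically with the scene's implicit
primitives (spheres, open cylinders) and BVH-indexed meshes, filling a
G-buffer of eye-space depth, view-space normal, albedo and object id.
Screen-space post-processes (shading, SSAO, fog, outline, supersampling
anti-aliasing, background compositing) then operate on the buffers only, so
each stage can be disabled to reproduce the previous stage bit-exactly.

Sphere/cylinder intersection is vectorized over pixels; union-group spheres
(solvent-accessible surfaces) use iterative re-entry so only the boundary of
the sphere union is ever shaded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .camera import Camera, camera_ray_dirs_camframe
from .intersect import MeshBVH
from .io.image import Image
from .reps import Scene

__all__ = [
    "GBuffer",
    "RenderSettings",
    "SSAOSettings",
    "FogSettings",
    "OutlineSettings",
    "AASettings",
    "render_gbuffer",
    "shade_deferred",
    "ssao",
    "apply_fog",
    "detect_outline",
    "antialias_supersample",
    "composite_background",
    "render_snapshot",
    "MAX_WIDTH",
    "MAX_HEIGHT",
]

MAX_WIDTH = 7680
MAX_HEIGHT = 4320

MISS_ID = -1
_T_EPS = 1e-6
_CHUNK = 262144  # pixels per ray-cast chunk (bounds temporary memory)


# ---------------------------------------------------------------------------
# settings


@dataclass(frozen=True)
class SSAOSettings:
    enabled: bool = False
    n_samples: int = 32
    radius: float = 1.5  # Angstrom
    seed: int = 0
    bias: float = 0.025


@dataclass(frozen=True)
class FogSettings:
    enabled: bool = False
    near: float = 10.0
    far: float = 50.0
    color: tuple[int, int, int] = (180, 190, 200)
    density: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("fog density must be in [0, 1]")


@dataclass(frozen=True)
class OutlineSettings:
    enabled: bool = False
    threshold: float = 0.1
    color: tuple[int, int, int] = (0, 0, 0)
    thickness: int = 1


@dataclass(frozen=True)
class AASettings:
    enabled: bool = False
    factor: int = 2


@dataclass(frozen=True)
class RenderSettings:
    shading: str = "matte"  # flat | matte | glossy | toon
    ssao: SSAOSettings = field(default_factory=SSAOSettings)
    fog: FogSettings = field(default_factory=FogSettings)
    outline: OutlineSettings = field(default_factory=OutlineSettings)
    aa: AASettings = field(default_factory=AASettings)
    background: tuple[int, int, int, int] | Image = (0, 0, 0, 0)
    light_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)  # view space, headlight

    def __post_init__(self) -> None:
        if self.shading not in ("flat", "matte", "glossy", "toon"):
            raise ValueError(f"unknown shading mode {self.shading!r}")


# ---------------------------------------------------------------------------
# G-buffer


@dataclass
class GBuffer:
    """Per-pixel geometry attributes.

    depth: eye-space Euclidean distance (+inf for miss); normal: view-space
    unit vector (zeros for miss); albedo: RGBA uint8 ((0,0,0,0) for miss);
    object_id: primitive index, or a mesh id offset, -1 for miss.
    """

    depth: np.ndarray  # (H, W) float64
    normal: np.ndarray  # (H, W, 3) float32, view space
    albedo: np.ndarray  # (H, W, 4) uint8
    object_id: np.ndarray  # (H, W) int32
    vertical_fov: float = 45.0  # needed to reconstruct view-space positions

    @property
    def height(self) -> int:
        return self.depth.shape[0]

    @property
    def width(self) -> int:
        return self.depth.shape[1]

    @property
    def hit_mask(self) -> np.ndarray:
        return np.isfinite(self.depth)


class _SceneIndex:
    """Flat numpy views of the scene's primitives plus mesh BVHs."""

    def __init__(self, scene: Scene):
        sp = scene.spheres
        self.s_center = np.array([s.center for s in sp]).reshape(-1, 3)
        self.s_radius = np.array([s.radius for s in sp], dtype=float)
        self.s_color = np.array([s.color for s in sp], dtype=np.uint8).reshape(-1, 4)
        self.s_group = np.array([s.union_group for s in sp], dtype=int)
        cy = scene.cylinders
        self.c_a = np.array([c.end_a for c in cy]).reshape(-1, 3)
        self.c_b = np.array([c.end_b for c in cy]).reshape(-1, 3)
        self.c_radius = np.array([c.radius for c in cy], dtype=float)
        self.c_color_a = np.array([c.color_a for c in cy], dtype=np.uint8).reshape(-1, 4)
        self.c_color_b = np.array([c.color_b for c in cy], dtype=np.uint8).reshape(-1, 4)
        self.meshes = [m for m in scene.meshes if m.n_triangles]
        self.bvhs = [MeshBVH(m) for m in self.meshes]
        self.n_spheres = len(sp)
        self.n_cylinders = len(cy)


def _cast_plain_spheres(idx, origin, dirs, t_best, obj_id, normal, albedo, sphere_ids):
    for k in sphere_ids:
        c = idx.s_center[k]
        r = idx.s_radius[k]
        oc = origin - c
        b = dirs @ oc
        disc = b * b - (oc @ oc - r * r)
        ok = disc >= 0
        if not ok.any():
            continue
        s = np.sqrt(np.where(ok, disc, 0.0))
        t = np.where(-b - s > _T_EPS, -b - s, -b + s)
        ok &= t > _T_EPS
        ok &= t < t_best
        if not ok.any():
            continue
        hit = origin + t[ok, None] * dirs[ok]
        t_best[ok] = t[ok]
        obj_id[ok] = k
        normal[ok] = (hit - c) / r
        albedo[ok] = idx.s_color[k]


def _cast_union_spheres(idx, origin, dirs, t_best, obj_id, normal, albedo, group_ids):
    """Iterative union traversal: candidate hits strictly inside another
    sphere of the group are rejected and the ray re-enters from that point."""
    centers = idx.s_center[group_ids]
    radii = idx.s_radius[group_ids]
    n_ray = len(dirs)
    t_start = np.zeros(n_ray)
    active = np.ones(n_ray, dtype=bool)
    for _ in range(4 * len(group_ids) + 8):
        if not active.any():
            break
        a_idx = np.nonzero(active)[0]
        d = dirs[a_idx]
        best_t = np.full(len(a_idx), np.inf)
        best_k = np.full(len(a_idx), -1, dtype=int)
        for g, (c, r) in enumerate(zip(centers, radii)):
            oc = origin - c
            b = d @ oc
            disc = b * b - (oc @ oc - r * r)
            ok = disc >= 0
            if not ok.any():
                continue
            s = np.sqrt(np.where(ok, disc, 0.0))
            lo = t_start[a_idx] + _T_EPS
            t1 = -b - s
            t2 = -b + s
            t = np.where(t1 > lo, t1, t2)
            ok &= t > lo
            better = ok & (t < best_t)
            best_t[better] = t[better]
            best_k[better] = g
        found = best_k >= 0
        if not found.any():
            active[a_idx] = False
            break
        f_idx = a_idx[found]
        tf = best_t[found]
        kf = best_k[found]
        hits = origin + tf[:, None] * dirs[f_idx]
        # strictly inside any *other* sphere of the group?
        inside = np.zeros(len(f_idx), dtype=bool)
        for g, (c, r) in enumerate(zip(centers, radii)):
            not_self = kf != g
            dist = np.linalg.norm(hits - c, axis=1)
            inside |= not_self & (dist < r - 1e-9)
        # boundary hits: commit if nearer than current best
        commit = ~inside & (tf < t_best[f_idx])
        ci = f_idx[commit]
        t_best[ci] = tf[commit]
        gk = np.asarray(group_ids)[kf[commit]]
        obj_id[ci] = gk
        normal[ci] = (hits[commit] - centers[kf[commit]]) / radii[kf[commit], None]
        albedo[ci] = idx.s_color[gk]
        # finished rays: boundary found (or nothing): deactivate
        active[a_idx] = False
        active[f_idx[inside]] = True
        t_start[f_idx[inside]] = tf[inside]
    return


def _cast_cylinders(idx, origin, dirs, t_best, obj_id, normal, albedo):
    for k in range(idx.n_cylinders):
        a = idx.c_a[k]
        b = idx.c_b[k]
        axis = b - a
        length = float(np.linalg.norm(axis))
        u = axis / length
        r = idx.c_radius[k]
        o = origin - a
        du = dirs @ u
        dp = dirs - du[:, None] * u
        op = o - (o @ u) * u
        A = np.einsum("ij,ij->i", dp, dp)
        B = 2.0 * (dp @ op)
        C = float(op @ op) - r * r
        ok = A > 1e-14
        disc = B * B - 4 * A * C
        ok &= disc >= 0
        if not ok.any():
            continue
        sq = np.sqrt(np.where(ok, disc, 0.0))
        A_safe = np.where(ok, A, 1.0)
        t1 = (-B - sq) / (2 * A_safe)
        t2 = (-B + sq) / (2 * A_safe)
        proj1 = (o @ u) + t1 * du
        ok1 = ok & (t1 > _T_EPS) & (proj1 > 0) & (proj1 < length)
        proj2 = (o @ u) + t2 * du
        ok2 = ok & (t2 > _T_EPS) & (proj2 > 0) & (proj2 < length)
        t = np.where(ok1, t1, np.where(ok2, t2, np.inf))
        hit_ok = np.isfinite(t) & (t < t_best)
        if not hit_ok.any():
            continue
        th = t[hit_ok]
        proj = (o @ u) + th * du[hit_ok]
        hitp = o + th[:, None] * dirs[hit_ok]
        rad = hitp - proj[:, None] * u
        t_best[hit_ok] = th
        obj_id[hit_ok] = idx.n_spheres + k
        normal[hit_ok] = rad / r
        col = np.where(
            (proj < length / 2)[:, None], idx.c_color_a[k][None, :], idx.c_color_b[k][None, :]
        )
        albedo[hit_ok] = col
    return


def render_gbuffer(scene: Scene, camera: Camera, width: int, height: int) -> GBuffer:
    """Ray-cast the scene into a fresh G-buffer."""
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be >= 1")
    idx = _SceneIndex(scene)
    dirs_cam = camera_ray_dirs_camframe(width, height, camera.vertical_fov)
    rot = camera.rotation
    dirs_world_full = (dirs_cam @ rot.T).reshape(-1, 3)
    del dirs_cam
    origin = camera.position

    n_pix = width * height
    depth = np.full(n_pix, np.inf)
    normal_world = np.zeros((n_pix, 3), dtype=np.float32)
    albedo = np.zeros((n_pix, 4), dtype=np.uint8)
    obj_id = np.full(n_pix, MISS_ID, dtype=np.int32)

    plain = [k for k in range(idx.n_spheres) if idx.s_group[k] < 0]
    groups: dict[int, list[int]] = {}
    for k in range(idx.n_spheres):
        g = idx.s_group[k]
        if g >= 0:
            groups.setdefault(int(g), []).append(k)

    for start in range(0, n_pix, _CHUNK):
        sl = slice(start, min(start + _CHUNK, n_pix))
        dirs = dirs_world_full[sl]
        t_best = depth[sl]
        _cast_plain_spheres(idx, origin, dirs, t_best, obj_id[sl], normal_world[sl], albedo[sl], plain)
        for members in groups.values():
            _cast_union_spheres(
                idx, origin, dirs, t_best, obj_id[sl], normal_world[sl], albedo[sl], members
            )
        if idx.n_cylinders:
            _cast_cylinders(idx, origin, dirs, t_best, obj_id[sl], normal_world[sl], albedo[sl])
        depth[sl] = t_best

    # meshes: per-ray BVH traversal
    for m_i, bvh in enumerate(idx.bvhs):
        mesh = idx.meshes[m_i]
        mesh_id = idx.n_spheres + idx.n_cylinders + m_i
        lo = mesh.vertices.min(axis=0)
        hi = mesh.vertices.max(axis=0)
        for p in range(n_pix):
            d = dirs_world_full[p]
            with np.errstate(divide="ignore", invalid="ignore"):
                inv = 1.0 / d
                t0 = (lo - origin) * inv
                t1 = (hi - origin) * inv
            if min(np.maximum(t0, t1).min(), depth[p]) < max(np.minimum(t0, t1).max(), 0.0):
                continue
            hit = bvh.intersect(origin, d)
            if hit is not None and hit[0] < depth[p]:
                t, n, tri = hit
                depth[p] = t
                normal_world[p] = n
                obj_id[p] = mesh_id
                if mesh.vertex_colors is not None:
                    tri_idx = mesh.triangles[tri]
                    albedo[p] = mesh.vertex_colors[tri_idx[0]]
                else:
                    albedo[p] = (200, 200, 200, 255)

    # world -> view-space normals
    normal_view = (normal_world @ rot).astype(np.float32)
    miss = ~np.isfinite(depth)
    normal_view[miss] = 0.0
    albedo[miss] = 0
    return GBuffer(
        depth=depth.reshape(height, width),
        normal=normal_view.reshape(height, width, 3),
        albedo=albedo.reshape(height, width, 4),
        object_id=obj_id.reshape(height, width),
        vertical_fov=camera.vertical_fov,
    )


# ---------------------------------------------------------------------------
# deferred shading and post-processes


def shade_deferred(
    gbuffer: GBuffer,
    settings: RenderSettings,
    light_dir: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Shaded RGB buffer in [0, 1] floats (miss pixels stay 0)."""
    L = np.asarray(light_dir if light_dir is not None else settings.light_dir, dtype=float)
    L = L / np.linalg.norm(L)
    albedo = gbuffer.albedo[:, :, :3].astype(np.float64) / 255.0
    if settings.shading == "flat":
        return albedo
    n = gbuffer.normal.astype(np.float64)
    ndotl = np.clip(n @ L, 0.0, None)
    if settings.shading == "matte":
        out = albedo * (0.15 + 0.85 * ndotl)[:, :, None]
    elif settings.shading == "glossy":
        V = np.array([0.0, 0.0, 1.0])
        H = L + V
        H = H / np.linalg.norm(H)
        ndoth = np.clip(n @ H, 0.0, None)
        out = albedo * (0.15 + 0.85 * ndotl)[:, :, None] + 0.4 * (ndoth**32)[:, :, None]
    elif settings.shading == "toon":
        band = np.minimum(np.floor(ndotl * 4.0), 3.0)  # 4 equal bands
        out = albedo * ((band + 1.0) * 0.25)[:, :, None]
    else:  # pragma: no cover
        raise ValueError(settings.shading)
    out[~gbuffer.hit_mask] = 0.0
    return np.clip(out, 0.0, 1.0)


def _cosine_hemisphere_kernel(n_samples: int, seed: int) -> np.ndarray:
    """Deterministic cosine-weighted hemisphere kernel (+z oriented), with
    volume-distributed lengths in (0, 1]."""
    rng = np.random.default_rng(seed)
    u1 = rng.random(n_samples)
    u2 = rng.random(n_samples)
    u3 = rng.random(n_samples)
    r = np.sqrt(u1)
    theta = 2 * np.pi * u2
    dirs = np.stack([r * np.cos(theta), r * np.sin(theta), np.sqrt(1.0 - u1)], axis=1)
    return dirs * np.cbrt(u3)[:, None]


def ssao(gbuffer: GBuffer, params: SSAOSettings) -> np.ndarray:
    """Per-pixel openness in [0, 1] (1 = fully open); miss pixels are 1.

    A sample counts occluded when the depth stored at its projected pixel is
    closer than the sample's own eye distance minus the bias, within the
    radius range check.
    """
    h, w = gbuffer.depth.shape
    if not params.enabled:
        return np.ones((h, w))
    kernel = _cosine_hemisphere_kernel(params.n_samples, params.seed) * params.radius

    dirs_cam = camera_ray_dirs_camframe(w, h, gbuffer.vertical_fov)
    hit = gbuffer.hit_mask
    depth = gbuffer.depth
    pos = dirs_cam * depth[:, :, None]  # view-space position of each hit
    pos = pos[hit]
    n = gbuffer.normal[hit].astype(np.float64)
    n_hit = len(pos)
    if n_hit == 0:
        return np.ones((h, w))

    # per-pixel tangent basis around the view-space normal
    helper = np.where(np.abs(n[:, 0:1]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    t = np.cross(helper, n)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    b = np.cross(n, t)

    tan_v = math.tan(math.radians(gbuffer.vertical_fov) / 2.0)
    aspect = w / h
    occluded = np.zeros(n_hit, dtype=np.int64)
    for k in range(params.n_samples):
        off = kernel[k]
        q = pos + off[0] * t + off[1] * b + off[2] * n
        qz = q[:, 2]
        in_front = qz < -1e-9
        px = np.full(n_hit, -1, dtype=np.int64)
        py = np.full(n_hit, -1, dtype=np.int64)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_ndc = np.where(in_front, q[:, 0] / -qz / (tan_v * aspect), 0.0)
            y_ndc = np.where(in_front, q[:, 1] / -qz / tan_v, 0.0)
        px = np.floor((x_ndc + 1.0) / 2.0 * w).astype(np.int64)
        py = np.floor((1.0 - y_ndc) / 2.0 * h).astype(np.int64)
        valid = in_front & (px >= 0) & (px < w) & (py >= 0) & (py < h)
        sample_dist = np.linalg.norm(q, axis=1)
        stored = np.full(n_hit, np.inf)
        stored[valid] = depth[py[valid], px[valid]]
        occ = (stored < sample_dist - params.bias) & (
            np.abs(stored - sample_dist) <= params.radius
        )
        occluded += occ
    openness = 1.0 - occluded / params.n_samples
    out = np.ones((h, w))
    out[hit] = openness
    return out


def apply_fog(color: np.ndarray, depth: np.ndarray, fog: FogSettings) -> np.ndarray:
    """Linear fog: out = (1 - w) color + w fog_color, w = density * clamp((d - near)/(far - near))."""
    if not fog.enabled:
        return color
    if fog.far <= fog.near:
        raise ValueError("fog requires far > near")
    w = fog.density * np.clip((depth - fog.near) / (fog.far - fog.near), 0.0, 1.0)
    w = np.where(np.isfinite(depth), w, 0.0)  # miss pixels untouched
    fog_rgb = np.asarray(fog.color, dtype=np.float64) / 255.0
    return (1.0 - w)[:, :, None] * color + w[:, :, None] * fog_rgb


def detect_outline(gbuffer: GBuffer, params: OutlineSettings) -> np.ndarray:
    """Boolean outline mask from inverse-depth gradients and normal breaks."""
    depth = gbuffer.depth
    inv = np.where(np.isfinite(depth), 1.0 / np.maximum(depth, 1e-12), 0.0)
    peak = inv.max()
    if peak > 0:
        inv = inv / peak
    gx = ndimage.sobel(inv, axis=0, mode="nearest") / 4.0
    gy = ndimage.sobel(inv, axis=1, mode="nearest") / 4.0
    grad = np.hypot(gx, gy)
    mask = grad > params.threshold

    # normal discontinuity between neighbouring *hit* pixels
    n = gbuffer.normal.astype(np.float64)
    hit = gbuffer.hit_mask
    disc = np.zeros_like(inv)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        n_sh = np.roll(n, shift, axis=axis)
        hit_sh = np.roll(hit, shift, axis=axis)
        dot = np.einsum("ijk,ijk->ij", n, n_sh)
        term = np.where(hit & hit_sh, 1.0 - dot, 0.0)
        disc = np.maximum(disc, term)
    mask |= disc > params.threshold
    if params.thickness > 1:
        mask = ndimage.binary_dilation(mask, iterations=params.thickness - 1)
    return mask


def apply_outline(color: np.ndarray, mask: np.ndarray, params: OutlineSettings) -> np.ndarray:
    out = color.copy()
    out[mask] = np.asarray(params.color, dtype=np.float64) / 255.0
    return out


def _box_downsample(buf: np.ndarray, factor: int) -> np.ndarray:
    h, w = buf.shape[:2]
    hh, ww = h // factor, w // factor
    shaped = buf[: hh * factor, : ww * factor].reshape(
        hh, factor, ww, factor, *buf.shape[2:]
    )
    return shaped.mean(axis=(1, 3))


def composite_background(
    color: np.ndarray,
    alpha: np.ndarray,
    background: tuple[int, int, int, int] | Image,
) -> Image:
    """Source-over compositing of shaded geometry onto the background.

    ``color`` is float RGB in [0, 1]; ``alpha`` is float coverage in [0, 1]
    (1 on geometry, 0 on miss pixels, fractional after anti-aliasing).
    """
    h, w = alpha.shape
    if isinstance(background, Image):
        if background.height != h or background.width != w:
            raise ValueError(
                f"background is {background.width}x{background.height}, "
                f"render is {w}x{h}"
            )
        bg = background.pixels.astype(np.float64) / 255.0
    else:
        bg = np.empty((h, w, 4))
        bg[:] = np.asarray(background, dtype=np.float64) / 255.0
    src_a = alpha[:, :, None]
    out_a = src_a + bg[:, :, 3:4] * (1.0 - src_a)
    out_rgb = color * src_a + bg[:, :, :3] * bg[:, :, 3:4] * (1.0 - src_a)
    # un-premultiply where alpha > 0
    safe_a = np.where(out_a > 0, out_a, 1.0)
    out_rgb = out_rgb / safe_a
    px = np.empty((h, w, 4), dtype=np.uint8)
    px[:, :, :3] = np.clip(np.round(out_rgb * 255.0), 0, 255).astype(np.uint8)
    px[:, :, 3] = np.clip(np.round(out_a[:, :, 0] * 255.0), 0, 255).astype(np.uint8)
    return Image(px)


def antialias_supersample(render_fn, width: int, height: int, factor: int = 2):
    """Render at ``factor`` x resolution via ``render_fn(w, h)`` and box-filter
    down to the requested size; returns (color, alpha) float buffers."""
    if factor < 1:
        raise ValueError("supersample factor must be >= 1")
    color, alpha = render_fn(width * factor, height * factor)
    if factor == 1:
        return color, alpha
    return _box_downsample(color, factor), _box_downsample(alpha, factor)


def render_snapshot(
    scene: Scene,
    camera: Camera,
    settings: RenderSettings,
    width: int,
    height: int,
) -> Image:
    """Full deterministic pipeline: gbuffer -> shade -> ssao -> fog ->
    outline -> anti-alias -> background compositing."""
    if not 1 <= width <= MAX_WIDTH or not 1 <= height <= MAX_HEIGHT:
        raise ValueError(
            f"snapshot dimensions {width}x{height} outside the supported "
            f"range (max {MAX_WIDTH}x{MAX_HEIGHT})"
        )

    def stage(w: int, h: int) -> tuple[np.ndarray, np.ndarray]:
        gbuf = render_gbuffer(scene, camera, w, h)
        color = shade_deferred(gbuf, settings)
        if settings.ssao.enabled:
            color = color * ssao(gbuf, settings.ssao)[:, :, None]
        if settings.fog.enabled:
            color = apply_fog(color, gbuf.depth, settings.fog)
        if settings.outline.enabled:
            color = apply_outline(color, detect_outline(gbuf, settings.outline), settings.outline)
        alpha = gbuf.hit_mask.astype(np.float64)
        return color, alpha

    factor = settings.aa.factor if settings.aa.enabled else 1
    color, alpha = antialias_supersample(stage, width, height, factor)
    bg = settings.background
    return composite_background(color, alpha, bg)


def frame_scene(scene: Scene, vertical_fov: float = 45.0, mode: str = "trackball") -> Camera:
    """Convenience camera framing the whole scene along -z."""
    lo, hi = scene.bounds()
    center = (lo + hi) / 2
    radius = float(np.linalg.norm(hi - lo)) / 2 + 1e-6
    dist = radius / math.tan(math.radians(vertical_fov) / 2) + radius
    position = center + np.array([0.0, 0.0, dist])
    far = dist + radius * 2 + 10.0
    return Camera.looking_at(
        position, center, vertical_fov=vertical_fov, mode=mode, far=max(far, 1000.0)
    )
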