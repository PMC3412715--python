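"""Sectioning-plane geometry: the viewing transform and viewing modes.

A virtual section through a volume is the plane perpendicular to the
line of sight, which is set by two angles (*pitch*, *yaw*); a third
angle (*roll*) spins the section image in its own plane.  The rotation
centre is the *fixed point* **f** and the plane sits at signed distance
*d* along the view direction.  The whole thing is one affine map

    v' = s · Rz(roll) · Ry(pitch) · Rz(yaw) · (v − f)

with the section plane the locus z' = d.  Angles are decimal degrees,
axes right-handed with x = column (k), y = line (l, grows down-screen)
and z = plane (p); screen-up is therefore −y.  The elementary rotations
are fixed as

    Rz(t) = [[ c,  s, 0], [−s, c, 0], [0, 0, 1]]
    Ry(t) = [[ c, 0, −s], [0, 1,  0], [s, 0, c]]

so with pitch = yaw = 0 the section plane is the ordinary z-plane and
the view direction in object space is (sin p·cos y, sin p·sin y, cos p).

Four *viewing modes* reduce the free parameters for navigation:

``absolute``   all three angles given explicitly.
``statue``     roll pinned to 0; with non-zero pitch, changing yaw makes
               the section appear to rotate on screen.
``up_is_up``   roll chosen so a reference up vector projects onto the
               vertical screen axis (pointing up, i.e. −y).
``fixed_line`` the line through two fixed points stays in the section
               plane; one rotational degree of freedom (``line_angle``)
               remains, spinning the plane about that line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import DegenerateLineError, DegenerateUpError, GeometryError

__all__ = [
    "ViewSpec",
    "ViewTransform",
    "SectionFrame",
    "resolve_mode",
    "build_transform",
    "section_frame",
    "project_point",
    "unproject_point",
]

MODES = ("absolute", "statue", "up_is_up", "fixed_line")

_PARALLEL_TOL = 1e-9


def normalize_angle(deg: float) -> float:
    """Map an angle in degrees to the canonical range (−180, 180]."""
    a = math.fmod(deg, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class ViewSpec:
    """Complete parametrization of one section view.

    ``fixed`` is the rotation centre **f** in voxel coordinates; ``dist``
    is the signed plane distance d; ``scale`` the isotropic in-plane
    magnification; ``up`` the reference up vector for up-is-up mode
    (default (0, 0, −1), i.e. decreasing plane number is "up");
    ``fixed2``/``line_angle`` parametrize fixed-line mode.
    """

    fixed: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pitch: float = 0.0
    yaw: float = 0.0
    roll: float = 0.0
    dist: float = 0.0
    scale: float = 1.0
    mode: str = "absolute"
    up: tuple[float, float, float] = (0.0, 0.0, -1.0)
    fixed2: tuple[float, float, float] | None = None
    line_angle: float = 0.0

    def __post_init__(self):
        if self.scale <= 0:
            raise GeometryError(f"scale must be positive, got {self.scale}")
        if self.mode not in MODES:
            raise GeometryError(f"unknown viewing mode {self.mode!r}")


def _rz(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def view_direction(pitch: float, yaw: float) -> np.ndarray:
    """Unit line-of-sight in object space (the section-plane normal)."""
    p, y = math.radians(pitch), math.radians(yaw)
    return np.array([math.sin(p) * math.cos(y), math.sin(p) * math.sin(y), math.cos(p)])


def resolve_mode(view: ViewSpec) -> ViewSpec:
    """Return an equivalent view with ``mode='absolute'`` and concrete angles.

    statue pins roll to 0.  up_is_up solves for the unique roll in
    (−180°, 180°] that sends the in-plane projection of ``up`` to the
    screen-up direction (−y).  fixed_line derives pitch/yaw from the
    plane normal perpendicular to the line through ``fixed`` and
    ``fixed2`` (selected by ``line_angle``), chooses roll so the line's
    on-screen image is independent of ``line_angle``, and pins ``dist``
    to 0 so both points lie on the section plane.
    """
    mode = view.mode
    if mode == "absolute":
        return replace(
            view,
            pitch=normalize_angle(view.pitch),
            yaw=normalize_angle(view.yaw),
            roll=normalize_angle(view.roll),
        )
    if mode == "statue":
        return replace(view, mode="absolute", roll=0.0,
                       pitch=normalize_angle(view.pitch), yaw=normalize_angle(view.yaw))
    if mode == "up_is_up":
        pitch = normalize_angle(view.pitch)
        yaw = normalize_angle(view.yaw)
        r0 = _ry(pitch) @ _rz(yaw)
        up = np.asarray(view.up, dtype=float)
        if np.linalg.norm(up) == 0:
            raise DegenerateUpError("up vector must be non-zero")
        ux, uy, _ = r0 @ up
        if math.hypot(ux, uy) < _PARALLEL_TOL * np.linalg.norm(up):
            raise DegenerateUpError("up vector is parallel to the viewing direction")
        # Rz(roll) turns in-plane vectors by −roll; send up to angle −90°.
        roll = normalize_angle(math.degrees(math.atan2(uy, ux)) + 90.0)
        return replace(view, mode="absolute", pitch=pitch, yaw=yaw, roll=roll)
    if mode == "fixed_line":
        if view.fixed2 is None:
            raise DegenerateLineError("fixed_line mode requires a second fixed point")
        f1 = np.asarray(view.fixed, dtype=float)
        f2 = np.asarray(view.fixed2, dtype=float)
        w = f2 - f1
        wn = np.linalg.norm(w)
        if wn < _PARALLEL_TOL:
            raise DegenerateLineError("the two fixed points coincide")
        w = w / wn
        # deterministic orthonormal basis of the plane perpendicular to w
        helper = np.array([0.0, 0.0, 1.0])
        if abs(w @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n1 = np.cross(helper, w)
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(w, n1)
        a = math.radians(view.line_angle)
        normal = math.cos(a) * n1 + math.sin(a) * n2
        pitch = math.degrees(math.acos(np.clip(normal[2], -1.0, 1.0)))
        sp = math.sin(math.radians(pitch))
        yaw = math.degrees(math.atan2(normal[1], normal[0])) if abs(sp) > _PARALLEL_TOL else 0.0
        # roll aligns the line image with +x so it is invariant in line_angle
        wx, wy, _ = _ry(pitch) @ _rz(yaw) @ w
        roll = normalize_angle(math.degrees(math.atan2(wy, wx)))
        return replace(
            view, mode="absolute",
            pitch=normalize_angle(pitch), yaw=normalize_angle(yaw), roll=roll, dist=0.0,
        )
    raise GeometryError(f"unknown viewing mode {mode!r}")


@dataclass(frozen=True)
class ViewTransform:
    """The affine sectioning map ``v' = scale · R · (v − fixed)``."""

    rotation: np.ndarray
    fixed: tuple[float, float, float]
    scale: float
    dist: float

    def to_view(self, v: Sequence[float] | np.ndarray) -> np.ndarray:
        """Object coordinates → view coordinates; accepts (..., 3) arrays."""
        v = np.asarray(v, dtype=float)
        return self.scale * ((v - np.asarray(self.fixed)) @ self.rotation.T)

    def from_view(self, vp: Sequence[float] | np.ndarray) -> np.ndarray:
        """View coordinates → object coordinates; accepts (..., 3) arrays."""
        vp = np.asarray(vp, dtype=float)
        return (vp / self.scale) @ self.rotation + np.asarray(self.fixed)

    @property
    def view_axis(self) -> np.ndarray:
        """Unit view direction in object space, Rᵀ·(0,0,1)."""
        return self.rotation.T @ np.array([0.0, 0.0, 1.0])


def build_transform(view: ViewSpec) -> ViewTransform:
    """Assemble the affine transform of a resolved (absolute-mode) view."""
    view = resolve_mode(view)
    rot = _rz(view.roll) @ _ry(view.pitch) @ _rz(view.yaw)
    return ViewTransform(rotation=rot, fixed=tuple(float(c) for c in view.fixed),
                         scale=float(view.scale), dist=float(view.dist))


def to_view(t: ViewTransform, v) -> np.ndarray:
    return t.to_view(v)


def from_view(t: ViewTransform, vp) -> np.ndarray:
    return t.from_view(vp)


@dataclass(frozen=True)
class SectionFrame:
    """Raster frame of a section: size in pixels plus view-frame offsets.

    Computed from the *full 3D bounding box*, not the current plane's
    intersection polygon, so the frame — and therefore tile indices —
    stay put while the user scrolls the plane distance.
    ``dist_min``/``dist_max`` bound the useful distance range.
    """

    width: int
    height: int
    x_off: int
    y_off: int
    dist_min: float
    dist_max: float


def section_frame(bbox: tuple[int, int, int, int, int, int], t: ViewTransform) -> SectionFrame:
    """Frame of the section raster for a volume bounding box under *t*.

    All eight corners of the (inclusive) box are pushed through the
    transform; offsets are the floor of the minimum x'/y', the size
    spans to the ceiling of the maximum.
    """
    k1, l1, p1, k2, l2, p2 = bbox
    corners = np.array([[k, l, p] for k in (k1, k2) for l in (l1, l2) for p in (p1, p2)], dtype=float)
    vc = t.to_view(corners)
    x_off = math.floor(vc[:, 0].min())
    y_off = math.floor(vc[:, 1].min())
    width = math.ceil(vc[:, 0].max()) - x_off + 1
    height = math.ceil(vc[:, 1].max()) - y_off + 1
    return SectionFrame(width=width, height=height, x_off=x_off, y_off=y_off,
                        dist_min=float(vc[:, 2].min()), dist_max=float(vc[:, 2].max()))


def project_point(t: ViewTransform, frame: SectionFrame, p) -> tuple[float, float, float]:
    """Section-frame (x, y) of a 3D point and its distance from the plane."""
    x, y, z = t.to_view(np.asarray(p, dtype=float))
    return (float(x) - frame.x_off, float(y) - frame.y_off, float(z) - t.dist)


def unproject_point(t: ViewTransform, frame: SectionFrame, xy) -> np.ndarray:
    """The unique 3D point on the section plane imaging to section (x, y).

    The inverse of :func:`project_point` for points at distance 0; this
    backs the on-screen measurement tool (two clicked pixels map to two
    3D points whose physical separation can then be computed).
    """
    x, y = xy
    return t.from_view(np.array([x + frame.x_off, y + frame.y_off, t.dist]))
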