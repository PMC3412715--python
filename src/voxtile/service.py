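"""Tile-protocol service: request parsing, tile delivery, object queries.

The wire format is an HTTP GET query string of ``CMD=value`` pairs
joined by ``&``.  A request names a resource (``WLZ``), sets the view
(``PIT``/``YAW``/``ROL``/``DST``/``FXP``/``SCL``/``MOD``/``UPV`` plus
any number of ``SEL`` overlay selections) and asks for exactly one
thing: a compressed or raw tile (``JTL``/``PTL``/``TIL``), a full
section (``CVT``), or an object query (``OBJ``, optionally anchored by
a 2D tile point ``PRT`` or a 3D point ``PAB``).

Responses are a pure function of (resource bytes, query string,
configuration): encoder settings are pinned in the configuration so
repeated identical requests are byte-identical, which also lets three
LRU caches — encoded tiles, opened objects, resolved view transforms —
serve hits without any observable difference from recomputation.

A substring routing table supports the proxy deployment pattern: the
first rule whose match string occurs anywhere in the query wins,
otherwise the default backend takes the request.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import math
import threading
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import EmptyObjectError, NoValuesError, ProtocolError, VoxtileError
from .geometry import (SectionFrame, ViewSpec, ViewTransform, build_transform,
                       resolve_mode, section_frame)
from .io import read_compound_manifest, read_nifti, read_tiff_stack
from .overlay import SelEntry, colour_domain_layer, composite, filter_value_layer, parse_sel
from .section import SectionImage, cut_domain_section, cut_section
from .store import open_store
from .volume import OUTSIDE, CompoundObject, VoxelVolume

__all__ = [
    "Request",
    "TileKey",
    "RoutingTable",
    "ServiceConfig",
    "TileService",
    "LRUCache",
    "parse_request",
    "tile_grid",
    "route_request",
    "serve",
]

SERVER_ID = "IIP3D/1.0 voxtile"

_MODE_TOKENS = {
    "absolute": "absolute",
    "statue": "statue",
    "up_is_up": "up_is_up",
    "upisup": "up_is_up",
    "up-is-up": "up_is_up",
    "fixed_line": "fixed_line",
    "fixedline": "fixed_line",
    "fixed-line": "fixed_line",
}

OBJ_QUERIES = (
    "IIP-server",
    "Max-size",
    "Tile-size",
    "Wlz-3d-bounding-box",
    "Wlz-coordinate-3D",
    "Wlz-distance-range",
    "Wlz-foreground-objects",
    "Wlz-grey-value",
    "Wlz-sectioning-angles",
    "Wlz-transformed-coordinate-3d",
    "Wlz-true-voxel-size",
    "Wlz-volume",
)
_OBJ_BY_LOWER = {q.lower(): q for q in OBJ_QUERIES}


# ---------------------------------------------------------------------------
# request parsing


@dataclass(frozen=True)
class Request:
    """A fully parsed protocol request."""

    resource: str | None
    view: ViewSpec
    sel: tuple[SelEntry, ...]
    action: str  # 'tile' | 'full' | 'query' | 'none'
    fmt: str | None = None  # 'jpeg' | 'png' | 'raw'
    level: int = 0
    tile_index: int | None = None
    quality: int | None = None
    obj_name: str | None = None
    prt: tuple[float, float] | None = None
    pab: tuple[float, float, float] | None = None


def _floats(cmd: str, value: str, n: int) -> tuple[float, ...]:
    parts = value.split(",")
    if len(parts) != n:
        raise ProtocolError(f"{cmd} expects {n} comma-separated numbers, got {value!r}")
    try:
        return tuple(float(p) for p in parts)
    except ValueError:
        raise ProtocolError(f"{cmd} has a malformed number in {value!r}")


def _one_float(cmd: str, value: str) -> float:
    return _floats(cmd, value, 1)[0]


def _ints(cmd: str, value: str, n: int) -> tuple[int, ...]:
    parts = value.split(",")
    if len(parts) != n:
        raise ProtocolError(f"{cmd} expects {n} comma-separated integers, got {value!r}")
    try:
        return tuple(int(p) for p in parts)
    except ValueError:
        raise ProtocolError(f"{cmd} has a malformed integer in {value!r}")


def parse_request(query: str) -> Request:
    """Parse a ``CMD=value&...`` query string into a :class:`Request`.

    Command tokens are case-insensitive; commands apply in request
    order, later non-``SEL`` repeats overriding earlier ones.  An
    action (tile, full section or object query) requires ``WLZ`` to
    have named a resource.
    """
    resource = None
    view_kw: dict = {}
    sel: list[SelEntry] = []
    action = "none"
    fmt = None
    level = 0
    tile_index = None
    quality = None
    obj_name = None
    prt = None
    pab = None

    query = query.lstrip("?")
    for part in query.split("&"):
        if not part:
            continue
        if "=" not in part:
            raise ProtocolError(f"malformed command {part!r} (expected CMD=value)")
        cmd, value = part.split("=", 1)
        cmd = cmd.strip().upper()
        if cmd == "WLZ":
            resource = value
        elif cmd == "DST":
            view_kw["dist"] = _one_float(cmd, value)
        elif cmd == "PIT":
            view_kw["pitch"] = _one_float(cmd, value)
        elif cmd == "YAW":
            view_kw["yaw"] = _one_float(cmd, value)
        elif cmd == "ROL":
            view_kw["roll"] = _one_float(cmd, value)
        elif cmd == "SCL":
            view_kw["scale"] = _one_float(cmd, value)
        elif cmd == "FXP":
            view_kw["fixed"] = _floats(cmd, value, 3)
        elif cmd == "FXT":
            view_kw["fixed2"] = _floats(cmd, value, 3)
        elif cmd == "LNA":
            view_kw["line_angle"] = _one_float(cmd, value)
        elif cmd == "UPV":
            view_kw["up"] = _floats(cmd, value, 3)
        elif cmd == "MOD":
            mode = _MODE_TOKENS.get(value.strip().lower())
            if mode is None:
                raise ProtocolError(f"unknown viewing mode {value!r}")
            view_kw["mode"] = mode
        elif cmd == "SEL":
            sel.append(parse_sel(value.split(",")))
        elif cmd in ("JTL", "PTL", "TIL"):
            level, tile_index = _ints(cmd, value, 2)
            if level < 0 or tile_index < 0:
                raise ProtocolError(f"{cmd} level and tile index must be >= 0")
            action = "tile"
            fmt = {"JTL": "jpeg", "PTL": "png", "TIL": "raw"}[cmd]
        elif cmd == "CVT":
            action = "full"
            fmt = value.strip().lower()
            if fmt not in ("jpeg", "png", "raw"):
                raise ProtocolError(f"CVT format must be jpeg, png or raw, got {value!r}")
        elif cmd == "LEV":
            level = _ints(cmd, value, 1)[0]
            if level < 0:
                raise ProtocolError("LEV must be >= 0")
        elif cmd == "QLT":
            quality = _ints(cmd, value, 1)[0]
            if not 1 <= quality <= 100:
                raise ProtocolError(f"QLT must be in 1..100, got {quality}")
        elif cmd == "OBJ":
            name = _OBJ_BY_LOWER.get(value.strip().lower())
            if name is None:
                raise ProtocolError(f"unknown object query {value!r}")
            action = "query"
            obj_name = name
        elif cmd == "PRT":
            prt = _floats(cmd, value, 2)
        elif cmd == "PAB":
            pab = _floats(cmd, value, 3)
        else:
            raise ProtocolError(f"unknown command {cmd!r}")

    if action != "none" and resource is None:
        raise ProtocolError("request has an action but no WLZ resource")
    try:
        view = ViewSpec(**view_kw)
    except VoxtileError:
        raise
    return Request(resource=resource, view=view, sel=tuple(sel), action=action,
                   fmt=fmt, level=level, tile_index=tile_index, quality=quality,
                   obj_name=obj_name, prt=prt, pab=pab)


# ---------------------------------------------------------------------------
# tile grid


def tile_grid(section_size: tuple[int, int], tile_size: tuple[int, int]) -> tuple[int, int, int]:
    """Tile layout of a section: ``(cols, rows, count)``.

    Tiles are numbered row-major from 0; edge tiles are cropped to the
    section, so a 700x400 section with 256-pixel tiles is 3x2 = 6 tiles.
    """
    w, h = section_size
    tw, th = tile_size
    if w <= 0 or h <= 0 or tw <= 0 or th <= 0:
        raise ValueError("section and tile sizes must be positive")
    cols = -(-w // tw)
    rows = -(-h // th)
    return cols, rows, cols * rows


# ---------------------------------------------------------------------------
# caching


class LRUCache:
    """Thread-safe LRU cache instrumented with hit/miss/eviction history."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._d: dict = {}
        self._lock = threading.RLock()
        self.hits = 0
        self.misses = 0
        self.evicted: list = []

    def __len__(self) -> int:
        return len(self._d)

    def __contains__(self, key) -> bool:
        with self._lock:
            return key in self._d

    def get(self, key):
        with self._lock:
            if key not in self._d:
                self.misses += 1
                return None
            self.hits += 1
            val = self._d.pop(key)
            self._d[key] = val
            return val

    def put(self, key, val) -> None:
        with self._lock:
            if key in self._d:
                self._d.pop(key)
            self._d[key] = val
            while len(self._d) > self.capacity:
                old = next(iter(self._d))
                self._d.pop(old)
                self.evicted.append(old)

    def get_or_compute(self, key, compute):
        val = self.get(key)
        if val is None:
            val = compute()
            self.put(key, val)
        return val


@dataclass(frozen=True)
class TileKey:
    """Cache identity of one encoded tile.

    Two requests with equal keys must produce byte-identical responses;
    the view digest covers every resolved view parameter at full float
    precision, so even an epsilon change of an angle is a cache miss.
    """

    resource: str
    view_digest: str
    sel_digest: str
    level: int
    tile_index: int
    fmt: str
    quality: int


def view_digest(view: ViewSpec) -> str:
    resolved = resolve_mode(view)
    payload = repr((resolved.fixed, resolved.pitch, resolved.yaw, resolved.roll,
                    resolved.dist, resolved.scale))
    return hashlib.sha1(payload.encode()).hexdigest()


def sel_digest(sel: tuple[SelEntry, ...]) -> str:
    payload = repr([(e.index, e.rgba) for e in sel])
    return hashlib.sha1(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# routing


@dataclass
class RoutingTable:
    """Ordered substring → backend rules with a mandatory default."""

    rules: list[tuple[str, str]] = field(default_factory=list)
    default: str = "default"


def route_request(query: str, table: RoutingTable) -> str:
    """Pick a backend for a query: first substring match wins, else default.

    Matching is purely string-level over the raw query, so any request
    syntax can be routed and proxies can be chained.
    """
    for needle, backend in table.rules:
        if needle in query:
            return backend
    return table.default


# ---------------------------------------------------------------------------
# encoding


def _grey_to_u8(pixels: np.ndarray, kind: str) -> np.ndarray:
    if kind == "u8":
        return pixels
    if kind == "u16":
        return (pixels >> 8).astype(np.uint8)
    if kind == "u32":
        return (pixels >> 24).astype(np.uint8)
    if kind == "f32":
        return np.floor(np.clip(pixels, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    raise ValueError(f"not a grey kind: {kind}")


def section_to_rgba(section: SectionImage) -> np.ndarray:
    """Render a section as 8-bit RGBA; out-of-domain pixels get alpha 0."""
    inside = section.inside
    if section.kind == "rgba":
        out = section.pixels.copy()
        out[~inside] = 0
        return out
    g = _grey_to_u8(section.pixels, section.kind)
    out = np.empty(inside.shape + (4,), dtype=np.uint8)
    out[..., 0] = g
    out[..., 1] = g
    out[..., 2] = g
    out[..., 3] = np.where(inside, 255, 0)
    out[~inside, :3] = 0
    return out


def encode_rgba(rgba: np.ndarray, fmt: str, quality: int, jpeg_background: int = 0) -> tuple[bytes, str]:
    """Encode an RGBA raster; PNG keeps alpha, JPEG flattens onto a grey."""
    if fmt == "png":
        buf = _io.BytesIO()
        Image.fromarray(rgba, "RGBA").save(buf, format="PNG", optimize=False)
        return buf.getvalue(), "image/png"
    if fmt == "jpeg":
        a = rgba[..., 3:4].astype(np.float64) / 255.0
        rgb = rgba[..., :3].astype(np.float64) * a + jpeg_background * (1.0 - a)
        img = Image.fromarray(np.floor(rgb + 0.5).astype(np.uint8), "RGB")
        buf = _io.BytesIO()
        img.save(buf, format="JPEG", quality=quality)
        return buf.getvalue(), "image/jpeg"
    if fmt == "raw":
        return np.ascontiguousarray(rgba).tobytes(), "application/octet-stream"
    raise ProtocolError(f"unknown image format {fmt!r}")


def encode_section(section: SectionImage, fmt: str, quality: int) -> tuple[bytes, str]:
    """Encode a bare (un-filtered) section.

    ``raw`` returns the native-kind pixel buffer (row-major, C order,
    little-endian); png/jpeg go through 8-bit RGBA rendering.
    """
    if fmt == "raw":
        px = np.ascontiguousarray(section.pixels)
        if px.dtype.byteorder == ">":
            px = px.astype(px.dtype.newbyteorder("<"))
        return px.tobytes(), "application/octet-stream"
    return encode_rgba(section_to_rgba(section), fmt, quality)


# ---------------------------------------------------------------------------
# the service


@dataclass
class ServiceConfig:
    """Server configuration; encoder settings are part of cache identity."""

    root: str | Path = "."
    tile_size: tuple[int, int] = (256, 256)
    tile_cache_capacity: int = 512
    object_cache_capacity: int = 8
    transform_cache_capacity: int = 64
    jpeg_quality: int = 75
    routing: RoutingTable | None = None
    port: int = 8080

    @classmethod
    def from_json(cls, path: str | Path) -> "ServiceConfig":
        spec = json.loads(Path(path).read_text())
        routing = None
        if "routing" in spec:
            routing = RoutingTable(
                rules=[tuple(r) for r in spec["routing"].get("rules", [])],
                default=spec["routing"].get("default", "default"),
            )
        return cls(
            root=spec.get("root", "."),
            tile_size=tuple(spec.get("tile_size", (256, 256))),
            tile_cache_capacity=spec.get("tile_cache_capacity", 512),
            object_cache_capacity=spec.get("object_cache_capacity", 8),
            transform_cache_capacity=spec.get("transform_cache_capacity", 64),
            jpeg_quality=spec.get("jpeg_quality", 75),
            routing=routing,
            port=spec.get("port", 8080),
        )


def load_object(path: Path):
    """Open a resource file as a volume or compound object.

    Recognized: block stores (``.vxb``), NIfTI (``.nii``/``.nii.gz``),
    multi-page 3D TIFF (``.tif``), compound manifests (``.json``) and
    TIFF-stack directories.
    """
    import tifffile

    if path.is_dir():
        return read_tiff_stack(path)
    suffix = path.suffix.lower()
    if suffix == ".vxb":
        return open_store(path)
    if suffix == ".json":
        return read_compound_manifest(path)
    if suffix in (".nii", ".gz"):
        return read_nifti(path)
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim not in (3, 4):
            raise ProtocolError(f"TIFF resource {path} is not a 3D volume")
        return VoxelVolume.from_dense(arr)
    raise ProtocolError(f"unrecognized resource type: {path.name}")


class TileService:
    """Library facade behind the HTTP endpoint.

    :meth:`handle` maps a raw query string to ``(status, mime, body)``.
    Everything else is the open-coded pipeline it uses, available for
    direct calls.
    """

    def __init__(self, config: ServiceConfig | None = None):
        self.config = config or ServiceConfig()
        self.tile_cache = LRUCache(self.config.tile_cache_capacity)
        self.object_cache = LRUCache(self.config.object_cache_capacity)
        self.transform_cache = LRUCache(self.config.transform_cache_capacity)

    # -- resources ----------------------------------------------------------

    def resolve_resource(self, resource: str) -> Path:
        """Map a WLZ path onto the object root, refusing path traversal."""
        root = Path(self.config.root).resolve()
        candidate = (root / resource.lstrip("/")).resolve()
        if not candidate.is_relative_to(root):
            raise ProtocolError(f"resource path {resource!r} escapes the object root")
        if not candidate.exists():
            raise ProtocolError(f"no such resource: {resource}")
        return candidate

    def open_object(self, resource: str):
        path = self.resolve_resource(resource)
        return self.object_cache.get_or_compute(str(path), lambda: load_object(path))

    # -- geometry -----------------------------------------------------------

    def get_transform(self, view: ViewSpec) -> ViewTransform:
        digest = view_digest(view)
        return self.transform_cache.get_or_compute(digest, lambda: build_transform(view))

    def frame_for(self, obj, t: ViewTransform) -> SectionFrame:
        bbox = obj.bounding_box()
        return section_frame(bbox, t)

    # -- rendering ----------------------------------------------------------

    def _render_region(self, obj, view: ViewSpec, sel: tuple[SelEntry, ...],
                       region, level: int, frame: SectionFrame):
        """Cut (and optionally SEL-composite) one region.

        Returns a :class:`SectionImage` when no SEL stack is present,
        otherwise an RGBA ndarray.
        """
        t = self.get_transform(view)
        if not sel:
            if isinstance(obj, CompoundObject):
                raise ProtocolError("rendering a compound object requires SEL entries")
            return cut_section(obj, t, region=region, level=level, frame=frame)
        layers = []
        for entry in sel:
            if isinstance(obj, CompoundObject):
                if entry.index >= len(obj):
                    raise ProtocolError(
                        f"SEL index {entry.index} out of range (compound has {len(obj)} members)")
                member = obj[entry.index]
            else:
                if entry.index != 0:
                    raise ProtocolError(
                        f"SEL index {entry.index} invalid for a non-compound resource")
                member = obj
            if member.has_values:
                sec = cut_section(member, t, region=region, level=level, frame=frame)
                layers.append(filter_value_layer(sec, entry))
            else:
                mask = cut_domain_section(member.domain, t, frame, region=region, level=level)
                layers.append(colour_domain_layer(mask, entry))
        return composite(layers)

    def _encode(self, rendered, fmt: str, quality: int) -> tuple[bytes, str]:
        if isinstance(rendered, SectionImage):
            return encode_section(rendered, fmt, quality)
        return encode_rgba(rendered, fmt, quality)

    def _tile_region(self, frame: SectionFrame, level: int, index: int):
        wl = -(-frame.width // (1 << level))
        hl = -(-frame.height // (1 << level))
        cols, rows, count = tile_grid((wl, hl), self.config.tile_size)
        if index >= count:
            raise ProtocolError(f"tile index {index} out of range (grid has {count} tiles)")
        tw, th = self.config.tile_size
        col, row = index % cols, index // cols
        tile_w = min(tw, wl - col * tw)
        tile_h = min(th, hl - row * th)
        f = 1 << level
        return (col * tw * f, row * th * f, tile_w * f, tile_h * f)

    def get_tile(self, resource: str, view: ViewSpec, sel: tuple[SelEntry, ...],
                 level: int, index: int, fmt: str, quality: int | None = None) -> tuple[bytes, str]:
        """Cut, composite and encode one tile, through the tile cache."""
        quality = quality if quality is not None else self.config.jpeg_quality
        key = TileKey(resource=resource, view_digest=view_digest(view),
                      sel_digest=sel_digest(sel), level=level, tile_index=index,
                      fmt=fmt, quality=quality)
        mime = {"png": "image/png", "jpeg": "image/jpeg", "raw": "application/octet-stream"}[fmt]

        def compute() -> bytes:
            obj = self.open_object(resource)
            t = self.get_transform(view)
            frame = self.frame_for(obj, t)
            region = self._tile_region(frame, level, index)
            rendered = self._render_region(obj, view, sel, region, level, frame)
            return self._encode(rendered, fmt, quality)[0]

        return self.tile_cache.get_or_compute(key, compute), mime

    def get_full_section(self, resource: str, view: ViewSpec, sel: tuple[SelEntry, ...],
                         level: int, fmt: str, quality: int | None = None) -> tuple[bytes, str]:
        """Cut, composite and encode the whole section frame (CVT)."""
        quality = quality if quality is not None else self.config.jpeg_quality
        obj = self.open_object(resource)
        t = self.get_transform(view)
        frame = self.frame_for(obj, t)
        rendered = self._render_region(obj, view, sel, None, level, frame)
        return self._encode(rendered, fmt, quality)

    # -- object queries ------------------------------------------------------

    def answer_obj_query(self, request: Request) -> str:
        """Answer a Table-style object query as a ``Name:value`` line."""
        name = request.obj_name
        if name == "IIP-server":
            return f"IIP-server:{SERVER_ID}\n"
        obj = self.open_object(request.resource)
        view = request.view
        t = self.get_transform(view)
        frame = self.frame_for(obj, t)

        def fmt_num(x: float) -> str:
            return f"{x:.6g}"

        if name == "Max-size":
            f = 1 << request.level
            return f"Max-size:{-(-frame.width // f)} {-(-frame.height // f)}\n"
        if name == "Tile-size":
            tw, th = self.config.tile_size
            return f"Tile-size:{tw} {th}\n"
        if name == "Wlz-3d-bounding-box":
            k1, l1, p1, k2, l2, p2 = obj.bounding_box()
            return f"Wlz-3d-bounding-box:{p1} {l1} {k1} {p2} {l2} {k2}\n"
        if name == "Wlz-distance-range":
            return f"Wlz-distance-range:{fmt_num(frame.dist_min)} {fmt_num(frame.dist_max)}\n"
        if name == "Wlz-sectioning-angles":
            r = resolve_mode(view)
            return f"Wlz-sectioning-angles:{fmt_num(r.pitch)} {fmt_num(r.yaw)} {fmt_num(r.roll)}\n"
        if name == "Wlz-true-voxel-size":
            sx, sy, sz = obj.voxel_size
            return f"Wlz-true-voxel-size:{fmt_num(sx)} {fmt_num(sy)} {fmt_num(sz)}\n"
        if name == "Wlz-volume":
            if isinstance(obj, CompoundObject):
                union = obj[0].domain
                for m in obj.members[1:]:
                    union = union | m.domain
                count = union.voxel_count
            else:
                count = obj.voxel_count
            return f"Wlz-volume:{count}\n"
        if name == "Wlz-transformed-coordinate-3d":
            if request.pab is None:
                raise ProtocolError("Wlz-transformed-coordinate-3d needs a PAB point")
            from .geometry import project_point
            x, y, dist = project_point(t, frame, request.pab)
            return f"Wlz-transformed-coordinate-3d:{fmt_num(x)} {fmt_num(y)} {fmt_num(dist)}\n"
        # the remaining queries need a concrete 3D point
        point3d = self._query_point(request, t, frame)
        if name == "Wlz-coordinate-3D":
            if request.prt is None:
                raise ProtocolError("Wlz-coordinate-3D needs a PRT point")
            x, y, z = point3d
            return f"Wlz-coordinate-3D:{fmt_num(x)} {fmt_num(y)} {fmt_num(z)}\n"
        voxel = tuple(int(math.floor(c + 0.5)) for c in point3d)
        if name == "Wlz-foreground-objects":
            if isinstance(obj, CompoundObject):
                idx = obj.members_at(voxel)
            else:
                idx = [0] if obj.domain.contains(*voxel) else []
            return "Wlz-foreground-objects:" + " ".join(str(i) for i in idx) + "\n"
        if name == "Wlz-grey-value":
            if isinstance(obj, CompoundObject):
                raise ProtocolError("Wlz-grey-value needs a value-bearing volume")
            v = obj.value_at(voxel)
            if v is OUTSIDE:
                return "Wlz-grey-value:outside\n"
            if isinstance(v, tuple):
                return "Wlz-grey-value:" + " ".join(str(c) for c in v) + "\n"
            if isinstance(v, float):
                return f"Wlz-grey-value:{fmt_num(v)}\n"
            return f"Wlz-grey-value:{v}\n"
        raise ProtocolError(f"unhandled object query {name!r}")

    def _query_point(self, request: Request, t: ViewTransform, frame: SectionFrame):
        """3D point of a query: PAB directly, or PRT unprojected."""
        if request.pab is not None:
            return tuple(request.pab)
        if request.prt is not None:
            from .geometry import unproject_point
            x, y = request.prt
            f = 1 << request.level
            if request.tile_index is not None:
                wl = -(-frame.width // f)
                cols, _, count = tile_grid((wl, -(-frame.height // f)), self.config.tile_size)
                if request.tile_index >= count:
                    raise ProtocolError(f"tile index {request.tile_index} out of range")
                tw, th = self.config.tile_size
                x += (request.tile_index % cols) * tw
                y += (request.tile_index // cols) * th
            return tuple(unproject_point(t, frame, (x * f, y * f)))
        raise ProtocolError(f"query {request.obj_name!r} needs a PRT or PAB point")

    # -- entry point ---------------------------------------------------------

    def handle(self, query: str) -> tuple[int, str, bytes]:
        """Serve one query string; returns ``(status, mime, body)``."""
        try:
            request = parse_request(query)
            if request.action == "tile":
                body, mime = self.get_tile(request.resource, request.view, request.sel,
                                           request.level, request.tile_index, request.fmt,
                                           request.quality)
                return 200, mime, body
            if request.action == "full":
                body, mime = self.get_full_section(request.resource, request.view, request.sel,
                                                   request.level, request.fmt, request.quality)
                return 200, mime, body
            if request.action == "query":
                return 200, "text/plain", self.answer_obj_query(request).encode()
            raise ProtocolError("request carries no action (tile, CVT or OBJ)")
        except ProtocolError as e:
            return 400, "text/plain", f"error:{e}\n".encode()
        except (EmptyObjectError, NoValuesError, VoxtileError) as e:
            return 422, "text/plain", f"error:{e}\n".encode()


class Proxy:
    """Protocol-level request router over a set of backend handlers.

    ``backends`` maps backend ids to objects with a ``handle(query)``
    method (typically :class:`TileService` instances).
    """

    def __init__(self, table: RoutingTable, backends: dict):
        if table.default not in backends:
            raise ValueError(f"default backend {table.default!r} not provided")
        self.table = table
        self.backends = backends

    def handle(self, query: str) -> tuple[int, str, bytes]:
        return self.backends[route_request(query, self.table)].handle(query)


def make_server(service: TileService, port: int | None = None, host: str = "127.0.0.1"):
    """Build the HTTP front end (``GET /iip3d?<query>``) without starting it."""
    from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

    class Handler(BaseHTTPRequestHandler):
        def do_GET(self):  # noqa: N802 (stdlib naming)
            path, _, query = self.path.partition("?")
            if path not in ("/iip3d", "/"):
                self.send_error(404, "unknown endpoint")
                return
            status, mime, body = service.handle(query)
            self.send_response(status)
            self.send_header("Content-Type", mime)
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def log_message(self, *args):
            pass

    return ThreadingHTTPServer((host, service.config.port if port is None else port), Handler)


def serve(service: TileService, port: int | None = None, host: str = "127.0.0.1"):
    """Run the blocking HTTP front end: ``GET /iip3d?<query>``."""
    server = make_server(service, port=port, host=host)
    try:
        server.serve_forever()
    finally:
        server.server_close()
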