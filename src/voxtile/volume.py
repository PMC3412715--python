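"""Voxel volumes: an interval domain paired with a value table.

The spatial domain of an object and its image values are separate
structures.  A :class:`VoxelVolume` may carry no values at all
(a pure region of space, e.g. an anatomy delineation), or grey values
of several widths, or RGBA colour.  Values exist only for in-domain
voxels; everything else is *background*, which is never stored.

A :class:`CompoundObject` is an ordered, indexed list of volumes in a
single global coordinate frame.  Members may overlap arbitrarily and
their number is unbounded — the index is not constrained by the bit
depth of any raster.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .domain import IntervalDomain3D
from .errors import EmptyObjectError, NoValuesError

__all__ = [
    "OUTSIDE",
    "VALUE_KINDS",
    "VoxelVolume",
    "CompoundObject",
    "bounding_box",
    "volume_stats",
    "value_at",
    "members_at",
]


class _Outside:
    """Sentinel returned by value queries at out-of-domain points."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "OUTSIDE"

    def __bool__(self) -> bool:
        return False


OUTSIDE = _Outside()

#: value kind -> (numpy dtype, number of channels)
VALUE_KINDS: dict[str, tuple[np.dtype, int]] = {
    "u8": (np.dtype(np.uint8), 1),
    "u16": (np.dtype(np.uint16), 1),
    "u32": (np.dtype(np.uint32), 1),
    "f32": (np.dtype(np.float32), 1),
    "rgba": (np.dtype(np.uint8), 4),
}


def kind_of_dtype(dtype: np.dtype, channels: int = 1) -> str:
    if channels == 4:
        return "rgba"
    for kind, (dt, ch) in VALUE_KINDS.items():
        if ch == 1 and dt == dtype:
            return kind
    raise ValueError(f"unsupported value dtype {dtype}")


def default_background(kind: str):
    return (0, 0, 0, 0) if kind == "rgba" else 0


class VoxelVolume:
    """A 3D image object: domain, optional value table, voxel size.

    Values, when present, are held dense over the tight bounding box in
    plane-major order (``values[p - p1, l - l1, k - k1]``), which keeps
    axis-aligned plane reads contiguous; the domain alone decides which
    of those cells are real.  ``voxel_size`` is ``(sx, sy, sz)``
    physical units per step along k, l, p.
    """

    def __init__(
        self,
        domain: IntervalDomain3D,
        values: np.ndarray | None = None,
        kind: str | None = None,
        background=None,
        voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> None:
        if any(s <= 0 for s in voxel_size):
            raise ValueError("voxel_size components must be strictly positive")
        self.domain = domain
        self.voxel_size = tuple(float(s) for s in voxel_size)
        if values is None:
            self.values = None
            self.kind = kind
            self.background = background
            return
        values = np.asarray(values)
        if kind is None:
            kind = kind_of_dtype(values.dtype, values.shape[-1] if values.ndim == 4 else 1)
        dtype, channels = VALUE_KINDS[kind]
        expect_ndim = 4 if channels == 4 else 3
        if values.ndim != expect_ndim:
            raise ValueError(f"{kind} values must be {expect_ndim}D, got shape {values.shape}")
        if domain.is_empty:
            raise ValueError("cannot attach values to an empty domain")
        k1, l1, p1, k2, l2, p2 = domain.bbox
        expect_shape = (p2 - p1 + 1, l2 - l1 + 1, k2 - k1 + 1)
        if tuple(values.shape[:3]) != expect_shape:
            raise ValueError(
                f"value table shape {values.shape[:3]} does not cover bbox extent {expect_shape}"
            )
        self.values = np.ascontiguousarray(values, dtype=dtype)
        self.kind = kind
        self.background = background if background is not None else default_background(kind)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dense(
        cls,
        array: np.ndarray,
        origin: tuple[int, int, int] = (0, 0, 0),
        voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
        kind: str | None = None,
        background=None,
        domain: IntervalDomain3D | None = None,
    ) -> "VoxelVolume":
        """Wrap a dense ``[p, l, k]`` array; domain defaults to the full box."""
        array = np.asarray(array)
        if domain is None:
            k0, l0, p0 = origin
            n_p, n_l, n_k = array.shape[:3]
            domain = IntervalDomain3D.from_box(k0, l0, p0, k0 + n_k - 1, l0 + n_l - 1, p0 + n_p - 1)
        return cls(domain, array, kind=kind, background=background, voxel_size=voxel_size)

    @classmethod
    def domain_only(
        cls,
        domain: IntervalDomain3D,
        voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> "VoxelVolume":
        return cls(domain, None, voxel_size=voxel_size)

    # -- queries ------------------------------------------------------------

    @property
    def has_values(self) -> bool:
        return self.values is not None

    @property
    def channels(self) -> int:
        if self.kind is None:
            return 0
        return VALUE_KINDS[self.kind][1]

    def bounding_box(self) -> tuple[int, int, int, int, int, int]:
        """Tight inclusive ``(k1, l1, p1, k2, l2, p2)`` in global coordinates."""
        if self.domain.is_empty:
            raise EmptyObjectError("empty object has no bounding box")
        return self.domain.bbox

    @property
    def voxel_count(self) -> int:
        return self.domain.voxel_count

    @property
    def physical_volume(self) -> float:
        sx, sy, sz = self.voxel_size
        return self.domain.voxel_count * sx * sy * sz

    def read_values(self, kk: np.ndarray, ll: np.ndarray, pp: np.ndarray) -> np.ndarray:
        """Gather stored values at integer voxel coordinates.

        Callers are expected to have established domain membership;
        points merely inside the bounding box return whatever the value
        table holds there, points outside it return background.  Lazy
        representations override this with on-demand block reads.
        """
        if not self.has_values:
            raise NoValuesError("object has no value table")
        k1, l1, p1, k2, l2, p2 = self.domain.bbox
        kk = np.asarray(kk, dtype=np.int64)
        ll = np.asarray(ll, dtype=np.int64)
        pp = np.asarray(pp, dtype=np.int64)
        inb = (kk >= k1) & (kk <= k2) & (ll >= l1) & (ll <= l2) & (pp >= p1) & (pp <= p2)
        shape = kk.shape + ((4,) if self.channels == 4 else ())
        out = np.empty(shape, dtype=self.values.dtype)
        out[...] = np.asarray(self.background, dtype=self.values.dtype)
        out[inb] = self.values[pp[inb] - p1, ll[inb] - l1, kk[inb] - k1]
        return out

    def value_at(self, point: tuple[int, int, int]):
        """Value at a global voxel, or the :data:`OUTSIDE` sentinel.

        Raises :class:`NoValuesError` for domain-only objects.
        """
        if not self.has_values:
            raise NoValuesError("object has no value table")
        k, l, p = (int(round(c)) for c in point)
        if not self.domain.contains(k, l, p):
            return OUTSIDE
        v = self.read_values(np.array([k]), np.array([l]), np.array([p]))[0]
        if self.channels == 4:
            return tuple(int(c) for c in v)
        return v.item()

    def translate(self, dk: int, dl: int, dp: int) -> "VoxelVolume":
        return VoxelVolume(
            self.domain.translate(dk, dl, dp),
            self.values,
            kind=self.kind,
            background=self.background,
            voxel_size=self.voxel_size,
        )

    def __repr__(self) -> str:
        tag = self.kind if self.has_values else "domain-only"
        if self.domain.is_empty:
            return f"VoxelVolume({tag}, empty)"
        return f"VoxelVolume({tag}, bbox={self.domain.bbox}, voxels={self.voxel_count})"


class CompoundObject:
    """Ordered, indexed list of member volumes in one coordinate frame."""

    def __init__(self, members: Sequence[VoxelVolume]) -> None:
        self.members = list(members)

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, index: int) -> VoxelVolume:
        return self.members[index]

    def __iter__(self):
        return iter(self.members)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        if not self.members:
            return (1.0, 1.0, 1.0)
        return self.members[0].voxel_size

    def bounding_box(self) -> tuple[int, int, int, int, int, int]:
        """Union bounding box across all non-empty members."""
        boxes = [m.domain.bbox for m in self.members if not m.domain.is_empty]
        if not boxes:
            raise EmptyObjectError("compound object has no non-empty member")
        arr = np.asarray(boxes)
        lo = arr[:, :3].min(axis=0)
        hi = arr[:, 3:].max(axis=0)
        return (int(lo[0]), int(lo[1]), int(lo[2]), int(hi[0]), int(hi[1]), int(hi[2]))

    def members_at(self, point: tuple[int, int, int]) -> list[int]:
        """Ascending indices of every member whose domain contains *point*.

        Overlap means the answer is a list in general, possibly empty.
        """
        k, l, p = (int(c) for c in point)
        return [i for i, m in enumerate(self.members) if m.domain.contains(k, l, p)]


# ---------------------------------------------------------------------------
# functional aliases matching the operation-style API


def bounding_box(obj: VoxelVolume) -> tuple[int, int, int, int, int, int]:
    return obj.bounding_box()


def volume_stats(obj: VoxelVolume) -> tuple[int, float]:
    """``(voxel_count, physical_volume)`` where the latter is count × sx·sy·sz."""
    return obj.voxel_count, obj.physical_volume


def value_at(obj: VoxelVolume, point: tuple[int, int, int]):
    return obj.value_at(point)


def members_at(compound: CompoundObject, point: tuple[int, int, int]) -> list[int]:
    return compound.members_at(point)
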