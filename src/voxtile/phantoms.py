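"""Deterministic synthetic phantoms with closed-form answers.

These stand in for the atlas and whole-body volumes the system is meant
to serve: every phantom's value at any voxel, its domain membership and
its bounding box follow from a formula, so sectioning, query and store
round-trips can be checked bit-exactly without any external data.

The gradient phantom encodes the coordinate axes into the value with
coefficients (1, 10, 100): a single transposed axis or off-by-one flips
every affected pixel, so geometry bugs cannot hide.
"""

from __future__ import annotations

import numpy as np

from .domain import IntervalDomain3D
from .volume import CompoundObject, VoxelVolume

__all__ = [
    "make_gradient_volume",
    "make_sphere_phantom",
    "make_compound_phantom",
    "make_rgb_phantom",
    "make_random_domain",
]

_KIND_MOD = {"u8": 256, "u16": 65536, "u32": 2**32}


def make_gradient_volume(
    dims: tuple[int, int, int],
    kind: str = "u16",
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VoxelVolume:
    """Full-box volume with value ``(k + 10·l + 100·p) mod range``.

    ``dims`` is ``(nk, nl, np)``; the origin is (0, 0, 0).
    """
    nk, nl, npl = dims
    kk = np.arange(nk, dtype=np.int64)
    ll = np.arange(nl, dtype=np.int64)
    pp = np.arange(npl, dtype=np.int64)
    vals = (kk[None, None, :] + 10 * ll[None, :, None] + 100 * pp[:, None, None]) % _KIND_MOD[kind]
    dtype = {"u8": np.uint8, "u16": np.uint16, "u32": np.uint32}[kind]
    return VoxelVolume.from_dense(vals.astype(dtype), voxel_size=voxel_size, kind=kind)


def gradient_value(k: int, l: int, p: int, kind: str = "u16") -> int:
    """Closed-form oracle for :func:`make_gradient_volume`."""
    return (k + 10 * l + 100 * p) % _KIND_MOD[kind]


def make_sphere_phantom(
    dims: tuple[int, int, int],
    centre: tuple[int, int, int] | None = None,
    radius: float = 10.0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VoxelVolume:
    """Digital ball: domain = voxels within ``radius`` of ``centre``.

    Values are distance-coded grey (u8): round(distance from centre),
    so the centre voxel reads 0 and values grow outward.
    """
    nk, nl, npl = dims
    if centre is None:
        centre = (nk // 2, nl // 2, npl // 2)
    ck, cl, cp = centre
    kk = np.arange(nk, dtype=np.float64)[None, None, :] - ck
    ll = np.arange(nl, dtype=np.float64)[None, :, None] - cl
    pp = np.arange(npl, dtype=np.float64)[:, None, None] - cp
    dist = np.sqrt(kk**2 + ll**2 + pp**2)
    mask = dist <= radius
    domain = IntervalDomain3D.from_mask(mask)
    if domain.is_empty:
        return VoxelVolume.domain_only(domain, voxel_size=voxel_size)
    vals = np.floor(dist + 0.5).clip(0, 255).astype(np.uint8)
    k1, l1, p1, k2, l2, p2 = domain.bbox
    sub = vals[p1 : p2 + 1, l1 : l2 + 1, k1 : k2 + 1]
    return VoxelVolume(domain, sub, kind="u8", voxel_size=voxel_size)


def make_compound_phantom(
    dims: tuple[int, int, int],
    n_members: int = 4,
    overlap: float = 0.5,
    member_size: int | None = None,
    seed: int = 0,
) -> CompoundObject:
    """Indexed compound of cubic domains with controlled pairwise overlap.

    Members are axis-aligned cubes laid out along a raster path;
    consecutive members share a slab whose thickness is
    ``round(overlap · side)`` columns, so ``overlap > 0`` guarantees a
    lens region where exactly two members coincide and ``overlap = 0``
    makes all members disjoint.  ``n_members`` may exceed 255 — the
    index space is unbounded.  ``seed`` only varies the member grey
    tags, not the geometry, keeping overlaps exact by construction.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    nk, nl, npl = dims
    side = member_size if member_size is not None else max(2, min(nk, nl, npl) // 4)
    ov = int(round(overlap * side))
    step = side - ov if ov else side + 1
    per_row = max(1, (nk - side) // step + 1)
    per_plane_rows = max(1, (nl - side) // max(side + 1, 1) + 1)
    members = []
    for i in range(n_members):
        col = i % per_row
        row = (i // per_row) % per_plane_rows
        dep = i // (per_row * per_plane_rows)
        k0 = col * step
        l0 = row * (side + 1)
        p0 = dep * (side + 1)
        dom = IntervalDomain3D.from_box(k0, l0, p0, k0 + side - 1, l0 + side - 1, p0 + side - 1)
        members.append(VoxelVolume.domain_only(dom))
    return CompoundObject(members)


def compound_lens_point(compound: CompoundObject, i: int, j: int) -> tuple[int, int, int] | None:
    """A voxel inside both members ``i`` and ``j``, or None if disjoint."""
    lens = compound[i].domain & compound[j].domain
    if lens.is_empty:
        return None
    p, l, k0, _ = next(lens.interval_tuples())
    return (k0, l, p)


def make_rgb_phantom(
    dims: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VoxelVolume:
    """Full-box RGBA volume: r = k ramp, g = l ramp, b = p ramp, a = 255.

    Each ramp is taken mod 256; channel separability makes colour-filter
    and per-channel sectioning errors visible immediately.
    """
    nk, nl, npl = dims
    vals = np.empty((npl, nl, nk, 4), dtype=np.uint8)
    vals[..., 0] = (np.arange(nk) % 256)[None, None, :]
    vals[..., 1] = (np.arange(nl) % 256)[None, :, None]
    vals[..., 2] = (np.arange(npl) % 256)[:, None, None]
    vals[..., 3] = 255
    return VoxelVolume.from_dense(vals, voxel_size=voxel_size, kind="rgba")


def make_random_domain(
    dims: tuple[int, int, int],
    density: float = 0.5,
    seed: int = 0,
    origin: tuple[int, int, int] = (0, 0, 0),
) -> IntervalDomain3D:
    """Seeded random voxel set — substrate for set-operation oracles."""
    rng = np.random.default_rng(seed)
    nk, nl, npl = dims
    mask = rng.random((npl, nl, nk)) < density
    return IntervalDomain3D.from_mask(mask, origin)
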