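"""Cutting 2D section rasters out of 3D volumes.

Every output pixel centre of a requested region is inverse-mapped
through the viewing transform onto a continuous object-space point and
the volume is sampled there — nearest-neighbour by default (the right
choice for histology grey levels and mandatory for label domains),
trilinear on request for scalar kinds.

Resolution levels form a power-of-two pyramid on top of the continuous
``scale`` factor: a level-L raster is the level-0 cut of the same
region aggregated over 2^L × 2^L blocks (mean over in-domain pixels for
values, any-true for the inside mask).  Cutting at level L and
box-downscaling a level-0 cut therefore agree to within one grey level
of rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domain import IntervalDomain3D
from .errors import GeometryError
from .geometry import SectionFrame, ViewSpec, ViewTransform, build_transform, section_frame
from .volume import VALUE_KINDS, VoxelVolume

__all__ = ["SectionImage", "cut_section", "cut_domain_section", "downscale"]

Region = tuple[int, int, int, int]  # (x0, y0, width, height) at level 0, frame-relative


@dataclass
class SectionImage:
    """A cut 2D raster in section-frame coordinates.

    ``pixels`` carries the source value kind (shape ``(h, w)`` or
    ``(h, w, 4)`` for rgba); ``inside`` flags pixels whose sample point
    fell inside the object's domain — everything else holds background.
    """

    pixels: np.ndarray
    inside: np.ndarray
    frame: SectionFrame
    level: int
    kind: str
    background: object
    region: Region

    @property
    def shape(self) -> tuple[int, int]:
        return self.inside.shape


def _resolve(view: ViewSpec | ViewTransform) -> ViewTransform:
    if isinstance(view, ViewTransform):
        return view
    return build_transform(view)


def _full_region(frame: SectionFrame) -> Region:
    return (0, 0, frame.width, frame.height)


def _sample_grid(t: ViewTransform, frame: SectionFrame, region: Region) -> tuple[np.ndarray, ...]:
    """Nearest voxel coordinates for every level-0 pixel of *region*."""
    x0, y0, w, h = region
    xs = np.arange(x0, x0 + w, dtype=float) + frame.x_off
    ys = np.arange(y0, y0 + h, dtype=float) + frame.y_off
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx, gy, np.full_like(gx, float(t.dist))], axis=-1)
    obj = t.from_view(pts)
    # nearest-neighbour: round half toward +inf on every axis
    vox = np.floor(obj + 0.5).astype(np.int64)
    return obj, vox[..., 0], vox[..., 1], vox[..., 2]


def cut_section(
    vol: VoxelVolume,
    view: ViewSpec | ViewTransform,
    region: Region | None = None,
    level: int = 0,
    frame: SectionFrame | None = None,
    interp: str = "nearest",
) -> SectionImage:
    """Cut an arbitrary virtual section from a volume.

    ``region`` is a rectangle in level-0 section-frame pixels (relative
    to the frame offsets); the default is the whole frame.  ``frame``
    may be supplied to cut in a shared frame (e.g. a compound object's
    union frame); by default it derives from the volume's own bounding
    box.  The returned raster has ``ceil(region / 2**level)`` pixels.
    """
    if not vol.has_values:
        raise GeometryError("cut_section needs a value-bearing volume; "
                            "use cut_domain_section for domain-only objects")
    if level < 0:
        raise ValueError("level must be >= 0")
    t = _resolve(view)
    if frame is None:
        frame = section_frame(vol.bounding_box(), t)
    if region is None:
        region = _full_region(frame)
    base = _cut_level0(vol, t, frame, region, interp)
    if level:
        base = downscale(base, level)
    return base


def _cut_level0(vol: VoxelVolume, t: ViewTransform, frame: SectionFrame,
                region: Region, interp: str) -> SectionImage:
    obj, kk, ll, pp = _sample_grid(t, frame, region)
    inside = vol.domain.contains_points(kk, ll, pp)
    dtype, channels = VALUE_KINDS[vol.kind]
    shape = inside.shape + ((4,) if channels == 4 else ())
    pixels = np.empty(shape, dtype=dtype)
    pixels[...] = np.asarray(vol.background, dtype=dtype)
    if inside.any():
        if interp == "nearest":
            vals = vol.read_values(kk[inside], ll[inside], pp[inside])
        elif interp == "trilinear":
            if channels == 4:
                raise ValueError("trilinear interpolation is limited to scalar kinds")
            vals = _trilinear(vol, obj[inside])
            if dtype.kind == "u":
                vals = np.floor(vals + 0.5).clip(0, np.iinfo(dtype).max)
            vals = vals.astype(dtype)
        else:
            raise ValueError(f"unknown interpolation {interp!r}")
        pixels[inside] = vals
    return SectionImage(pixels=pixels, inside=inside, frame=frame, level=0,
                        kind=vol.kind, background=vol.background, region=region)


def _trilinear(vol: VoxelVolume, pts: np.ndarray) -> np.ndarray:
    """Trilinear sample at continuous (k, l, p); background pads missing corners."""
    base = np.floor(pts).astype(np.int64)
    frac = pts - base
    acc = np.zeros(len(pts), dtype=np.float64)
    for dk in (0, 1):
        for dl in (0, 1):
            for dp in (0, 1):
                kk = base[:, 0] + dk
                ll = base[:, 1] + dl
                pp = base[:, 2] + dp
                w = (
                    (frac[:, 0] if dk else 1 - frac[:, 0])
                    * (frac[:, 1] if dl else 1 - frac[:, 1])
                    * (frac[:, 2] if dp else 1 - frac[:, 2])
                )
                inside = vol.domain.contains_points(kk, ll, pp)
                corner = np.full(len(pts), float(np.asarray(vol.background)), dtype=np.float64)
                if inside.any():
                    corner[inside] = vol.read_values(kk[inside], ll[inside], pp[inside]).astype(np.float64)
                acc += w * corner
    return acc


def cut_domain_section(
    dom: IntervalDomain3D,
    view: ViewSpec | ViewTransform,
    frame: SectionFrame,
    region: Region | None = None,
    level: int = 0,
) -> np.ndarray:
    """Boolean section mask of a bare domain, same geometry as cut_section.

    Sectioning a domain commutes with set union: OR-ing per-member masks
    of a compound equals the mask of the union domain cut with the same
    view and frame.  Always nearest-neighbour.
    """
    t = _resolve(view)
    if region is None:
        region = _full_region(frame)
    _, kk, ll, pp = _sample_grid(t, frame, region)
    mask = dom.contains_points(kk, ll, pp)
    for _ in range(level):
        mask = _block_any(mask)
    return mask


def _pad_to_even(a: np.ndarray, fill) -> np.ndarray:
    h, w = a.shape[:2]
    ph, pw = h % 2, w % 2
    if not ph and not pw:
        return a
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (a.ndim - 2)
    return np.pad(a, pad, constant_values=fill)


def _block_any(mask: np.ndarray) -> np.ndarray:
    m = _pad_to_even(mask, False)
    h, w = m.shape
    return m.reshape(h // 2, 2, w // 2, 2).any(axis=(1, 3))


def downscale(section: SectionImage, levels: int = 1) -> SectionImage:
    """Box-filter a section down the pyramid by *levels* halvings.

    Value pixels average over the in-domain pixels of each 2×2 block
    (so background never bleeds into the object); the inside mask is
    any-true.  Integer kinds round half up once per halving.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    pixels, inside = section.pixels, section.inside
    dtype, channels = VALUE_KINDS[section.kind]
    for _ in range(levels):
        ins = _pad_to_even(inside, False)
        px = _pad_to_even(pixels, 0)
        h, w = ins.shape
        insb = ins.reshape(h // 2, 2, w // 2, 2)
        counts = insb.sum(axis=(1, 3))
        if channels == 4:
            pxb = px.reshape(h // 2, 2, w // 2, 2, 4).astype(np.float64)
            sums = (pxb * insb[..., None]).sum(axis=(1, 3))
        else:
            pxb = px.reshape(h // 2, 2, w // 2, 2).astype(np.float64)
            sums = (pxb * insb).sum(axis=(1, 3))
        inside = counts > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = sums / np.where(counts == 0, 1, counts)[..., None] if channels == 4 \
                else sums / np.where(counts == 0, 1, counts)
        if dtype.kind in "ui":
            mean = np.floor(mean + 0.5)
        out = np.empty(mean.shape, dtype=dtype)
        out[...] = np.asarray(section.background, dtype=dtype)
        out[inside] = mean[inside].astype(dtype)
        pixels = out
    return SectionImage(pixels=pixels, inside=inside, frame=section.frame,
                        level=section.level + levels, kind=section.kind,
                        background=section.background, region=section.region)
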