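"""Indexed overlay selection (SEL) and RGBA layer compositing.

An atlas overlay request is an ordered stack of SEL entries, each
naming a member index of a compound object plus an RGBA colour.  Bare
domains are painted with the colour; value-bearing layers are
colour-filtered channelwise.  The resulting RGBA layers are merged with
the standard source-over operator in request order, so overlapping
regions blend and the order matters.

Arithmetic is done in premultiplied float and quantized to 8 bits only
at the end, which keeps over-composition associative to within a single
final rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ProtocolError
from .section import SectionImage

__all__ = [
    "SelEntry",
    "parse_sel",
    "colour_domain_layer",
    "filter_value_layer",
    "composite",
    "composite_premultiplied",
]


@dataclass(frozen=True)
class SelEntry:
    """One overlay selection: member index plus RGBA channel specifiers."""

    index: int
    r: int = 255
    g: int = 255
    b: int = 255
    a: int = 255

    def __post_init__(self):
        if self.index < 0:
            raise ProtocolError(f"SEL index must be >= 0, got {self.index}")
        for name in ("r", "g", "b", "a"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ProtocolError(f"SEL channel {name}={v} outside 0..255")

    @property
    def rgba(self) -> tuple[int, int, int, int]:
        return (self.r, self.g, self.b, self.a)


def parse_sel(args: Sequence[str]) -> SelEntry:
    """Parse the argument list of one SEL command.

    Accepted arities, with 255 defaulting the omitted channels:

    * ``index`` — opaque white
    * ``index, alpha`` — white with the given opacity (dialect choice:
      the two-parameter form reads as per-layer visibility)
    * ``index, r, g, b`` — opaque colour
    * ``index, r, g, b, a`` — full form
    """
    try:
        vals = [int(a) for a in args]
    except (TypeError, ValueError):
        raise ProtocolError(f"SEL arguments must be integers, got {list(args)!r}")
    if len(vals) == 1:
        return SelEntry(vals[0])
    if len(vals) == 2:
        return SelEntry(vals[0], a=vals[1])
    if len(vals) == 4:
        return SelEntry(vals[0], *vals[1:], a=255)
    if len(vals) == 5:
        return SelEntry(vals[0], *vals[1:])
    raise ProtocolError(f"SEL takes 1, 2, 4 or 5 arguments, got {len(vals)}")


def colour_domain_layer(mask: np.ndarray, entry: SelEntry) -> np.ndarray:
    """Paint a boolean section mask with the entry's RGBA colour.

    Out-of-mask pixels are fully transparent.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape + (4,), dtype=np.uint8)
    out[mask] = np.array(entry.rgba, dtype=np.uint8)
    return out


def filter_value_layer(section: SectionImage, entry: SelEntry) -> np.ndarray:
    """Colour-filter a value-bearing section into an RGBA layer.

    Grey g0 becomes ``(g0·r/255, g0·g/255, g0·b/255, a)`` (integer floor
    arithmetic); RGBA input is filtered channelwise, including alpha.
    Out-of-domain pixels are fully transparent.  Wider grey kinds are
    range-compressed to 8 bits first.
    """
    inside = section.inside
    out = np.zeros(inside.shape + (4,), dtype=np.uint8)
    px = section.pixels
    if section.kind == "rgba":
        filt = np.array(entry.rgba, dtype=np.uint32)
        vals = (px.astype(np.uint32) * filt) // 255
        out[inside] = vals[inside].astype(np.uint8)
        return out
    grey = px.astype(np.float64)
    if section.kind == "u16":
        grey = grey / 257.0
    elif section.kind == "u32":
        grey = grey / 16843009.0
    elif section.kind == "f32":
        grey = np.clip(grey, 0.0, 1.0) * 255.0
    g8 = np.floor(grey).astype(np.uint32).clip(0, 255)
    layer = np.empty(inside.shape + (4,), dtype=np.uint8)
    layer[..., 0] = (g8 * entry.r) // 255
    layer[..., 1] = (g8 * entry.g) // 255
    layer[..., 2] = (g8 * entry.b) // 255
    layer[..., 3] = entry.a
    out[inside] = layer[inside]
    return out


def _to_premultiplied(layer: np.ndarray) -> np.ndarray:
    f = layer.astype(np.float64) / 255.0
    out = np.empty_like(f)
    out[..., :3] = f[..., :3] * f[..., 3:4]
    out[..., 3] = f[..., 3]
    return out


def composite_premultiplied(stack: Iterable[np.ndarray]) -> np.ndarray:
    """Fold source-over across premultiplied float RGBA layers."""
    acc = None
    for layer in stack:
        if acc is None:
            acc = layer.copy()
            continue
        if layer.shape != acc.shape:
            raise ValueError(f"layer shape {layer.shape} != {acc.shape}")
        acc = layer + acc * (1.0 - layer[..., 3:4])
    if acc is None:
        raise ValueError("cannot composite an empty stack")
    return acc


def composite(stack: Sequence[np.ndarray]) -> np.ndarray:
    """Source-over composite of 8-bit RGBA rasters in stack order.

    Later entries go *over* earlier ones.  The fold runs in
    premultiplied float; the result is un-premultiplied and quantized
    round-half-up to 8 bits.
    """
    if not stack:
        raise ValueError("cannot composite an empty stack")
    shapes = {tuple(layer.shape) for layer in stack}
    if len(shapes) != 1:
        raise ValueError(f"layer shapes differ: {sorted(shapes)}")
    acc = composite_premultiplied(_to_premultiplied(np.asarray(l)) for l in stack)
    alpha = acc[..., 3:4]
    rgb = np.divide(acc[..., :3], alpha, out=np.zeros_like(acc[..., :3]), where=alpha > 0)
    out = np.concatenate([rgb, alpha], axis=-1)
    return np.floor(out * 255.0 + 0.5).clip(0, 255).astype(np.uint8)
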