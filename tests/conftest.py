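"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from voxtile.geometry import ViewSpec, build_transform
from voxtile.phantoms import (make_compound_phantom, make_gradient_volume,
                              make_rgb_phantom, make_sphere_phantom)


@pytest.fixture(scope="session")
def gradient_vol():
    return make_gradient_volume((40, 40, 40), kind="u16")


@pytest.fixture(scope="session")
def sphere_vol():
    return make_sphere_phantom((50, 50, 50), radius=20.0)


@pytest.fixture(scope="session")
def rgb_vol():
    return make_rgb_phantom((16, 16, 16))


@pytest.fixture(scope="session")
def compound_overlapping():
    return make_compound_phantom((40, 40, 40), n_members=4, overlap=0.5)


def random_views(rng: np.random.Generator, n: int, fixed_range: float = 20.0):
    """Draw arbitrary absolute-mode views for oracle comparisons."""
    views = []
    for _ in range(n):
        views.append(ViewSpec(
            fixed=tuple(rng.uniform(0, fixed_range, 3)),
            pitch=float(rng.uniform(-90, 90)),
            yaw=float(rng.uniform(-180, 180)),
            roll=float(rng.uniform(-180, 180)),
            dist=float(rng.uniform(-5, 5)),
            scale=float(rng.uniform(0.5, 2.0)),
        ))
    return views


def oracle_cut_pixels(vol, view: ViewSpec, frame, region=None):
    """Per-pixel reference for cut_section at level 0.

    Loops over output pixels, applies the inverse affine map with plain
    scalar arithmetic, rounds each coordinate half-up to the nearest
    voxel, and looks the value up in a dense mask/value copy.  Entirely
    independent of the vectorized production path.
    """
    t = build_transform(view)
    rot = t.rotation
    fx, fy, fz = t.fixed
    mask, (ok, ol, op) = vol.domain.to_mask()
    dense = np.asarray(vol.values)
    if region is None:
        region = (0, 0, frame.width, frame.height)
    x0, y0, w, h = region
    channels = 4 if vol.kind == "rgba" else 1
    shape = (h, w) if channels == 1 else (h, w, 4)
    pixels = np.empty(shape, dtype=dense.dtype)
    pixels[...] = np.asarray(vol.background, dtype=dense.dtype)
    inside = np.zeros((h, w), dtype=bool)
    for j in range(h):
        for i in range(w):
            xv = (x0 + i + frame.x_off) / t.scale
            yv = (y0 + j + frame.y_off) / t.scale
            zv = t.dist / t.scale
            k = rot[0][0] * xv + rot[1][0] * yv + rot[2][0] * zv + fx
            l = rot[0][1] * xv + rot[1][1] * yv + rot[2][1] * zv + fy
            p = rot[0][2] * xv + rot[1][2] * yv + rot[2][2] * zv + fz
            ki = math.floor(k + 0.5)
            li = math.floor(l + 0.5)
            pi = math.floor(p + 0.5)
            zk, zl, zp = ki - ok, li - ol, pi - op
            if (0 <= zp < mask.shape[0] and 0 <= zl < mask.shape[1]
                    and 0 <= zk < mask.shape[2] and mask[zp, zl, zk]):
                inside[j, i] = True
                pixels[j, i] = dense[zp, zl, zk]
    return pixels, inside
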