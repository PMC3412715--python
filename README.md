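# voxtile

Interactive browsing of very large 3D biomedical images — histology
reconstructions, embryo atlases, whole-body colour volumes — is limited by
RAM and bandwidth: a single full-colour volume easily exceeds 10 GiB, and an
archive holds hundreds of them. `voxtile` solves the problem for *section
views*: it cuts arbitrary oblique 2D sections through volumetric data on the
server side and delivers them as compressed tiles over a small query
protocol, so a client only ever downloads the pixels it displays.

It is aimed at people building or serving image atlases: curators who need
indexed, possibly overlapping anatomical region overlays; developers of
browser-based section viewers; and anyone who must slice volumes that do not
fit in memory.

## The model

**Domains and values are separate.** The spatial domain of an image object is
an arbitrary point-set of voxel space, run-length coded as per-line column
*intervals* stacked per line and per plane. Values (8/16/32-bit grey, float,
or RGBA) exist only for in-domain voxels. Binary set operations reduce to
ordered interval merges; background is never stored. A *compound object* is
an indexed list of such objects in one coordinate frame — members may overlap
and the index is unbounded, unlike 8-bit label images.

**Sectioning is one affine map.** A view is the fixed point **f**, angles
*pitch*, *yaw*, *roll* (degrees), *scale* s and plane distance d:

    v' = s · Rz(roll) · Ry(pitch) · Rz(yaw) · (v − f),   section plane: z' = d

Viewing modes remove free parameters for navigation: *statue* (roll = 0),
*up-is-up* (roll chosen so a reference up vector is vertical on screen),
*fixed-line* (a line through two fixed points stays in the plane) and
*absolute*. Each output pixel is inverse-mapped through this transform and
sampled nearest-neighbour (trilinear optional).

**Delivery is tiled.** A section frame is decomposed into fixed-size tiles
across power-of-two resolution levels and served over `CMD=value` query
strings (`WLZ`, `PIT`/`YAW`/`ROL`/`DST`/`FXP`/`SCL`/`MOD`, `SEL`,
`JTL`/`PTL`/`TIL`/`CVT`, `OBJ` …), with PNG (alpha marks out-of-domain
pixels), JPEG and raw encodings, object queries (`Wlz-grey-value`,
`Wlz-volume`, `Wlz-foreground-objects`, …), three LRU caches (tiles, opened
objects, view transforms) and substring proxy routing.

**Larger-than-memory volumes** live in a chunked block store (`.vxb`): values
in fixed-size cuboidal blocks, byte-aligned to the filesystem block size and
reached through a lookup table, so a section read touches only the blocks its
plane crosses. The domain is always loaded eagerly; blocks wholly outside
the domain are absent from the file.

## Worked example

```python
import numpy as np
from voxtile import ViewSpec, cut_section, ServiceConfig, TileService
from voxtile.phantoms import make_gradient_volume
from voxtile.store import write_store, open_store

vol = make_gradient_volume((100, 100, 100), kind="u16")  # value = k + 10 l + 100 p
write_store(vol, "gradient.vxb")                          # chunked 32^3-block store

lazy = open_store("gradient.vxb")
lazy.reset_block_counter()
sec = cut_section(lazy, ViewSpec(fixed=(50, 50, 50), pitch=30, yaw=45, dist=2))
print(sec.pixels.shape, lazy.blocks_touched, lazy.n_blocks_present)

svc = TileService(ServiceConfig(root="."))
print(svc.handle("WLZ=/gradient.vxb&PAB=3,4,5&OBJ=Wlz-grey-value")[2].decode())
```

prints

```
(143, 173) 26 64
Wlz-grey-value:543

```

i.e. the oblique 30°/45° section spans 143×173 px and needed 26 of the 64
stored blocks, while the axis-aligned grey query returns the phantom's
closed-form value 3 + 10·4 + 100·5 = 543. The same pipeline runs from the
shell: `voxtile cut gradient.vxb sec.png --pitch 30 --yaw 45 --dist 2`, and
`voxtile serve --root .` exposes `GET /iip3d?<query>` over HTTP.

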