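# Methods

This note records the model, the numerical conventions and the design
decisions behind `voxtile`, and what the synthetic test substrate does and
does not establish about real data.

## Interval-coded domains

A 3D domain is a planewise stack of 2D domains; a 2D domain holds, per
line, a sorted list of disjoint, maximally merged column runs (*intervals*).
Coordinates are integers named k (column), l (line), p (plane), may be
negative, and every bound is inclusive on both ends — there are no half-open
ranges anywhere in the domain model. Planes with no voxels inside the plane
bounds are explicit absences and iteration skips them.

Normalization (tight bounding box, maximal merge) is an invariant of every
constructor and set operation, which makes structural equality coincide with
point-set equality. Union, intersection and difference are per-line
interval merges; neither operand is densified, so storage and set-operation
cost scale with the number of intervals, never with the bounding-box volume
(a diagonal of n voxels costs n intervals, not n³ cells).

Membership testing is vectorized through a flattened interval table built
lazily per domain: each interval is coded as `line_id · K + k_first` into a
single sorted array, so a batch of query points is one `searchsorted` plus
two comparisons.

## Volumes and value tables

A volume pairs a domain with an optional value table (u8/u16/u32/f32 grey or
8-bit RGBA) and a strictly positive physical voxel size `(sx, sy, sz)`.
Values are held dense over the tight bounding box in plane-major order
(`[p, l, k]`), which keeps axis-aligned plane reads contiguous; the domain
alone decides which cells are meaningful. Out-of-domain lookups return the
per-volume background (default 0, transparent for RGBA) through the bulk
path, and an explicit `OUTSIDE` sentinel through the point-query path so the
service layer can render "no data" distinctly from "value 0". Reported
volume statistics expose both the voxel count and the physical volume
(count · sx·sy·sz); the wire protocol's `Wlz-volume` reply carries the voxel
count, a deliberate choice flagged for callers since either reading is
defensible.

A compound object is an ordered list of member volumes in one global frame.
Overlap is permitted and the member index is an ordinary integer — nothing
ties it to the bit depth of any raster, so 300-member objects behave exactly
like 3-member ones.

## Viewing geometry

The sectioning transform is fixed, in degrees, as

    v' = s · Rz(roll) · Ry(pitch) · Rz(yaw) · (v − f)

with right-handed axes x = column, y = line (growing down-screen, so
screen-up is −y), z = plane, and the elementary rotations

    Rz(t) = [[ c,  s, 0], [−s, c, 0], [0, 0, 1]]
    Ry(t) = [[ c, 0, −s], [0, 1,  0], [s, 0, c]]

The section plane is z' = d and its normal in object space is
Rᵀ(0,0,1) = (sin p cos y, sin p sin y, cos p) — independent of roll, which
only spins the in-plane axes. Angles normalize to (−180°, 180°].

Mode resolution:

* **statue** — roll := 0. With non-zero pitch, varying yaw visibly rotates
  the section image, which is the intended navigation feel.
* **up-is-up** — Rz(roll) turns in-plane vectors by −roll, so the unique
  roll sending the projected up vector (default (0,0,−1)) to screen-up is
  `atan2(u'_y, u'_x) + 90°`. The up vector parallel to the view axis (within
  1e-9 of zero in-plane magnitude) is a degeneracy error, not a silent
  fallback.
* **fixed-line** — the plane normal must be perpendicular to the line
  through the two fixed points; the remaining degree of freedom
  (`line_angle`) selects the normal within that perpendicular plane via a
  deterministic orthonormal basis. Pitch/yaw follow from the normal, roll is
  chosen so the line's on-screen image is independent of `line_angle`, and
  the distance is pinned to 0 so both points actually lie on the plane. The
  exact parametrization of this mode was genuinely open; this construction
  is our choice and is asserted by its invariants (both points on-plane to
  1e-6; line image constant across the angle sweep).

The section frame (raster size and x/y offsets) comes from transforming the
eight corners of the *full* 3D bounding box, not the current plane's
intersection polygon: offsets are `floor(min)`, the size spans to
`ceil(max)` inclusive. The frame is therefore independent of d, so tile
indices stay put while the user scrolls the plane distance — the price is
that very oblique views carry some all-outside margin, which encodes as
fully transparent pixels.

## Sectioning and the resolution pyramid

Each level-0 output pixel (x, y) inverse-maps the view-frame point
`(x + x_off, y + y_off, d)` to a continuous object point and samples
nearest-neighbour: `floor(v + 0.5)` per axis, ties toward +∞, stated once
here and mirrored verbatim by the per-pixel oracle in the tests. Trilinear
sampling is an opt-in for scalar kinds; domain/label sections are always
nearest-neighbour because interpolating membership is meaningless.

Level L is implemented as the level-0 cut of the same region aggregated
over 2^L × 2^L blocks — the mean of the *in-domain* pixels of each block
(so background never bleeds into the object), any-true for the inside mask,
round-half-up once per halving for integer kinds. Cutting directly at
level L and box-downscaling a level-0 cut therefore agree to within one
grey level (one rounding per halving versus one overall), and tile mosaics
reassemble the full section bit-exactly at every level because block
boundaries align with tile origins.

## Overlays

A SEL entry is `(index, r, g, b, a)` with simplified arities 1, 2 and 4 and
255 for every omitted channel. The two-argument form is read as
`(index, alpha)`: colour already defaults to white and per-layer opacity is
the control a curator actually reaches for; this is a declared dialect
choice, as is failing loudly (protocol error) on an out-of-range member
index rather than skipping it. Domain members paint with the entry colour;
value-bearing members are filtered channelwise with integer floor
arithmetic (`g·c/255`; wider grey kinds range-compress to 8 bits first).
Layers merge with source-over in request order, computed in premultiplied
float and quantized round-half-up to 8 bits once at the end, which keeps
the fold associative to a single final rounding and makes
overlapping-region blends order-dependent exactly as intended.

## Tile protocol and caching

Transport is plain HTTP GET with `&`-separated `CMD=value` pairs; token
spellings (`WLZ`, `PIT`, `YAW`, `ROL`, `DST`, `FXP`, `SCL`, `MOD`, `UPV`,
`SEL`, `JTL`/`PTL`/`TIL`, `CVT`, `LEV`, `QLT`, `OBJ`, `PRT`, `PAB`, plus
`FXT`/`LNA` for the second fixed point and line angle) are this package's
declared dialect. `PRT` is an in-tile pixel position when a tile command
gives context, otherwise an absolute level-0 section position. Replies to
object queries are single `Name:value` lines with space-separated values
and a trailing newline; an out-of-domain grey query answers the literal
token `outside`. The bounding-box reply orders plane, line, column first
corner then last corner.

Responses are a pure function of resource bytes, query string and
configuration: tile size (default 256×256), JPEG quality and PNG settings
are pinned in the configuration, so the three LRU caches — encoded tiles
keyed by (resource, resolved-view digest, SEL digest, level, index, format,
quality), opened objects by path, view transforms by view digest — can
never change an answer, only its cost. View digests hash the resolved
parameters at full float precision, so an epsilon perturbation of one angle
is a genuine cache miss. Resource paths resolve strictly under a configured
root; traversal outside it is rejected. Substring routing (first matching
rule wins, else the default backend) operates on the raw query string and
is transport-agnostic.

## Block store

The `.vxb` container is deliberately simple: little-endian header, the
domain as interval runs, a dense 3D lookup table of block slots (−1 =
absent), then fixed-size blocks. Block byte size must be an integer
multiple of the filesystem block size (default 4096; violations raise with
aligned suggestions), so every block read is aligned. Defaults per kind
satisfy the rule (32³ for scalar kinds, 32×32×8 for RGBA). Edge blocks are
stored full-size padded with background — fixed-size blocks keep offsets
computable without per-block size fields. Blocks wholly outside the domain
occupy zero data bytes. After background removal during conversion the
header keeps the original full box (block addressing stays anchored there)
while the domain carries the tight extent.

Opening a store loads header, domain and LUT eagerly and fetches value
blocks on demand through a small in-memory LRU; an instrumented counter of
distinct blocks touched per operation turns the locality contract into a
testable assertion (a single voxel read touches 1 block; an axis-aligned
plane of a 100³/32³ store touches at most the 16 blocks of one LUT layer).
The lazy volume implements the same interface as the in-memory one, and the
equivalence is asserted bit-exactly across the test matrix. No performance
claims are made — only these locality contracts. Conversion from TIFF
stacks or NIfTI streams one block-slab of planes at a time, so peak memory
is bounded by a slab regardless of input size.

## Synthetic phantoms

All test substrate is generated: a gradient volume with value
`k + 10·l + 100·p` (coefficients chosen so any single transposed axis or
off-by-one flips affected pixels), a digital ball with distance-coded grey,
an RGBA phantom with one coordinate ramp per channel, compound objects of
cubes with exact controlled pairwise overlap, and seeded random voxel sets
for the set-algebra oracles. Phantoms are byte-deterministic given their
parameters.

These phantoms have closed-form answers everywhere, which is what makes
bit-exact oracle testing possible; they do not exhibit histology texture,
anisotropic noise, registration artefacts or non-trivial intensity
distributions. Passing tests therefore establish the geometric and
representational correctness of the pipeline — sampling, set algebra,
compositing arithmetic, storage round trips, protocol determinism — not the
perceptual quality of resampled real histology, nor any throughput figure.

## Problem sizes and other choices

Tests and the acceptance script run at desk scale: volumes up to 100³
(plus a 700×400×3 slab for the tile-grid check), 20 random views against
the per-pixel oracle, 1000 geometric round-trip cases, 100 random domain
pairs. Storage planning arithmetic uses binary units throughout (GiB,
MiB/s). The HTTP layer is the standard-library threaded server; the FCGI
deployment style of production atlas servers is infrastructure, not
semantics, and is out of scope, as are blend modes other than source-over,
perspective or curved sections, thick-slab projections, in-block
compression and authentication.

Known limitations: value tables are dense over the bounding box (the domain
still suppresses background semantically, but a sparse domain inside a huge
box should go through the block store); `convert` keeps per-plane interval
lists for the whole domain in memory (fine up to millions of intervals);
wider-than-8-bit grey encodes to PNG/JPEG by range compression (u16 ≫ 8,
u32 ≫ 24, f32 clipped to [0,1]) — the raw tile format preserves native
precision.
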