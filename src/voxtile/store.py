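"""Chunked on-disk volume store with lazy block reads.

Grey (or colour) values are kept in fixed-size cuboidal blocks reached
through a 3D lookup table, so a section read touches only the blocks
its plane actually crosses and a larger-than-memory volume never has to
be loaded whole.  The domain — small even for huge volumes — is always
read eagerly; values are fetched block by block on demand.

Block byte sizes must be an integer multiple of the filesystem block
size (default 4096 bytes), which keeps every block read aligned.
Blocks wholly outside the domain are simply absent from the file.

On-disk layout (little-endian throughout)::

    magic "VXBLSTO1" | header | domain intervals | block LUT | pad | blocks

    header: version u16, kind 4s, fs_block u32, block shape (bk,bl,bp) 3xu32,
            bbox (k1,l1,p1,k2,l2,p2) 6xi64, voxel size 3xf64,
            background 8s, n_intervals u64, LUT dims (nbk,nbl,nbp) 3xu32,
            data_offset u64
    intervals: n_intervals x (p,l,k_first,k_last) 4xi64
    LUT: nbp*nbl*nbk x i64 slot numbers in [p,l,k]-major order, -1 = absent
    blocks: slot s at data_offset + s*block_bytes, content [p,l,k(,channel)]
            C-order, edge blocks padded with background
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .domain import IntervalDomain3D
from .errors import BlockShapeError, FormatError
from .volume import VALUE_KINDS, VoxelVolume, default_background

__all__ = [
    "DEFAULT_FS_BLOCK",
    "default_block_shape",
    "suggest_block_shapes",
    "write_store",
    "open_store",
    "BlockStoreVolume",
    "convert",
]

MAGIC = b"VXBLSTO1"
VERSION = 1
DEFAULT_FS_BLOCK = 4096
_HEADER_FMT = "<8sH4sI3I6q3d8sQ3IQ"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT)

_DEFAULT_SHAPES = {
    "u8": (32, 32, 32),
    "u16": (32, 32, 32),
    "u32": (32, 32, 32),
    "f32": (32, 32, 32),
    "rgba": (32, 32, 8),
}


def _block_bytes(kind: str, shape: tuple[int, int, int]) -> int:
    dtype, channels = VALUE_KINDS[kind]
    bk, bl, bp = shape
    return bk * bl * bp * channels * dtype.itemsize


def default_block_shape(kind: str) -> tuple[int, int, int]:
    """Per-kind default satisfying the filesystem-block multiple rule."""
    return _DEFAULT_SHAPES[kind]


def suggest_block_shapes(kind: str, fs_block: int = DEFAULT_FS_BLOCK) -> list[tuple[int, int, int]]:
    """A few aligned block shapes for error messages and planning."""
    out = []
    for side in (16, 32, 64):
        for bp in (4, 8, 16, 32):
            shape = (side, side, bp)
            if _block_bytes(kind, shape) % fs_block == 0:
                out.append(shape)
    return out[:4]


def _check_block_shape(kind: str, shape: tuple[int, int, int], fs_block: int) -> None:
    if any(s <= 0 for s in shape):
        raise BlockShapeError(f"block shape {shape} must be positive")
    nbytes = _block_bytes(kind, shape)
    if nbytes % fs_block:
        raise BlockShapeError(
            f"block shape {shape} gives {nbytes} bytes per block, not a multiple of the "
            f"filesystem block ({fs_block}); aligned choices for {kind}: "
            f"{suggest_block_shapes(kind, fs_block)}"
        )


def _pack_background(kind: str, background) -> bytes:
    if kind == "rgba":
        return bytes(int(c) for c in background) + b"\0" * 4
    return struct.pack("<d", float(background))


def _unpack_background(kind: str, raw: bytes):
    if kind == "rgba":
        return tuple(raw[:4])
    v = struct.unpack("<d", raw)[0]
    return v if kind == "f32" else int(v)


def _align(offset: int, granule: int) -> int:
    return ((offset + granule - 1) // granule) * granule


def _present_blocks(domain: IntervalDomain3D, bbox, shape) -> np.ndarray:
    """Boolean LUT-shaped grid: block intersects the domain."""
    k1, l1, p1, k2, l2, p2 = bbox
    bk, bl, bp = shape
    dims = (
        -(-(p2 - p1 + 1) // bp),
        -(-(l2 - l1 + 1) // bl),
        -(-(k2 - k1 + 1) // bk),
    )
    present = np.zeros(dims, dtype=bool)
    for p, l, ka, kb in domain.interval_tuples():
        ip = (p - p1) // bp
        il = (l - l1) // bl
        present[ip, il, (ka - k1) // bk : (kb - k1) // bk + 1] = True
    return present


class _Writer:
    """Incremental store writer; feed blocks, then finish with the domain."""

    def __init__(self, path: str | Path, kind: str, voxel_size, background,
                 bbox, block_shape, fs_block: int):
        _check_block_shape(kind, block_shape, fs_block)
        self.path = Path(path)
        self.kind = kind
        self.voxel_size = voxel_size
        self.background = background if background is not None else default_background(kind)
        self.bbox = bbox
        self.block_shape = block_shape
        self.fs_block = fs_block
        self.block_bytes = _block_bytes(kind, block_shape)
        k1, l1, p1, k2, l2, p2 = bbox
        bk, bl, bp = block_shape
        self.lut_dims = (
            -(-(k2 - k1 + 1) // bk),
            -(-(l2 - l1 + 1) // bl),
            -(-(p2 - p1 + 1) // bp),
        )  # (nbk, nbl, nbp)
        nbk, nbl, nbp = self.lut_dims
        self.lut = np.full((nbp, nbl, nbk), -1, dtype=np.int64)
        self._tmp = self.path.with_suffix(self.path.suffix + ".part")
        self._data = open(self._tmp, "wb")
        self._next_slot = 0

    def put_block(self, ip: int, il: int, ik: int, data: np.ndarray) -> None:
        dtype, _ = VALUE_KINDS[self.kind]
        raw = np.ascontiguousarray(data, dtype=dtype).tobytes()
        if len(raw) != self.block_bytes:
            raise ValueError(f"block has {len(raw)} bytes, expected {self.block_bytes}")
        self.lut[ip, il, ik] = self._next_slot
        self._data.write(raw)
        self._next_slot += 1

    def finish(self, domain: IntervalDomain3D) -> Path:
        self._data.close()
        intervals = np.array(list(domain.interval_tuples()), dtype=np.int64).reshape(-1, 4)
        nbk, nbl, nbp = self.lut_dims
        lut_offset = _HEADER_SIZE + intervals.nbytes
        data_offset = _align(lut_offset + self.lut.nbytes, self.fs_block)
        header = struct.pack(
            _HEADER_FMT, MAGIC, VERSION, self.kind.encode().ljust(4), self.fs_block,
            *self.block_shape, *self.bbox, *self.voxel_size,
            _pack_background(self.kind, self.background),
            intervals.shape[0], nbk, nbl, nbp, data_offset,
        )
        with open(self.path, "wb") as f:
            f.write(header)
            f.write(intervals.tobytes())
            f.write(self.lut.tobytes())
            f.write(b"\0" * (data_offset - f.tell()))
            with open(self._tmp, "rb") as data:
                while chunk := data.read(1 << 20):
                    f.write(chunk)
        self._tmp.unlink()
        return self.path


def write_store(
    vol: VoxelVolume,
    path: str | Path,
    block_shape: tuple[int, int, int] | None = None,
    fs_block: int = DEFAULT_FS_BLOCK,
) -> Path:
    """Write a value-bearing volume as a block store file.

    The round trip through :func:`open_store` is exact on every
    in-domain voxel; blocks wholly outside the domain occupy no data
    bytes at all.
    """
    if not vol.has_values:
        raise FormatError("cannot store a domain-only object")
    kind = vol.kind
    shape = block_shape if block_shape is not None else default_block_shape(kind)
    bbox = vol.bounding_box()
    writer = _Writer(path, kind, vol.voxel_size, vol.background, bbox, shape, fs_block)
    present = _present_blocks(vol.domain, bbox, shape)
    k1, l1, p1, k2, l2, p2 = bbox
    bk, bl, bp = shape
    dtype, channels = VALUE_KINDS[kind]
    bg = np.asarray(vol.background, dtype=dtype)
    for ip, il, ik in np.argwhere(present):
        pk = k1 + ik * bk
        pl = l1 + il * bl
        pp = p1 + ip * bp
        gp, gl, gk = np.meshgrid(
            np.arange(pp, pp + bp), np.arange(pl, pl + bl), np.arange(pk, pk + bk),
            indexing="ij",
        )
        block = vol.read_values(gk, gl, gp)
        inside = vol.domain.contains_points(gk, gl, gp)
        block[~inside] = bg
        writer.put_block(ip, il, ik, block)
    return writer.finish(vol.domain)


class _LRU:
    """Minimal ordered-dict LRU used for in-memory block caching."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self._d: dict = {}

    def get(self, key):
        if key not in self._d:
            return None
        val = self._d.pop(key)
        self._d[key] = val
        return val

    def put(self, key, val):
        if key in self._d:
            self._d.pop(key)
        self._d[key] = val
        while len(self._d) > self.capacity:
            self._d.pop(next(iter(self._d)))


class BlockStoreVolume(VoxelVolume):
    """A volume whose values live on disk in a block store.

    Presents the exact in-memory :class:`VoxelVolume` interface —
    sections, point queries and statistics give identical answers — but
    fetches value blocks only when touched.  ``blocks_touched`` counts
    the distinct blocks any operations have needed since the last
    :meth:`reset_block_counter`, which makes the read-locality contract
    testable.
    """

    def __init__(self, path: str | Path, cache_blocks: int = 64):
        path = Path(path)
        with open(path, "rb") as f:
            head = f.read(_HEADER_SIZE)
            if len(head) < _HEADER_SIZE:
                raise FormatError(f"{path}: truncated header at offset {len(head)}")
            (magic, version, kind_raw, fs_block, bk, bl, bp,
             k1, l1, p1, k2, l2, p2, sx, sy, sz, bg_raw,
             n_ivl, nbk, nbl, nbp, data_offset) = struct.unpack(_HEADER_FMT, head)
            if magic != MAGIC:
                raise FormatError(f"{path}: bad magic at offset 0: {magic!r}")
            if version != VERSION:
                raise FormatError(f"{path}: unsupported version {version}")
            kind = kind_raw.decode().strip()
            if kind not in VALUE_KINDS:
                raise FormatError(f"{path}: unknown value kind {kind!r}")
            ivl_bytes = f.read(n_ivl * 32)
            if len(ivl_bytes) != n_ivl * 32:
                raise FormatError(f"{path}: truncated interval table at offset {_HEADER_SIZE}")
            intervals = np.frombuffer(ivl_bytes, dtype=np.int64).reshape(-1, 4)
            lut_n = nbk * nbl * nbp
            lut_bytes = f.read(lut_n * 8)
            if len(lut_bytes) != lut_n * 8:
                raise FormatError(f"{path}: truncated LUT at offset {_HEADER_SIZE + n_ivl * 32}")
            lut = np.frombuffer(lut_bytes, dtype=np.int64).reshape(nbp, nbl, nbk)
        domain = IntervalDomain3D.from_intervals(map(tuple, intervals.tolist()))
        if not domain.is_empty:
            dk1, dl1, dp1, dk2, dl2, dp2 = domain.bbox
            if dk1 < k1 or dl1 < l1 or dp1 < p1 or dk2 > k2 or dl2 > l2 or dp2 > p2:
                raise FormatError(f"{path}: domain extends outside the header bounding box")
        super().__init__(domain, None, kind=kind,
                         background=_unpack_background(kind, bg_raw),
                         voxel_size=(sx, sy, sz))
        self.path = path
        # block addressing is anchored at the header bbox, which may be
        # looser than the tight domain bbox (e.g. after background removal)
        self.store_bbox = (k1, l1, p1, k2, l2, p2)
        self.block_shape = (bk, bl, bp)
        self.fs_block = fs_block
        self.lut = lut
        self.data_offset = data_offset
        self.block_bytes = _block_bytes(kind, self.block_shape)
        if lut.max(initial=-1) >= 0:
            end = data_offset + (int(lut.max()) + 1) * self.block_bytes
            if path.stat().st_size < end:
                raise FormatError(f"{path}: data region truncated before offset {end}")
        self._cache = _LRU(cache_blocks)
        self._touched: set[tuple[int, int, int]] = set()
        self.blocks_loaded = 0

    # -- instrumentation ----------------------------------------------------

    def reset_block_counter(self) -> None:
        self._touched = set()

    @property
    def blocks_touched(self) -> int:
        """Distinct blocks needed by operations since the last reset."""
        return len(self._touched)

    @property
    def n_blocks_present(self) -> int:
        return int((self.lut >= 0).sum())

    # -- value access -------------------------------------------------------

    @property
    def has_values(self) -> bool:
        return True

    def _load_block(self, ip: int, il: int, ik: int) -> np.ndarray:
        key = (ip, il, ik)
        self._touched.add(key)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        dtype, channels = VALUE_KINDS[self.kind]
        bk, bl, bp = self.block_shape
        shape = (bp, bl, bk) + ((channels,) if channels > 1 else ())
        slot = int(self.lut[ip, il, ik])
        if slot < 0:
            block = np.empty(shape, dtype=dtype)
            block[...] = np.asarray(self.background, dtype=dtype)
        else:
            with open(self.path, "rb") as f:
                f.seek(self.data_offset + slot * self.block_bytes)
                raw = f.read(self.block_bytes)
            block = np.frombuffer(raw, dtype=dtype).reshape(shape)
            self.blocks_loaded += 1
        self._cache.put(key, block)
        return block

    def read_values(self, kk: np.ndarray, ll: np.ndarray, pp: np.ndarray) -> np.ndarray:
        k1, l1, p1, k2, l2, p2 = self.store_bbox
        bk, bl, bp = self.block_shape
        dtype, channels = VALUE_KINDS[self.kind]
        kk = np.asarray(kk, dtype=np.int64)
        ll = np.asarray(ll, dtype=np.int64)
        pp = np.asarray(pp, dtype=np.int64)
        shape = kk.shape + ((channels,) if channels > 1 else ())
        out = np.empty(shape, dtype=dtype)
        out[...] = np.asarray(self.background, dtype=dtype)
        inb = (kk >= k1) & (kk <= k2) & (ll >= l1) & (ll <= l2) & (pp >= p1) & (pp <= p2)
        if not inb.any():
            return out
        fk, fl, fp = kk[inb] - k1, ll[inb] - l1, pp[inb] - p1
        bik, bil, bip = fk // bk, fl // bl, fp // bp
        gathered = np.empty((fk.size,) + ((channels,) if channels > 1 else ()), dtype=dtype)
        codes = (bip * self.lut.shape[1] + bil) * self.lut.shape[2] + bik
        for code in np.unique(codes):
            sel = codes == code
            ip = int(code // (self.lut.shape[1] * self.lut.shape[2]))
            rem = int(code % (self.lut.shape[1] * self.lut.shape[2]))
            il, ik = rem // self.lut.shape[2], rem % self.lut.shape[2]
            block = self._load_block(ip, il, ik)
            gathered[sel] = block[fp[sel] - ip * bp, fl[sel] - il * bl, fk[sel] - ik * bk]
        out[inb] = gathered
        return out


def open_store(path: str | Path, cache_blocks: int = 64) -> BlockStoreVolume:
    """Open a block store as a lazily-read volume."""
    return BlockStoreVolume(path, cache_blocks=cache_blocks)


def convert(
    input_path: str | Path,
    output_path: str | Path,
    block_shape: tuple[int, int, int] | None = None,
    background=None,
    voxel_size: tuple[float, float, float] | None = None,
    fs_block: int = DEFAULT_FS_BLOCK,
) -> Path:
    """Convert a TIFF stack directory or NIfTI file into a block store.

    Planes are streamed one block-slab at a time, so peak memory is
    bounded by one slab regardless of volume size.  When ``background``
    is given, voxels equal to it are excluded from the domain (and
    blocks with no remaining foreground are dropped); otherwise the
    domain is the full box.
    """
    input_path = Path(input_path)
    planes, n_planes, plane_shape, kind, file_voxel = _plane_reader(input_path)
    if voxel_size is None:
        voxel_size = file_voxel
    shape = block_shape if block_shape is not None else default_block_shape(kind)
    bk, bl, bp = shape
    n_l, n_k = plane_shape
    bbox = (0, 0, 0, n_k - 1, n_l - 1, n_planes - 1)
    bg = background if background is not None else default_background(kind)
    writer = _Writer(output_path, kind, voxel_size, bg, bbox, shape, fs_block)
    dtype, channels = VALUE_KINDS[kind]
    all_intervals: list[tuple[int, int, int, int]] = []
    nbk, nbl, _ = writer.lut_dims
    pad_l = _align(n_l, bl)
    pad_k = _align(n_k, bk)
    for p0 in range(0, n_planes, bp):
        slab_planes = []
        slab_masks = []
        for p in range(p0, min(p0 + bp, n_planes)):
            arr = planes(p)
            if arr.shape[:2] != plane_shape:
                raise FormatError(f"plane {p} has shape {arr.shape[:2]}, expected {plane_shape}")
            if background is not None:
                if channels > 1:
                    mask = (arr != np.asarray(background, dtype=dtype)).any(axis=-1)
                else:
                    mask = arr != background
            else:
                mask = np.ones(plane_shape, dtype=bool)
            dom2d = IntervalDomain3D.from_mask(mask[None], (0, 0, p))
            all_intervals.extend(dom2d.interval_tuples())
            slab_planes.append(arr)
            slab_masks.append(mask)
        slab = np.zeros((bp, pad_l, pad_k) + ((channels,) if channels > 1 else ()), dtype=dtype)
        slab[...] = np.asarray(bg, dtype=dtype)
        smask = np.zeros((bp, pad_l, pad_k), dtype=bool)
        for i, (arr, mask) in enumerate(zip(slab_planes, slab_masks)):
            slab[i, :n_l, :n_k] = arr
            smask[i, :n_l, :n_k] = mask
        slab[~smask] = np.asarray(bg, dtype=dtype)
        ip = p0 // bp
        for il in range(nbl):
            for ik in range(nbk):
                sub_mask = smask[:, il * bl : (il + 1) * bl, ik * bk : (ik + 1) * bk]
                if not sub_mask.any():
                    continue
                writer.put_block(ip, il, ik,
                                 slab[:, il * bl : (il + 1) * bl, ik * bk : (ik + 1) * bk])
    domain = IntervalDomain3D.from_intervals(all_intervals)
    if domain.is_empty:
        writer._data.close()
        writer._tmp.unlink(missing_ok=True)
        raise FormatError(f"{input_path}: no foreground voxels after background removal")
    # the header bbox stays the full input box: blocks are addressed from its
    # origin even when background removal leaves a tighter domain
    return writer.finish(domain)


def _plane_reader(input_path: Path):
    """Uniform per-plane access for TIFF stacks and NIfTI volumes."""
    import nibabel as nib
    import tifffile

    from .volume import kind_of_dtype

    if input_path.is_dir():
        files = sorted(p for p in input_path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FormatError(f"no TIFF planes found in {input_path}")
        first = tifffile.imread(files[0])
        kind = "rgba" if (first.ndim == 3 and first.shape[-1] == 4) else kind_of_dtype(first.dtype)

        def planes(p: int) -> np.ndarray:
            return tifffile.imread(files[p])

        return planes, len(files), first.shape[:2], kind, (1.0, 1.0, 1.0)

    img = nib.load(str(input_path))
    shape = img.shape
    if len(shape) not in (3, 4):
        raise FormatError(f"unsupported NIfTI dimensionality {len(shape)}")
    zooms = img.header.get_zooms()[:3]
    voxel = tuple(float(z) if z > 0 else 1.0 for z in zooms)
    dtype = img.get_data_dtype()
    kind = "rgba" if (len(shape) == 4 and shape[3] == 4) else kind_of_dtype(np.dtype(dtype))

    def planes(p: int) -> np.ndarray:
        sl = np.asanyarray(img.dataobj[:, :, p])  # (i, j) = (k, l)
        return np.ascontiguousarray(np.moveaxis(sl, 0, 1))  # -> (l, k[, c])

    return planes, shape[2], (shape[1], shape[0]), kind, voxel
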