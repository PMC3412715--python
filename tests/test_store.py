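"""Block store: round trips, alignment rule, lazy-read locality."""

import numpy as np
import pytest

from voxtile.domain import IntervalDomain3D
from voxtile.errors import BlockShapeError, FormatError
from voxtile.geometry import ViewSpec, build_transform
from voxtile.phantoms import make_gradient_volume, make_rgb_phantom, make_sphere_phantom
from voxtile.section import cut_section
from voxtile.store import (convert, default_block_shape, open_store,
                           suggest_block_shapes, write_store)
from voxtile.volume import VALUE_KINDS, OUTSIDE, VoxelVolume


@pytest.fixture(scope="module")
def gradient_store(tmp_path_factory):
    vol = make_gradient_volume((100, 100, 100), kind="u16")
    path = tmp_path_factory.mktemp("store") / "gradient.vxb"
    write_store(vol, path)
    return vol, path


class TestAlignmentRule:
    def test_default_shapes_are_fs_block_multiples(self):
        for kind in VALUE_KINDS:
            bk, bl, bp = default_block_shape(kind)
            dtype, ch = VALUE_KINDS[kind]
            assert (bk * bl * bp * ch * dtype.itemsize) % 4096 == 0

    def test_misaligned_shape_rejected_with_suggestions(self):
        vol = make_gradient_volume((10, 10, 10), kind="u8")
        with pytest.raises(BlockShapeError, match="aligned choices"):
            write_store(vol, "/tmp/never-written.vxb", block_shape=(10, 10, 10))
        assert suggest_block_shapes("u8")  # non-empty advice

    def test_lut_dimensions_ceil(self, gradient_store):
        _, path = gradient_store
        lazy = open_store(path)
        assert lazy.lut.shape == (4, 4, 4)  # ceil(100/32) per axis
        assert lazy.n_blocks_present == 64


class TestRoundTrip:
    @pytest.mark.parametrize("kind", ["u8", "u16", "u32", "f32", "rgba"])
    def test_random_volumes_round_trip_exact(self, kind, tmp_path):
        rng = np.random.default_rng(hash(kind) % 2**31)
        dtype, ch = VALUE_KINDS[kind]
        shape = (20, 33, 41) + ((4,) if ch == 4 else ())
        if dtype.kind == "f":
            data = rng.random(shape, dtype=np.float32)
        else:
            data = rng.integers(0, np.iinfo(dtype).max, shape, endpoint=True).astype(dtype)
        mask = rng.random((20, 33, 41)) < 0.6
        mask[0, 0, 0] = mask[-1, -1, -1] = True  # keep bbox the full box
        dom = IntervalDomain3D.from_mask(mask)
        vol = VoxelVolume(dom, data, kind=kind, voxel_size=(0.5, 0.7, 2.0))
        path = tmp_path / f"{kind}.vxb"
        write_store(vol, path)
        lazy = open_store(path)
        assert lazy.kind == kind
        assert lazy.voxel_size == vol.voxel_size
        assert lazy.domain == vol.domain
        pp, ll, kk = np.nonzero(mask)
        assert np.array_equal(lazy.read_values(kk, ll, pp), vol.read_values(kk, ll, pp))

    def test_sphere_store_drops_empty_corner_blocks(self, tmp_path):
        vol = make_sphere_phantom((100, 100, 100), centre=(50, 50, 50), radius=10.0)
        # embed in the full box so corner blocks exist but hold no domain
        full = VoxelVolume(
            vol.domain | IntervalDomain3D.from_intervals([(0, 0, 0, 0), (99, 99, 99, 99)]),
            None)
        path = tmp_path / "sphere.vxb"
        write_store(vol, path, block_shape=(32, 32, 32))
        lazy = open_store(path)
        # sphere bbox is 21^3 -> a single 32^3 block suffices
        assert lazy.n_blocks_present == 1
        assert lazy.voxel_count == vol.voxel_count

    def test_sparse_file_smaller_than_dense(self, tmp_path):
        sparse = make_sphere_phantom((96, 96, 96), centre=(16, 16, 16), radius=10.0)
        # widen bbox to the full box with two far-corner voxels
        dom = sparse.domain | IntervalDomain3D.from_intervals([(95, 95, 95, 95)])
        mask, origin = dom.to_mask()
        vals = np.zeros(mask.shape, np.uint8)
        vol = VoxelVolume(dom, vals, kind="u8")
        path = tmp_path / "sparse.vxb"
        write_store(vol, path, block_shape=(32, 32, 32))
        lazy = open_store(path)
        dense_bytes = 96**3
        assert lazy.n_blocks_present < 27
        assert path.stat().st_size < dense_bytes // 2


class TestLazyLocality:
    def test_single_voxel_touches_one_block(self, gradient_store):
        _, path = gradient_store
        lazy = open_store(path)
        lazy.reset_block_counter()
        assert lazy.value_at((3, 4, 5)) == 543
        assert lazy.blocks_touched == 1

    def test_z_plane_section_touches_one_block_layer(self, gradient_store):
        _, path = gradient_store
        lazy = open_store(path)
        lazy.reset_block_counter()
        cut_section(lazy, ViewSpec(dist=50))
        assert lazy.blocks_touched <= 16  # one 4x4 layer of the 4x4x4 LUT

    def test_blocks_touched_bounded_by_slab_oracle(self, gradient_store):
        vol, path = gradient_store
        view = ViewSpec(fixed=(50, 50, 50), pitch=30, yaw=40, dist=0)
        lazy = open_store(path)
        lazy.reset_block_counter()
        cut_section(lazy, view)
        # independent geometric oracle: LUT cells whose centre-to-plane
        # distance is at most half the block diagonal
        t = build_transform(view)
        normal = t.view_axis
        bk = np.array([32, 32, 32], dtype=float)
        half_diag = float(np.abs(normal) @ bk) / 2.0
        count = 0
        for ip in range(4):
            for il in range(4):
                for ik in range(4):
                    centre = np.array([ik * 32 + 15.5, il * 32 + 15.5, ip * 32 + 15.5])
                    dist_to_plane = abs(t.to_view(centre)[2] - t.dist) / t.scale
                    if dist_to_plane <= half_diag + 1.0:
                        count += 1
        assert lazy.blocks_touched <= count

    def test_absent_block_reads_background(self, tmp_path):
        vol = make_sphere_phantom((64, 64, 64), centre=(16, 16, 16), radius=8.0)
        dom = vol.domain | IntervalDomain3D.from_intervals([(63, 63, 60, 63)])
        mask, origin = dom.to_mask()
        vals = np.full(mask.shape, 5, np.uint8)
        path = tmp_path / "bg.vxb"
        write_store(VoxelVolume(dom, vals, kind="u8", background=7), path)
        lazy = open_store(path)
        # a bbox-interior point in an absent block returns the background
        assert not lazy.domain.contains(40, 40, 40)
        got = lazy.read_values(np.array([40]), np.array([40]), np.array([40]))
        assert got[0] == 7


class TestRepresentationEquivalence:
    def test_sections_queries_identical_lazy_vs_memory(self, gradient_store):
        vol, path = gradient_store
        lazy = open_store(path)
        rng = np.random.default_rng(47)
        views = [ViewSpec(dist=50),
                 ViewSpec(fixed=(50, 50, 50), pitch=30, yaw=60, roll=20, dist=5),
                 ViewSpec(fixed=(50, 50, 50), pitch=75, yaw=-120, scale=1.5)]
        for view in views:
            a = cut_section(vol, view)
            b = cut_section(lazy, view)
            assert np.array_equal(a.pixels, b.pixels)
            assert np.array_equal(a.inside, b.inside)
        for _ in range(50):
            pt = tuple(int(v) for v in rng.integers(-5, 105, 3))
            va, vb = vol.value_at(pt), lazy.value_at(pt)
            assert (va is OUTSIDE and vb is OUTSIDE) or va == vb
        assert vol.voxel_count == lazy.voxel_count
        assert vol.bounding_box() == lazy.bounding_box()


class TestConvert:
    def test_tiff_stack_convert_bbox(self, tmp_path):
        from voxtile.io import write_tiff_stack
        vol = make_gradient_volume((64, 64, 10), kind="u8")
        stack = tmp_path / "stack"
        write_tiff_stack(vol, stack)
        out = convert(stack, tmp_path / "stack.vxb")
        lazy = open_store(out)
        assert lazy.bounding_box() == (0, 0, 0, 63, 63, 9)
        assert lazy.value_at((3, 4, 5)) == (3 + 40 + 500) % 256

    def test_background_threshold_builds_sphere_domain(self, tmp_path):
        from voxtile.io import write_nifti
        sphere = make_sphere_phantom((40, 40, 40), centre=(20, 20, 20), radius=9.0)
        mask, _ = sphere.domain.to_mask()
        dense = np.zeros((40, 40, 40), np.uint8)
        dense[11:30, 11:30, 11:30][mask] = 1 + sphere.values[mask]
        vol = VoxelVolume.from_dense(dense)
        nii = tmp_path / "sphere.nii"
        write_nifti(vol, nii)
        out = convert(nii, tmp_path / "sphere.vxb", background=0)
        lazy = open_store(out)
        assert lazy.voxel_count == sphere.voxel_count
        assert lazy.value_at((20, 20, 20)) == 1

    def test_nifti_voxel_size_propagates(self, tmp_path):
        from voxtile.io import write_nifti
        vol = make_gradient_volume((16, 16, 16), kind="u8", voxel_size=(0.5, 0.25, 2.0))
        nii = tmp_path / "vox.nii"
        write_nifti(vol, nii)
        out = convert(nii, tmp_path / "vox.vxb")
        lazy = open_store(out)
        assert lazy.voxel_size == (0.5, 0.25, 2.0)

    def test_rgba_convert_round_trip(self, tmp_path):
        from voxtile.io import write_tiff_stack
        vol = make_rgb_phantom((40, 40, 12))
        stack = tmp_path / "rgb"
        write_tiff_stack(vol, stack)
        out = convert(stack, tmp_path / "rgb.vxb")
        lazy = open_store(out)
        assert lazy.kind == "rgba"
        assert lazy.value_at((3, 5, 7)) == (3, 5, 7, 255)


class TestCorruptFiles:
    def test_bad_magic_reports_offset(self, tmp_path, gradient_store):
        _, path = gradient_store
        raw = bytearray(path.read_bytes())
        raw[0:4] = b"XXXX"
        bad = tmp_path / "bad.vxb"
        bad.write_bytes(bytes(raw))
        with pytest.raises(FormatError, match="offset 0"):
            open_store(bad)

    def test_truncated_file_detected(self, tmp_path, gradient_store):
        _, path = gradient_store
        bad = tmp_path / "trunc.vxb"
        bad.write_bytes(path.read_bytes()[:100])
        with pytest.raises(FormatError):
            open_store(bad)
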