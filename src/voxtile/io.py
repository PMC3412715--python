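"""Import and export of volumes: TIFF stacks, NIfTI-1, compound manifests.

A *TIFF stack* is a directory with one 2D image per plane; lexicographic
file order is ascending plane number.  NIfTI volumes map array axes
(i, j, k) onto (column k, line l, plane p) and carry the voxel size in
the header zooms.  Compound objects come either from an integer-labelled
volume (each distinct non-zero label becomes one domain-only member —
which cannot express overlap) or from a JSON manifest listing one mask
file per member, which can.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .domain import IntervalDomain3D
from .errors import FormatError
from .volume import CompoundObject, VoxelVolume, kind_of_dtype

__all__ = [
    "read_tiff_stack",
    "write_tiff_stack",
    "read_nifti",
    "write_nifti",
    "compound_from_labels",
    "read_labelled_volume",
    "read_compound_manifest",
    "write_compound_manifest",
]


def _dense_to_volume(arr: np.ndarray, voxel_size, background) -> VoxelVolume:
    if arr.ndim == 4 and arr.shape[-1] == 4:
        kind = "rgba"
    elif arr.ndim == 3:
        kind = kind_of_dtype(arr.dtype)
    else:
        raise FormatError(f"unsupported array shape {arr.shape}")
    return VoxelVolume.from_dense(arr, voxel_size=voxel_size, kind=kind, background=background)


def read_tiff_stack(directory: str | Path, voxel_size=(1.0, 1.0, 1.0), background=None) -> VoxelVolume:
    """Read a one-file-per-plane TIFF directory into a full-box volume."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    if not files:
        raise FormatError(f"no TIFF planes found in {directory}")
    planes = [tifffile.imread(f) for f in files]
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent plane shapes in {directory}: {sorted(shapes)}")
    arr = np.stack(planes, axis=0)  # [p, l, k] (tifffile yields row=line, col=column)
    return _dense_to_volume(arr, voxel_size, background)


def write_tiff_stack(vol: VoxelVolume, directory: str | Path) -> list[Path]:
    """Write the dense bounding-box raster of a volume, one TIFF per plane.

    Out-of-domain cells hold the background value; the rectangular
    format cannot carry the domain or the global offsets.
    """
    if not vol.has_values:
        raise FormatError("cannot export a domain-only object as a TIFF stack")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mask, _ = vol.domain.to_mask()
    dense = np.array(vol.values)
    dense[~mask] = np.asarray(vol.background, dtype=dense.dtype)
    paths = []
    for ip in range(dense.shape[0]):
        path = directory / f"plane_{ip:05d}.tif"
        tifffile.imwrite(path, dense[ip])
        paths.append(path)
    return paths


def read_nifti(path: str | Path, background=None) -> VoxelVolume:
    """Read a NIfTI-1 volume; header zooms become the voxel size."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise FormatError(f"unsupported NIfTI dimensionality {data.ndim}")
    zooms = img.header.get_zooms()[:3]
    voxel_size = tuple(float(z) if z > 0 else 1.0 for z in zooms)
    # NIfTI arrays are (i, j, k) = (column, line, plane): transpose to [p, l, k]
    axes = (2, 1, 0) if data.ndim == 3 else (2, 1, 0, 3)
    return _dense_to_volume(np.ascontiguousarray(data.transpose(axes)), voxel_size, background)


def write_nifti(vol: VoxelVolume, path: str | Path) -> Path:
    """Write the dense bounding-box raster as NIfTI-1 with voxel-size zooms."""
    if not vol.has_values:
        raise FormatError("cannot export a domain-only object as NIfTI")
    mask, _ = vol.domain.to_mask()
    dense = np.array(vol.values)
    dense[~mask] = np.asarray(vol.background, dtype=dense.dtype)
    axes = (2, 1, 0) if dense.ndim == 3 else (2, 1, 0, 3)
    sx, sy, sz = vol.voxel_size
    img = nib.Nifti1Image(dense.transpose(axes), affine=np.diag([sx, sy, sz, 1.0]))
    img.header.set_zooms((sx, sy, sz) + (() if dense.ndim == 3 else (1.0,)))
    nib.save(img, str(path))
    return Path(path)


def compound_from_labels(labels: np.ndarray, origin=(0, 0, 0), voxel_size=(1.0, 1.0, 1.0)) -> CompoundObject:
    """Split an integer-labelled ``[p, l, k]`` grid into domain-only members.

    Distinct non-zero labels in ascending order become members 0, 1, ...;
    a labelled raster cannot express overlapping members.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise FormatError("labelled volume must be a 3D integer grid")
    members = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        dom = IntervalDomain3D.from_mask(labels == lab, origin)
        members.append(VoxelVolume.domain_only(dom, voxel_size=voxel_size))
    return CompoundObject(members)


def read_labelled_volume(path: str | Path) -> CompoundObject:
    """Read an integer-labelled NIfTI or TIFF-stack volume as a compound."""
    path = Path(path)
    if path.is_dir():
        vol = read_tiff_stack(path)
    else:
        vol = read_nifti(path)
    return compound_from_labels(vol.values, voxel_size=vol.voxel_size)


def _read_mask_file(path: Path) -> np.ndarray:
    if path.is_dir():
        return np.asarray(read_tiff_stack(path).values) != 0
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim != 3:
            raise FormatError(f"mask {path} must be a 3D TIFF")
        return arr != 0
    return np.asanyarray(nib.load(str(path)).dataobj).transpose(2, 1, 0) != 0


def read_compound_manifest(path: str | Path) -> CompoundObject:
    """Read a JSON manifest of per-member mask files (overlap-capable).

    Schema::

        {"voxel_size": [sx, sy, sz],
         "members": [{"mask": "relative/path", "origin": [k, l, p]}, ...]}

    Member order in the file is member index order.
    """
    path = Path(path)
    try:
        spec = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"bad manifest {path}: {e}")
    voxel_size = tuple(spec.get("voxel_size", (1.0, 1.0, 1.0)))
    members = []
    for entry in spec.get("members", []):
        mask_path = path.parent / entry["mask"]
        origin = tuple(entry.get("origin", (0, 0, 0)))
        dom = IntervalDomain3D.from_mask(_read_mask_file(mask_path), origin)
        members.append(VoxelVolume.domain_only(dom, voxel_size=voxel_size))
    return CompoundObject(members)


def write_compound_manifest(compound: CompoundObject, directory: str | Path,
                            name: str = "compound.json") -> Path:
    """Write a compound as per-member 3D TIFF masks plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, member in enumerate(compound):
        mask, origin = member.domain.to_mask()
        fname = f"member_{i:05d}.tif"
        tifffile.imwrite(directory / fname, mask.astype(np.uint8))
        entries.append({"mask": fname, "origin": list(origin)})
    manifest = directory / name
    manifest.write_text(json.dumps(
        {"voxel_size": list(compound.voxel_size), "members": entries}, indent=1))
    return manifest
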