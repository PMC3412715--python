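"""Storage and transfer arithmetic for store planning.

Helpers used when deciding whether a volume must go through the chunked
block store rather than RAM: raw value-table size of a dense volume,
binary-unit formatting, and lower-bound sequential read times at a
given disk rate.  All units are binary (KiB = 2**10 ...), matching how
file sizes are reported by the tools of this field.
"""

from __future__ import annotations

from .volume import VALUE_KINDS

__all__ = [
    "storage_bytes",
    "bytes_per_voxel",
    "to_gib",
    "transfer_seconds",
    "transfer_minutes",
]

GIB = 2**30
MIB = 2**20


def bytes_per_voxel(kind: str) -> int:
    """Bytes per voxel for a value kind (e.g. 4 for rgba or u32)."""
    dtype, channels = VALUE_KINDS[kind]
    return dtype.itemsize * channels


def storage_bytes(dims: tuple[int, int, int], kind_or_bpv: str | int = "u8") -> int:
    """Raw dense value-table size of a ``(nk, nl, np)`` volume in bytes."""
    nk, nl, npl = dims
    if nk <= 0 or nl <= 0 or npl <= 0:
        raise ValueError("dims must be positive")
    bpv = kind_or_bpv if isinstance(kind_or_bpv, int) else bytes_per_voxel(kind_or_bpv)
    return nk * nl * npl * bpv


def to_gib(nbytes: int) -> float:
    """Bytes → GiB."""
    return nbytes / GIB


def transfer_seconds(nbytes: float, rate_mib_per_s: float) -> float:
    """Lower-bound sequential read time at a given rate in MiB/s."""
    if rate_mib_per_s <= 0:
        raise ValueError("transfer rate must be positive")
    return nbytes / (rate_mib_per_s * MIB)


def transfer_minutes(nbytes: float, rate_mib_per_s: float) -> float:
    return transfer_seconds(nbytes, rate_mib_per_s) / 60.0
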