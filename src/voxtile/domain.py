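"""Interval-coded 3D spatial domains.

A *domain* is an arbitrary point-set of 3D voxel space, stored as a
planewise stack of 2D domains, each of which holds per-line runs of
in-domain columns (*intervals*).  This run-length representation keeps
storage proportional to the boundary complexity of the region rather
than its bounding box, and reduces binary set operations to ordered
interval merges.

Coordinates are integer and global: ``k`` is the column, ``l`` the line
and ``p`` the plane.  All bounds are inclusive on both ends and may be
negative.  Dense numpy views of a domain are indexed ``[p, l, k]``
(plane-major).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .errors import EmptyObjectError

__all__ = ["Interval", "IntervalDomain3D", "domain_from_mask", "domain_to_mask"]


@dataclass(frozen=True)
class Interval:
    """A maximal run of in-domain columns on one line.

    ``k_first`` and ``k_last`` are inclusive global column coordinates.
    """

    line: int
    k_first: int
    k_last: int

    def __post_init__(self) -> None:
        if self.k_first > self.k_last:
            raise ValueError(f"k_first {self.k_first} > k_last {self.k_last}")

    def __len__(self) -> int:
        return self.k_last - self.k_first + 1


# ---------------------------------------------------------------------------
# interval-list primitives: lists of (k0, k1) tuples, sorted, disjoint and
# maximally merged (no two runs are adjacent)


def _merge_runs(runs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Normalize an arbitrary run list: sort, merge overlaps and adjacency."""
    if not runs:
        return []
    runs = sorted(runs)
    out = [runs[0]]
    for k0, k1 in runs[1:]:
        c0, c1 = out[-1]
        if k0 <= c1 + 1:
            if k1 > c1:
                out[-1] = (c0, k1)
        else:
            out.append((k0, k1))
    return out


def _union_runs(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return _merge_runs(list(a) + list(b))


def _intersect_runs(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _difference_runs(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    j = 0
    for k0, k1 in a:
        cur = k0
        while j < len(b) and b[j][1] < cur:
            j += 1
        jj = j
        while jj < len(b) and b[jj][0] <= k1:
            b0, b1 = b[jj]
            if b0 > cur:
                out.append((cur, b0 - 1))
            cur = max(cur, b1 + 1)
            if cur > k1:
                break
            jj += 1
        if cur <= k1:
            out.append((cur, k1))
    return out


_RUN_OPS = {
    "union": _union_runs,
    "intersect": _intersect_runs,
    "difference": _difference_runs,
}


class IntervalDomain3D:
    """An arbitrary 3D point-set as planewise stacks of per-line intervals.

    Instances are normalized: the bounding box is tight, intervals on a
    line are sorted, disjoint and maximally merged, and planes entirely
    outside the domain between ``p_first`` and ``p_last`` are explicit
    absences.  Equality is structural, which normalization makes
    equivalent to point-set equality.

    Construct via :meth:`from_mask`, :meth:`from_box`,
    :meth:`from_intervals` or the set operations; the raw constructor
    trusts its inputs.
    """

    __slots__ = ("_p_first", "_planes", "_lut", "_bbox", "_count")

    def __init__(self, p_first: int, planes: list) -> None:
        # planes: list over p_first..p_first+len-1 of None or
        # (l_first, rows) where rows is a list of run lists.
        self._p_first = p_first
        self._planes = planes
        self._lut = None
        self._bbox: tuple[int, int, int, int, int, int] | None = None
        self._count: int | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def empty(cls) -> "IntervalDomain3D":
        return cls(0, [])

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[int, int, int, int]]) -> "IntervalDomain3D":
        """Build from an iterable of ``(p, l, k_first, k_last)`` runs."""
        line_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for p, l, k0, k1 in intervals:
            if k0 > k1:
                raise ValueError(f"k_first {k0} > k_last {k1}")
            line_map.setdefault((p, l), []).append((k0, k1))
        for key in line_map:
            line_map[key] = _merge_runs(line_map[key])
        return cls._from_line_map(line_map)

    @classmethod
    def from_box(cls, k0: int, l0: int, p0: int, k1: int, l1: int, p1: int) -> "IntervalDomain3D":
        """A full cuboid with inclusive corners."""
        return cls.from_intervals(
            (p, l, k0, k1) for p in range(p0, p1 + 1) for l in range(l0, l1 + 1)
        )

    @classmethod
    def from_mask(cls, mask: np.ndarray, origin: tuple[int, int, int] = (0, 0, 0)) -> "IntervalDomain3D":
        """Build a domain from a dense boolean grid indexed ``[p, l, k]``.

        ``origin`` = (k, l, p) places ``mask[0, 0, 0]`` at that global
        coordinate.  An all-false mask yields the empty domain.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("mask must be 3D, indexed [p, l, k]")
        k_org, l_org, p_org = origin
        line_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
        n_p, n_l, n_k = mask.shape
        pad = np.zeros((n_l, 1), dtype=np.int8)
        for ip in range(n_p):
            plane = mask[ip]
            if not plane.any():
                continue
            d = np.diff(np.concatenate([pad, plane.astype(np.int8), pad], axis=1), axis=1)
            srow, scol = np.nonzero(d == 1)
            erow, ecol = np.nonzero(d == -1)
            # starts and ends pair up in order within each row
            for r, c0, c1 in zip(srow, scol, ecol):
                line_map.setdefault((p_org + ip, l_org + int(r)), []).append(
                    (k_org + int(c0), k_org + int(c1) - 1)
                )
        return cls._from_line_map(line_map)

    @classmethod
    def _from_line_map(cls, line_map: dict[tuple[int, int], list[tuple[int, int]]]) -> "IntervalDomain3D":
        line_map = {key: runs for key, runs in line_map.items() if runs}
        if not line_map:
            return cls.empty()
        p_first = min(p for p, _ in line_map)
        p_last = max(p for p, _ in line_map)
        planes: list = []
        by_plane: dict[int, dict[int, list[tuple[int, int]]]] = {}
        for (p, l), runs in line_map.items():
            by_plane.setdefault(p, {})[l] = runs
        for p in range(p_first, p_last + 1):
            lines = by_plane.get(p)
            if not lines:
                planes.append(None)
                continue
            l_first = min(lines)
            l_last = max(lines)
            rows = [lines.get(l, []) for l in range(l_first, l_last + 1)]
            planes.append((l_first, rows))
        return cls(p_first, planes)

    # -- basic queries ------------------------------------------------------

    @property
    def is_empty(self) -> bool:
        return not self._planes

    @property
    def p_first(self) -> int:
        if self.is_empty:
            raise EmptyObjectError("empty domain has no plane bounds")
        return self._p_first

    @property
    def p_last(self) -> int:
        if self.is_empty:
            raise EmptyObjectError("empty domain has no plane bounds")
        return self._p_first + len(self._planes) - 1

    def intervals(self) -> Iterator[Interval]:
        """Yield every interval as :class:`Interval`, with its plane via pairs.

        Iteration order is ascending plane, line, column.
        """
        for p, l, k0, k1 in self.interval_tuples():
            yield Interval(l, k0, k1)

    def interval_tuples(self) -> Iterator[tuple[int, int, int, int]]:
        """Yield ``(p, l, k_first, k_last)`` in ascending order."""
        for ip, plane in enumerate(self._planes):
            if plane is None:
                continue
            l_first, rows = plane
            for il, runs in enumerate(rows):
                for k0, k1 in runs:
                    yield (self._p_first + ip, l_first + il, k0, k1)

    @property
    def interval_count(self) -> int:
        return sum(1 for _ in self.interval_tuples())

    @property
    def voxel_count(self) -> int:
        if self._count is None:
            self._count = sum(k1 - k0 + 1 for _, _, k0, k1 in self.interval_tuples())
        return self._count

    @property
    def bbox(self) -> tuple[int, int, int, int, int, int]:
        """Tight inclusive bounds ``(k1, l1, p1, k2, l2, p2)``."""
        if self.is_empty:
            raise EmptyObjectError("empty domain has no bounding box")
        if self._bbox is None:
            k_min = l_min = None
            k_max = l_max = None
            for _, l, k0, k1 in self.interval_tuples():
                k_min = k0 if k_min is None else min(k_min, k0)
                k_max = k1 if k_max is None else max(k_max, k1)
                l_min = l if l_min is None else min(l_min, l)
                l_max = l if l_max is None else max(l_max, l)
            self._bbox = (k_min, l_min, self.p_first, k_max, l_max, self.p_last)
        return self._bbox

    def to_mask(self) -> tuple[np.ndarray, tuple[int, int, int]]:
        """Dense boolean grid over the tight bounding box plus its origin.

        The exact inverse of :meth:`from_mask`; an empty domain yields a
        zero-size grid with origin (0, 0, 0).
        """
        if self.is_empty:
            return np.zeros((0, 0, 0), dtype=bool), (0, 0, 0)
        k1, l1, p1, k2, l2, p2 = self.bbox
        mask = np.zeros((p2 - p1 + 1, l2 - l1 + 1, k2 - k1 + 1), dtype=bool)
        for p, l, ka, kb in self.interval_tuples():
            mask[p - p1, l - l1, ka - k1 : kb - k1 + 1] = True
        return mask, (k1, l1, p1)

    # -- membership ---------------------------------------------------------

    def _build_lut(self):
        """CSR-style flattened interval table for vectorized membership."""
        k1, l1, p1, k2, l2, p2 = self.bbox
        l_span = l2 - l1 + 1
        big = k2 - k1 + 2
        lines, k0s, k1s = [], [], []
        for p, l, ka, kb in self.interval_tuples():
            lines.append((p - p1) * l_span + (l - l1))
            k0s.append(ka - k1)
            k1s.append(kb - k1)
        codes = np.asarray(lines, dtype=np.int64) * big + np.asarray(k0s, dtype=np.int64)
        self._lut = (
            codes,
            np.asarray(lines, dtype=np.int64),
            np.asarray(k1s, dtype=np.int64),
            (k1, l1, p1, k2, l2, p2, l_span, big),
        )

    def contains_points(self, kk: np.ndarray, ll: np.ndarray, pp: np.ndarray) -> np.ndarray:
        """Vectorized membership test for integer voxel coordinates."""
        kk = np.asarray(kk, dtype=np.int64)
        ll = np.asarray(ll, dtype=np.int64)
        pp = np.asarray(pp, dtype=np.int64)
        out = np.zeros(kk.shape, dtype=bool)
        if self.is_empty:
            return out
        if self._lut is None:
            self._build_lut()
        codes, ivl_line, ivl_k1, (k1, l1, p1, k2, l2, p2, l_span, big) = self._lut
        inb = (kk >= k1) & (kk <= k2) & (ll >= l1) & (ll <= l2) & (pp >= p1) & (pp <= p2)
        if not inb.any():
            return out
        line_id = (pp[inb] - p1) * l_span + (ll[inb] - l1)
        q = line_id * big + (kk[inb] - k1)
        idx = np.searchsorted(codes, q, side="right") - 1
        ok = idx >= 0
        idx = np.clip(idx, 0, None)
        ok &= ivl_line[idx] == line_id
        ok &= (kk[inb] - k1) <= ivl_k1[idx]
        out[inb] = ok
        return out

    def contains(self, k: int, l: int, p: int) -> bool:
        return bool(self.contains_points(np.array([k]), np.array([l]), np.array([p]))[0])

    # -- set algebra --------------------------------------------------------

    def binary_op(self, other: "IntervalDomain3D", op: str) -> "IntervalDomain3D":
        """Voxelwise ``union`` / ``intersect`` / ``difference`` with *other*.

        Implemented purely by per-line interval merging; neither operand
        is densified.
        """
        try:
            run_op = _RUN_OPS[op]
        except KeyError:
            raise ValueError(f"unknown op {op!r}; expected union/intersect/difference")
        a = {(p, l): runs for p, l, runs in self._line_runs()}
        b = {(p, l): runs for p, l, runs in other._line_runs()}
        if op == "union":
            keys = set(a) | set(b)
        elif op == "intersect":
            keys = set(a) & set(b)
        else:
            keys = set(a)
        line_map = {}
        for key in keys:
            runs = run_op(a.get(key, []), b.get(key, []))
            if runs:
                line_map[key] = runs
        return IntervalDomain3D._from_line_map(line_map)

    def _line_runs(self) -> Iterator[tuple[int, int, list[tuple[int, int]]]]:
        for ip, plane in enumerate(self._planes):
            if plane is None:
                continue
            l_first, rows = plane
            for il, runs in enumerate(rows):
                if runs:
                    yield (self._p_first + ip, l_first + il, runs)

    def union(self, other: "IntervalDomain3D") -> "IntervalDomain3D":
        return self.binary_op(other, "union")

    def intersect(self, other: "IntervalDomain3D") -> "IntervalDomain3D":
        return self.binary_op(other, "intersect")

    def difference(self, other: "IntervalDomain3D") -> "IntervalDomain3D":
        return self.binary_op(other, "difference")

    __or__ = union
    __and__ = intersect
    __sub__ = difference

    def translate(self, dk: int, dl: int, dp: int) -> "IntervalDomain3D":
        """Shift the whole point-set by integer offsets."""
        return IntervalDomain3D.from_intervals(
            (p + dp, l + dl, k0 + dk, k1 + dk) for p, l, k0, k1 in self.interval_tuples()
        )

    # -- dunder -------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalDomain3D):
            return NotImplemented
        if self.is_empty or other.is_empty:
            return self.is_empty and other.is_empty
        return self._p_first == other._p_first and list(self.interval_tuples()) == list(
            other.interval_tuples()
        )

    def __hash__(self):  # normalized form is canonical
        return hash((self._p_first if not self.is_empty else 0, tuple(self.interval_tuples())))

    def __repr__(self) -> str:
        if self.is_empty:
            return "IntervalDomain3D(empty)"
        return f"IntervalDomain3D(bbox={self.bbox}, voxels={self.voxel_count})"


def domain_from_mask(mask: np.ndarray, origin: tuple[int, int, int] = (0, 0, 0)) -> IntervalDomain3D:
    """Functional alias for :meth:`IntervalDomain3D.from_mask`."""
    return IntervalDomain3D.from_mask(mask, origin)


def domain_to_mask(domain: IntervalDomain3D) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Functional alias for :meth:`IntervalDomain3D.to_mask`."""
    return domain.to_mask()
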