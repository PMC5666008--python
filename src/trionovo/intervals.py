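"""Genomic interval sets (0-based, half-open).

A :class:`RegionSet` is the pipeline's canonical representation of target
regions, filter removals and masks: per chromosome, a sorted array of
disjoint ``[start, end)`` intervals.  Touching intervals are merged on
construction, so equality of region sets is equality of arrays.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, Mapping, Tuple

import numpy as np

Interval = Tuple[str, int, int]


def _merge(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge an ``(n, 2)`` array of half-open intervals.

    Overlapping *and* adjacent intervals are coalesced, giving a canonical
    form.  Empty intervals (end <= start) are dropped.
    """
    if intervals.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = intervals[intervals[:, 1] > intervals[:, 0]]
    if iv.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.lexsort((iv[:, 1], iv[:, 0]))
    s = iv[order, 0]
    e = iv[order, 1]
    running_max = np.maximum.accumulate(e)
    # a new merged block starts where the interval begins strictly after
    # everything seen so far has ended
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > running_max[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    out = np.empty((n_blocks, 2), dtype=np.int64)
    out[:, 0] = s[new_block]
    out[block_id, 1] = 0  # placeholder
    np.maximum.at(out[:, 1], block_id, e)
    return out


class RegionSet:
    """A set of disjoint half-open genomic intervals.

    Parameters
    ----------
    intervals:
        Mapping ``chrom -> (n, 2) array`` or an iterable of
        ``(chrom, start, end)`` tuples.  Intervals are merged on input.
    """

    def __init__(self, intervals: Mapping[str, np.ndarray] | Iterable[Interval] | None = None):
        self._ivs: Dict[str, np.ndarray] = {}
        if intervals is None:
            return
        if isinstance(intervals, Mapping):
            for chrom, arr in intervals.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                merged = _merge(arr)
                if len(merged):
                    self._ivs[chrom] = merged
        else:
            by_chrom: Dict[str, list] = {}
            for chrom, start, end in intervals:
                by_chrom.setdefault(chrom, []).append((start, end))
            for chrom, ivs in by_chrom.items():
                merged = _merge(np.asarray(ivs, dtype=np.int64))
                if len(merged):
                    self._ivs[chrom] = merged

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_mask(cls, chrom: str, mask: np.ndarray, offset: int = 0) -> "RegionSet":
        """Build from a per-base boolean mask (True = inside the set)."""
        mask = np.asarray(mask, dtype=bool)
        edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
        ivs = edges.reshape(-1, 2) + offset
        return cls({chrom: ivs})

    @classmethod
    def whole_genome(cls, chrom_lengths: Mapping[str, int]) -> "RegionSet":
        return cls({c: np.array([[0, n]]) for c, n in chrom_lengths.items()})

    @classmethod
    def from_points(cls, chrom: str, positions: np.ndarray, pad: int = 0) -> "RegionSet":
        """Intervals ``[p - pad, p + pad + 1)`` around point positions, floored at 0."""
        positions = np.asarray(positions, dtype=np.int64)
        ivs = np.stack([np.maximum(positions - pad, 0), positions + pad + 1], axis=1)
        return cls({chrom: ivs})

    # -- basic queries ---------------------------------------------------
    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(sorted(self._ivs))

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivs.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __iter__(self) -> Iterator[Interval]:
        for chrom in sorted(self._ivs):
            for s, e in self._ivs[chrom]:
                yield (chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(a) for a in self._ivs.values())

    def __bool__(self) -> bool:
        return any(len(a) for a in self._ivs.values())

    @property
    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._ivs.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if set(self._ivs) != set(other._ivs):
            return False
        return all(np.array_equal(self._ivs[c], other._ivs[c]) for c in self._ivs)

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals, {self.total_length} bp)"

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean array: is each position inside the set."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        iv = self.intervals(chrom)
        if not len(iv):
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(iv[:, 0], positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < iv[idx[ok], 1]
        return out

    # -- set algebra -----------------------------------------------------
    def union(self, other: "RegionSet") -> "RegionSet":
        out = {}
        for chrom in set(self._ivs) | set(other._ivs):
            out[chrom] = np.concatenate([self.intervals(chrom), other.intervals(chrom)])
        return RegionSet(out)

    def intersection(self, other: "RegionSet") -> "RegionSet":
        out = {}
        for chrom in set(self._ivs) & set(other._ivs):
            out[chrom] = _intersect_arrays(self._ivs[chrom], other._ivs[chrom])
        return RegionSet(out)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        out = {}
        for chrom, iv in self._ivs.items():
            oiv = other.intervals(chrom)
            if not len(oiv):
                out[chrom] = iv
            else:
                lo = min(iv[0, 0], oiv[0, 0])
                hi = max(iv[-1, 1], oiv[-1, 1])
                out[chrom] = _intersect_arrays(iv, _complement_array(oiv, lo, hi))
        return RegionSet(out)

    def complement(self, chrom_lengths: Mapping[str, int]) -> "RegionSet":
        return RegionSet.whole_genome(chrom_lengths).subtract(self)


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two merged interval arrays (linear sweep)."""
    out = []
    i = j = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def _complement_array(iv: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Complement of a merged interval array within [lo, hi)."""
    bounds = np.concatenate(([lo], iv.ravel(), [hi]))
    gaps = bounds.reshape(-1, 2)
    return gaps[gaps[:, 1] > gaps[:, 0]]


def union_all(region_sets: Iterable[RegionSet]) -> RegionSet:
    out: Dict[str, list] = {}
    for rs in region_sets:
        for chrom in rs.chroms:
            out.setdefault(chrom, []).append(rs.intervals(chrom))
    return RegionSet({c: np.concatenate(arrs) for c, arrs in out.items()})
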