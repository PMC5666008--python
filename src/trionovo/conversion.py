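"""Clustering copy-number-neutral inherited variants into conversion events.

CNIVs produced by a single allelic-conversion tract sit within a few
hundred bp of each other, far closer than expected if the same number of
CNIVs were scattered uniformly over the target regions.  The null model
places n points uniformly on a region of length L: the expected mean
adjacent distance is L/n, and a pooled-gap bootstrap gives a confidence
interval for a single adjacent distance.  CNIVs closer than the interval's
lower bound are chained (single linkage) into one putative event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd


def expected_adjacent_distance(n: int, L: float) -> float:
    """Expected mean distance between adjacent points, n uniform on [0, L)."""
    if n < 2:
        raise ValueError("need at least two points for an adjacent distance")
    if L <= 0:
        raise ValueError("region length must be positive")
    return L / n


@dataclass(frozen=True)
class DistanceNull:
    """Uniform-placement null for adjacent CNIV distances."""

    n: int
    L: float
    expected_mean: float
    lower: float
    upper: float
    level: float
    reps: int
    seed: int

    def to_dict(self) -> dict:
        return {"n": self.n, "L": self.L, "expected_mean": self.expected_mean,
                "lower": self.lower, "upper": self.upper, "level": self.level,
                "reps": self.reps, "seed": self.seed}


def bootstrap_distance_ci(n: int, L: float, reps: int = 10_000,
                          level: float = 0.99, seed: int = 0) -> DistanceNull:
    """Bootstrap interval for the distance between adjacent uniform points.

    Each replicate scatters n points on [0, L) and records the n-1
    adjacent gaps; gaps are pooled across replicates and the central
    ``level`` percentile interval is returned.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    # replicate-wise in blocks to bound memory at large reps * n
    block = max(1, int(5e6 // max(n, 1)))
    gaps = []
    done = 0
    while done < reps:
        b = min(block, reps - done)
        pts = rng.uniform(0.0, L, size=(b, n))
        pts.sort(axis=1)
        gaps.append(np.diff(pts, axis=1).ravel())
        done += b
    pooled = np.concatenate(gaps)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(pooled, [alpha, 1.0 - alpha])
    return DistanceNull(n, float(L), expected_adjacent_distance(n, L),
                        float(lower), float(upper), level, reps, seed)


@dataclass
class ConversionEvent:
    """A cluster of CNIVs attributed to one allelic-conversion event."""

    chrom: str
    members: Tuple[int, ...]

    def __post_init__(self):
        self.members = tuple(sorted(int(p) for p in self.members))
        if not self.members:
            raise ValueError("an event needs at least one member CNIV")

    @property
    def start(self) -> int:
        return self.members[0]

    @property
    def end(self) -> int:
        return self.members[-1] + 1

    @property
    def span(self) -> int:
        return self.members[-1] - self.members[0]

    @property
    def n_members(self) -> int:
        return len(self.members)


def cluster_cnivs(positions_by_chrom: Mapping[str, Sequence[int]],
                  threshold: float) -> List[ConversionEvent]:
    """Single-linkage chaining of CNIVs with adjacent gap <= ``threshold``.

    Gaps across chromosomes are infinite; isolated CNIVs form singleton
    events.
    """
    events: List[ConversionEvent] = []
    for chrom in sorted(positions_by_chrom):
        pos = np.sort(np.asarray(positions_by_chrom[chrom], dtype=np.int64))
        if not len(pos):
            continue
        gaps = np.diff(pos)
        breaks = np.flatnonzero(gaps > threshold) + 1
        for chunk in np.split(pos, breaks):
            events.append(ConversionEvent(chrom, tuple(chunk)))
    return events


def adjacency_profile(positions_by_chrom: Mapping[str, Sequence[int]],
                      cutoffs: Sequence[float] = (100, 1000, 17_500)
                      ) -> Dict[float, int]:
    """Per cutoff: how many CNIVs have a nearest neighbour within it."""
    counts = {c: 0 for c in cutoffs}
    for chrom in positions_by_chrom:
        pos = np.sort(np.asarray(positions_by_chrom[chrom], dtype=np.int64))
        if len(pos) < 2:
            continue
        gaps = np.diff(pos).astype(np.float64)
        nn = np.empty(len(pos))
        nn[0] = gaps[0]
        nn[-1] = gaps[-1]
        if len(pos) > 2:
            nn[1:-1] = np.minimum(gaps[:-1], gaps[1:])
        for c in cutoffs:
            counts[c] += int((nn <= c).sum())
    return counts


def events_to_frame(events: Sequence[ConversionEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "event_id": i, "chrom": ev.chrom, "start": ev.start, "end": ev.end,
        "n_members": ev.n_members, "span": ev.span,
    } for i, ev in enumerate(events)],
        columns=["event_id", "chrom", "start", "end", "n_members", "span"])
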