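"""High-confidence target-region definition.

Five per-site/per-variant filters plus a repeat mask carve the genome
down to the regions in which trio genotypes are trusted:

(i)   read-depth outliers (outside mean +/- 3 sigma for any member,
      with the mean/sigma computed after clamping to a sane pre-range),
(ii)  mapped-read strand balance (>= 10 forward and >= 10 reverse reads
      in every member),
(iii) indel positions +/- 50 bp,
(iv)  allelic/strand bias at variant sites (every observed allele must
      be seen on both strands) +/- 10 bp,
(v)   variants whose supporting reads sit within 10 bp of a read end,
      +/- 10 bp.

Per-filter removals are reported individually (overlaps counted per
filter); the final target is the genome minus the union of removals
minus the repeat mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .intervals import RegionSet, union_all
from .simulate import DepthTrack, HET, HOM_ALT

DEFAULT_PREMIN = {"father": 15, "mother": 15, "offspring": 18}
DEFAULT_PREMAX = 512


@dataclass(frozen=True)
class DepthBounds:
    """Acceptable depth range for one individual: mean +/- 3 sigma.

    The mean and sigma are computed only from sites whose depth lies in
    ``[premin, premax]``, so pathological pileups do not distort them.
    """

    mean: float
    sd: float
    lower: float
    upper: float
    premin: int
    premax: int

    @classmethod
    def from_moments(cls, mean: float, sd: float, premin: int, premax: int,
                     n_sigma: float = 3.0) -> "DepthBounds":
        return cls(mean, sd, max(0.0, mean - n_sigma * sd), mean + n_sigma * sd,
                   premin, premax)


class UnconfigurableBoundsError(ValueError):
    """No site falls inside the depth pre-clamp range."""


def compute_depth_bounds(track: DepthTrack, premin: int, premax: int = DEFAULT_PREMAX,
                         n_sigma: float = 3.0) -> DepthBounds:
    """Depth mean/sigma over in-range sites, bounds at mean +/- ``n_sigma``*sigma."""
    if premin >= premax:
        raise ValueError("premin must be < premax")
    total = n = 0
    sq = 0.0
    for arr in track.depth.values():
        sel = arr[(arr >= premin) & (arr <= premax)]
        total += int(sel.sum())
        sq += float((sel.astype(np.float64) ** 2).sum())
        n += len(sel)
    if n == 0:
        raise UnconfigurableBoundsError(
            f"no site with depth in [{premin}, {premax}]")
    mean = total / n
    var = max(sq / n - mean**2, 0.0)
    return DepthBounds.from_moments(mean, float(np.sqrt(var)), premin, premax, n_sigma)


def filter_depth(tracks: Mapping[str, DepthTrack],
                 bounds: Mapping[str, DepthBounds]) -> RegionSet:
    """Sites where ANY member's depth is outside its own bounds."""
    removed = []
    chroms = next(iter(tracks.values())).depth.keys()
    for chrom in chroms:
        bad: Optional[np.ndarray] = None
        for name, track in tracks.items():
            b = bounds[name]
            arr = track.depth[chrom]
            out = (arr < b.lower) | (arr > b.upper)
            bad = out if bad is None else (bad | out)
        removed.append(RegionSet.from_mask(chrom, bad))
    return union_all(removed)


def filter_read_balance(tracks: Mapping[str, DepthTrack],
                        min_per_strand: int = 10) -> RegionSet:
    """Sites lacking >= ``min_per_strand`` forward AND reverse reads in every member."""
    removed = []
    chroms = next(iter(tracks.values())).depth.keys()
    for chrom in chroms:
        bad: Optional[np.ndarray] = None
        for track in tracks.values():
            fwd = track.fwd[chrom]
            rev = track.depth[chrom] - fwd
            out = (fwd < min_per_strand) | (rev < min_per_strand)
            bad = out if bad is None else (bad | out)
        removed.append(RegionSet.from_mask(chrom, bad))
    return union_all(removed)


def filter_indels(indel_positions: Mapping[str, np.ndarray], pad: int = 50) -> RegionSet:
    """Each indel position +/- ``pad`` bp (a 2*pad+1-bp half-open interval)."""
    parts = [RegionSet.from_points(chrom, pos, pad)
             for chrom, pos in indel_positions.items() if len(pos)]
    return union_all(parts) if parts else RegionSet()


def filter_allele_strand_bias(trio_table: pd.DataFrame, pad: int = 10) -> RegionSet:
    """Variant sites with an allele unseen on one strand in a carrier, +/- ``pad``.

    For each individual carrying the variant: a heterozygote must show all
    of RF, RR, AF, AR >= 1; a homozygous-alternate carrier (no reference
    reads expected) must show AF >= 1 and AR >= 1.
    """
    removed: Dict[str, list] = {}
    for ind in ("father", "mother", "offspring"):
        gt = trio_table[f"gt_{ind}"].to_numpy()
        rf = trio_table[f"rf_{ind}"].to_numpy()
        rr = trio_table[f"rr_{ind}"].to_numpy()
        af = trio_table[f"af_{ind}"].to_numpy()
        ar = trio_table[f"ar_{ind}"].to_numpy()
        het_bad = (gt == HET) & ((rf < 1) | (rr < 1) | (af < 1) | (ar < 1))
        hom_bad = (gt == HOM_ALT) & ((af < 1) | (ar < 1))
        bad = het_bad | hom_bad
        for chrom, pos in zip(trio_table.loc[bad, "chrom"], trio_table.loc[bad, "pos"]):
            removed.setdefault(chrom, []).append(pos)
    parts = [RegionSet.from_points(c, np.asarray(ps), pad) for c, ps in removed.items()]
    return union_all(parts) if parts else RegionSet()


def filter_read_ends(trio_table: pd.DataFrame, pad: int = 10,
                     max_end_distance: float = 10.0) -> RegionSet:
    """Variant sites whose supporting reads average <= ``max_end_distance``
    bp from a read end in any member, +/- ``pad`` bp."""
    removed: Dict[str, list] = {}
    any_variant = ((trio_table["gt_father"] > 0) | (trio_table["gt_mother"] > 0)
                   | (trio_table["gt_offspring"] > 0))
    for ind in ("father", "mother", "offspring"):
        col = f"end_dist_{ind}"
        if col not in trio_table:
            continue
        d = trio_table[col].to_numpy(np.float64)
        bad = any_variant.to_numpy() & (d <= max_end_distance)
        for chrom, pos in zip(trio_table.loc[bad, "chrom"], trio_table.loc[bad, "pos"]):
            removed.setdefault(chrom, []).append(pos)
    parts = [RegionSet.from_points(c, np.asarray(ps), pad) for c, ps in removed.items()]
    return union_all(parts) if parts else RegionSet()


@dataclass
class FilterReport:
    """Base pairs removed per filter and final retained target size."""

    genome_length: int
    per_filter_bp: Dict[str, int] = field(default_factory=dict)
    retained_bp: int = 0

    @property
    def per_filter_pct(self) -> Dict[str, float]:
        return {k: 100.0 * v / self.genome_length for k, v in self.per_filter_bp.items()}

    @property
    def retained_pct(self) -> float:
        return 100.0 * self.retained_bp / self.genome_length

    def to_dict(self) -> dict:
        return {
            "genome_length": self.genome_length,
            "per_filter_bp": dict(self.per_filter_bp),
            "per_filter_pct": {k: round(v, 4) for k, v in self.per_filter_pct.items()},
            "retained_bp": self.retained_bp,
            "retained_pct": round(self.retained_pct, 4),
        }


class EmptyTargetError(RuntimeError):
    """All of the genome was removed by filters."""


def build_target_regions(chrom_lengths: Mapping[str, int],
                         removals: Mapping[str, RegionSet],
                         repeat_mask: Optional[RegionSet] = None,
                         ) -> Tuple[RegionSet, FilterReport]:
    """Genome minus the union of filter removals minus the repeat mask.

    The report counts each filter's removal separately (overlapping
    removals are counted once per filter, as each filter is described
    against the whole genome), so the per-filter sum can exceed the
    union.
    """
    genome = RegionSet.whole_genome(chrom_lengths)
    glen = genome.total_length
    report = FilterReport(genome_length=glen)
    pieces = []
    for name, rs in removals.items():
        clipped = rs.intersection(genome)
        report.per_filter_bp[name] = clipped.total_length
        pieces.append(clipped)
    if repeat_mask is not None:
        clipped = repeat_mask.intersection(genome)
        report.per_filter_bp["repeat_mask"] = clipped.total_length
        pieces.append(clipped)
    target = genome.subtract(union_all(pieces)) if pieces else genome
    report.retained_bp = target.total_length
    if report.retained_bp == 0:
        raise EmptyTargetError("filters removed the entire genome")
    return target, report
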