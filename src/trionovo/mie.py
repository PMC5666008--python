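"""Mendelian-inheritance-error detection and four-way classification.

A trio genotype configuration is a Mendelian inheritance error (MIE)
when no choice of one allele from the father's genotype and one from the
mother's reproduces the offspring's genotype.  Each MIE is then placed
in one of four categories using the offspring's novel-allele status and
windowed read-depth comparisons against each parent:

* ``DENOVO_SNV`` -- the offspring carries an allele absent from both
  parents and all three depths are normal (a new germline or somatic
  point mutation);
* ``CNIV``       -- all offspring alleles are inherited and depths are
  normal (copy-number-neutral inherited variant: the signature of an
  allelic conversion that erased an obligate allele);
* ``HDIV``       -- exactly one parent shares the offspring's half-depth
  state (a transmitted hemizygous deletion);
* ``DENOVO_CNV`` -- only the offspring is at half depth (a new deletion).

Anything else (e.g. both parents at half depth) is reported as
``UNCLASSIFIED``, never dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .intervals import RegionSet
from .simulate import DepthTrack, HOM_REF, HET, HOM_ALT

# Depth-window call: normalized depth <= HALF_DEPTH_THRESHOLD reads as
# "one copy" (midpoint of the 0.5 and 1.0 expectations).
HALF_DEPTH_THRESHOLD = 0.75
DEFAULT_WINDOW_BP = 1000


class MieCategory(str, Enum):
    DENOVO_SNV = "DENOVO_SNV"
    CNIV = "CNIV"
    HDIV = "HDIV"
    DENOVO_CNV = "DENOVO_CNV"
    UNCLASSIFIED = "UNCLASSIFIED"


_ALLELES = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}


def _consistent(gf: int, gm: int, go: int) -> bool:
    want = tuple(sorted(_ALLELES[go]))
    for a in set(_ALLELES[gf]):
        for b in set(_ALLELES[gm]):
            if tuple(sorted((a, b))) == want:
                return True
    return False


# 3x3x3 lookup over genotype codes, built once by exhaustive assortment
_CONSISTENT = np.zeros((3, 3, 3), dtype=bool)
for _f in (HOM_REF, HET, HOM_ALT):
    for _m in (HOM_REF, HET, HOM_ALT):
        for _o in (HOM_REF, HET, HOM_ALT):
            _CONSISTENT[_f, _m, _o] = _consistent(_f, _m, _o)


def mendelian_consistent(gt_father: np.ndarray, gt_mother: np.ndarray,
                         gt_offspring: np.ndarray) -> np.ndarray:
    """Vectorized Mendelian-consistency check over genotype codes 0/1/2."""
    return _CONSISTENT[np.asarray(gt_father), np.asarray(gt_mother),
                       np.asarray(gt_offspring)]


def offspring_novel_allele(gt_father: np.ndarray, gt_mother: np.ndarray,
                           gt_offspring: np.ndarray) -> np.ndarray:
    """Does the offspring carry an allele present in neither parent?"""
    gf = np.asarray(gt_father)
    gm = np.asarray(gt_mother)
    go = np.asarray(gt_offspring)
    parents_have_alt = (gf > HOM_REF) | (gm > HOM_REF)
    parents_have_ref = (gf < HOM_ALT) | (gm < HOM_ALT)
    o_has_alt = go > HOM_REF
    o_has_ref = go < HOM_ALT
    return (o_has_alt & ~parents_have_alt) | (o_has_ref & ~parents_have_ref)


@dataclass
class MieRecord:
    """One classified Mendelian inheritance error."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gt_father: int
    gt_mother: int
    gt_offspring: int
    category: MieCategory = MieCategory.UNCLASSIFIED
    ratio_father_offspring: float = np.nan
    ratio_mother_offspring: float = np.nan
    half_father: bool = False
    half_mother: bool = False
    half_offspring: bool = False
    origin: str = "unassigned"


@dataclass
class MieDetectionResult:
    records: List[MieRecord]
    n_sites_tested: int
    n_skipped_missing: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "gt_father": r.gt_father, "gt_mother": r.gt_mother,
            "gt_offspring": r.gt_offspring, "category": r.category.value,
            "ratio_father_offspring": r.ratio_father_offspring,
            "ratio_mother_offspring": r.ratio_mother_offspring,
            "half_father": r.half_father, "half_mother": r.half_mother,
            "half_offspring": r.half_offspring, "origin": r.origin,
        } for r in self.records]
        cols = ["chrom", "pos", "ref", "alt", "gt_father", "gt_mother",
                "gt_offspring", "category", "ratio_father_offspring",
                "ratio_mother_offspring", "half_father", "half_mother",
                "half_offspring", "origin"]
        return pd.DataFrame(rows, columns=cols)


def detect_mies(trio_table: pd.DataFrame,
                target_regions: Optional[RegionSet] = None) -> MieDetectionResult:
    """Flag Mendelian inheritance errors among trio genotypes.

    ``trio_table`` needs columns chrom, pos, ref, alt, gt_{father,mother,
    offspring} and status_{...}; sites with a missing or filtered genotype
    in any member are skipped (and counted), as are sites outside
    ``target_regions``.
    """
    df = trio_table
    ok = np.ones(len(df), dtype=bool)
    for ind in ("father", "mother", "offspring"):
        scol = f"status_{ind}"
        if scol in df:
            ok &= (df[scol] == "pass").to_numpy()
        else:
            ok &= (df[f"gt_{ind}"] >= 0).to_numpy()
    n_skipped = int((~ok).sum())
    in_target = np.ones(len(df), dtype=bool)
    if target_regions is not None:
        for chrom, sub in df.groupby("chrom"):
            in_target[sub.index] = target_regions.contains(
                chrom, sub["pos"].to_numpy(np.int64))
    keep = ok & in_target
    sub = df[keep]
    if not len(sub):
        return MieDetectionResult([], int(keep.sum()), n_skipped)
    bad = ~mendelian_consistent(sub["gt_father"].to_numpy(np.int8),
                                sub["gt_mother"].to_numpy(np.int8),
                                sub["gt_offspring"].to_numpy(np.int8))
    records = [
        MieRecord(row.chrom, int(row.pos), row.ref, row.alt,
                  int(row.gt_father), int(row.gt_mother), int(row.gt_offspring))
        for row in sub[bad].itertuples()
    ]
    return MieDetectionResult(records, int(keep.sum()), n_skipped)


class UndefinedRatioError(ZeroDivisionError):
    """A depth-ratio window has zero coverage."""


def depth_ratio(chrom: str, start: int, end: int,
                track_a: DepthTrack, track_b: DepthTrack) -> float:
    """Normalized depth of b relative to a over a window.

    ratio = (mean_b / genome_mean_b) / (mean_a / genome_mean_a); 1.0 means
    the two individuals have the same relative copy number there.
    """
    mean_a = track_a.window_mean(chrom, start, end)
    mean_b = track_b.window_mean(chrom, start, end)
    if mean_a == 0 or track_a.genome_mean == 0 or track_b.genome_mean == 0:
        raise UndefinedRatioError(f"zero coverage in window {chrom}:{start}-{end}")
    return (mean_b / track_b.genome_mean) / (mean_a / track_a.genome_mean)


def _half_flags(chrom: str, pos: int, tracks: Mapping[str, DepthTrack],
                window_bp: int, threshold: float,
                genome_means: Mapping[str, float]) -> Dict[str, bool]:
    half = {}
    for name, track in tracks.items():
        s = max(0, pos - window_bp // 2)
        e = pos + window_bp // 2 + 1
        r = track.window_mean(chrom, s, e) / genome_means[name]
        half[name] = r <= threshold
    return half


def classify_mie(record: MieRecord, half_father: bool, half_mother: bool,
                 half_offspring: bool) -> MieRecord:
    """Assign the category from novel-allele status and half-depth flags.

    Decision order: the novel-allele test runs before any depth test, so
    a de novo SNV in a normal-depth region cannot be shadowed by a noisy
    ratio.
    """
    novel = bool(offspring_novel_allele(record.gt_father, record.gt_mother,
                                        record.gt_offspring))
    any_half = half_father or half_mother or half_offspring
    if novel and not any_half:
        cat = MieCategory.DENOVO_SNV
    elif not novel and not any_half:
        cat = MieCategory.CNIV
    elif half_offspring and (half_father != half_mother):
        cat = MieCategory.HDIV
    elif half_offspring and not half_father and not half_mother:
        cat = MieCategory.DENOVO_CNV
    else:
        cat = MieCategory.UNCLASSIFIED
    record.category = cat
    record.half_father = half_father
    record.half_mother = half_mother
    record.half_offspring = half_offspring
    return record


def classify_mies(result: MieDetectionResult, tracks: Mapping[str, DepthTrack],
                  window_bp: int = DEFAULT_WINDOW_BP,
                  half_depth_threshold: float = HALF_DEPTH_THRESHOLD
                  ) -> MieDetectionResult:
    """Classify every detected MIE using windowed depth around each site."""
    genome_means = {k: t.genome_mean for k, t in tracks.items()}
    for rec in result.records:
        half = _half_flags(rec.chrom, rec.pos, tracks, window_bp,
                           half_depth_threshold, genome_means)
        classify_mie(rec, half["father"], half["mother"], half["offspring"])
        rec.ratio_father_offspring = depth_ratio(
            rec.chrom, max(0, rec.pos - window_bp // 2), rec.pos + window_bp // 2 + 1,
            tracks["father"], tracks["offspring"])
        rec.ratio_mother_offspring = depth_ratio(
            rec.chrom, max(0, rec.pos - window_bp // 2), rec.pos + window_bp // 2 + 1,
            tracks["mother"], tracks["offspring"])
    return result


def segment_half_depth(track: DepthTrack, window_bp: int = DEFAULT_WINDOW_BP,
                       half_depth_threshold: float = HALF_DEPTH_THRESHOLD,
                       min_length: int = 0) -> RegionSet:
    """Maximal runs of half-depth windows for one individual.

    The genome is tiled with non-overlapping ``window_bp`` windows; a
    window is "half" when its mean depth, normalized by the genome-wide
    mean, is <= the threshold.  Adjacent (within one window) half windows
    merge; segments shorter than ``min_length`` are dropped.
    """
    gm = track.genome_mean
    segments = []
    for chrom, arr in track.depth.items():
        n_full = len(arr) // window_bp
        if n_full == 0:
            continue
        means = arr[: n_full * window_bp].reshape(n_full, window_bp).mean(axis=1)
        half = means / gm <= half_depth_threshold
        rs = RegionSet.from_mask(chrom, np.repeat(half, window_bp))
        for c, s, e in rs:
            if e - s >= min_length:
                segments.append((c, s, e))
    return RegionSet(segments)
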