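"""Parental-origin assignment for de novo SNVs via read-pair linkage.

A sequenced fragment that covers both a de novo site (showing the new
allele) and a nearby parentally informative heterozygous site ties the
new allele to one parental haplotype.  An informative site is one where
the offspring is heterozygous and each of its alleles can have come from
exactly one parent (father hom-ref x mother hom-alt, or the reverse).

The default policy is conservative: a de novo SNV is assigned only when
every supporting fragment votes for the same parent; any conflict (or no
informative coverage) leaves it unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .simulate import Fragment, HOM_REF, HET, HOM_ALT, FATHER, MOTHER


def informative_sites(trio_table: pd.DataFrame, chrom: str, denovo_pos: int,
                      max_distance: int = 500) -> pd.DataFrame:
    """Nearby het sites whose alleles have unambiguous parental origin.

    Returns the subset of ``trio_table`` within ``max_distance`` of the de
    novo site where the offspring is heterozygous and the parents are
    opposite homozygotes, plus an ``alt_parent`` column naming the parent
    who contributed the alternate allele.
    """
    sub = trio_table[(trio_table["chrom"] == chrom)
                     & (trio_table["pos"] != denovo_pos)
                     & (abs(trio_table["pos"] - denovo_pos) <= max_distance)]
    gf = sub["gt_father"].to_numpy()
    gm = sub["gt_mother"].to_numpy()
    go = sub["gt_offspring"].to_numpy()
    informative = (go == HET) & (((gf == HOM_REF) & (gm == HOM_ALT))
                                 | ((gf == HOM_ALT) & (gm == HOM_REF)))
    out = sub[informative].copy()
    out["alt_parent"] = np.where(out["gt_father"] == HOM_ALT, FATHER, MOTHER)
    return out


@dataclass(frozen=True)
class OriginCall:
    """Parental-origin verdict for one de novo SNV."""

    chrom: str
    pos: int
    origin: str  # father / mother / unassigned
    supporting: int
    conflicting: int


def assign_origin(chrom: str, denovo_pos: int, denovo_allele: str,
                  fragments: Sequence[Fragment],
                  informative: pd.DataFrame) -> OriginCall:
    """Vote over fragments that carry the de novo allele.

    Each such fragment votes for the parent whose diagnostic allele it
    shows at an informative site it covers.  A unanimous non-empty vote
    assigns the origin; zero votes or any conflict leaves it unassigned.
    """
    info_alt = dict(zip(informative["pos"].astype(int), informative["alt_parent"]))
    info_ref_allele = dict(zip(informative["pos"].astype(int), informative["ref"]))
    votes: List[str] = []
    for frag in fragments:
        if frag.chrom != chrom or not (frag.start <= denovo_pos < frag.end):
            continue
        if frag.alleles.get(denovo_pos) != denovo_allele:
            continue
        for p, alt_parent in info_alt.items():
            a = frag.alleles.get(p)
            if a is None:
                continue
            if a == info_ref_allele[p]:
                votes.append(MOTHER if alt_parent == FATHER else FATHER)
            else:
                votes.append(alt_parent)
    if not votes:
        return OriginCall(chrom, denovo_pos, "unassigned", 0, 0)
    counts = {FATHER: votes.count(FATHER), MOTHER: votes.count(MOTHER)}
    winner = max(counts, key=counts.get)
    n_support, n_conflict = counts[winner], counts[FATHER] + counts[MOTHER] - counts[winner]
    if n_conflict > 0:
        return OriginCall(chrom, denovo_pos, "unassigned", n_support, n_conflict)
    return OriginCall(chrom, denovo_pos, winner, n_support, 0)


def paternal_fraction(calls: Sequence[OriginCall],
                      ci_level: float = 0.95) -> Tuple[float, float, float]:
    """Fraction of assigned de novo SNVs of paternal origin, with a
    Wilson binomial confidence interval."""
    n_father = sum(1 for c in calls if c.origin == FATHER)
    n_mother = sum(1 for c in calls if c.origin == MOTHER)
    n = n_father + n_mother
    if n == 0:
        raise ValueError("no assigned origin calls")
    lo, hi = proportion_confint(n_father, n, alpha=1.0 - ci_level, method="wilson")
    return n_father / n, float(lo), float(hi)


def calls_to_frame(calls: Sequence[OriginCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": c.chrom, "pos": c.pos, "origin": c.origin,
        "supporting": c.supporting, "conflicting": c.conflicting,
    } for c in calls], columns=["chrom", "pos", "origin", "supporting", "conflicting"])
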