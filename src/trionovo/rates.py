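"""Validation bookkeeping and mutation-rate arithmetic.

Covers the downstream quantitative steps of a trio de novo study:

* confirmation ("Sanger") genotypes versus the sequencing calls give a
  false-positive rate; offspring blood-vs-hair discordance flags somatic
  (rather than germline) de novo SNVs;
* the corrected germline count divides by twice the target size to give
  a per-site per-generation rate, and by the mean parental age at
  conception to give a per-year rate;
* the phylogenetic calculator converts interspecies divergence d into a
  rate, correcting for ancestral polymorphism: the expected pairwise
  divergence is 2*mu_y*t + 4*Ne*g*mu_y, so mu_y = d / (2t + 4*Ne*g) and
  mu_g = mu_y * g;
* the CpG fraction annotates de novo SNVs falling on hypermutable CpG
  dinucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


def round_sig(x: float, n: int) -> float:
    """Round to ``n`` significant figures, half away from zero.

    Display rounding for reported rates: the float is first written at 12
    significant decimal digits (stripping binary-representation noise, so
    an exact decimal quantity like 1.875e-8 is treated as such) and then
    rounded half-up, the convention used for printed rates.
    """
    if x == 0 or not np.isfinite(x):
        return float(x)
    d = Decimal(f"{x:.12e}")
    shift = d.adjusted() - (n - 1)
    q = d.scaleb(-shift).quantize(Decimal(1), rounding=ROUND_HALF_UP).scaleb(shift)
    return float(q)

VERDICTS = ("confirmed_germline", "somatic", "false_positive", "untestable")


@dataclass(frozen=True)
class ValidationRecord:
    """Confirmation-genotyping verdict for one de novo candidate."""

    chrom: str
    pos: int
    verdict: str

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


class UnknownSiteError(KeyError):
    """Confirmation table refers to a site that is not a candidate."""


def validate_candidates(candidates: pd.DataFrame,
                        confirmation: Optional[pd.DataFrame]
                        ) -> Tuple[List[ValidationRecord], float]:
    """Per-candidate verdicts and the false-positive rate.

    ``candidates`` needs chrom, pos, ref, alt and the trio genotype codes.
    ``confirmation`` (may be None) has chrom, pos and confirmation
    genotypes ``sanger_father``, ``sanger_mother``, ``sanger_blood``,
    ``sanger_hair`` written as genotype strings like "A/G".  A candidate
    absent from the table is ``untestable``.  A tested candidate whose
    confirmation genotypes contradict the de novo call (the new allele is
    missing from the offspring's blood, or present in a parent) is a
    ``false_positive``; blood/hair discordance at a confirmed site marks
    it ``somatic``; otherwise ``confirmed_germline``.

    The FP rate is FP count / testable count.
    """
    conf_lut: Dict[Tuple[str, int], pd.Series] = {}
    if confirmation is not None and len(confirmation):
        cand_idx = set(zip(candidates["chrom"], candidates["pos"].astype(int)))
        for row in confirmation.itertuples():
            key = (row.chrom, int(row.pos))
            if key not in cand_idx:
                raise UnknownSiteError(f"confirmation site {key} is not a candidate")
            conf_lut[key] = row
    records: List[ValidationRecord] = []
    n_fp = n_testable = 0
    for row in candidates.itertuples():
        key = (row.chrom, int(row.pos))
        conf = conf_lut.get(key)
        if conf is None:
            records.append(ValidationRecord(row.chrom, int(row.pos), "untestable"))
            continue
        n_testable += 1
        alt = row.alt
        blood = set(str(conf.sanger_blood).split("/"))
        hair = set(str(conf.sanger_hair).split("/"))
        father = set(str(conf.sanger_father).split("/"))
        mother = set(str(conf.sanger_mother).split("/"))
        if alt not in blood or alt in father or alt in mother:
            verdict = "false_positive"
            n_fp += 1
        elif blood != hair:
            verdict = "somatic"
        else:
            verdict = "confirmed_germline"
        records.append(ValidationRecord(row.chrom, int(row.pos), verdict))
    fp_rate = n_fp / n_testable if n_testable else 0.0
    return records, fp_rate


def germline_count(n_candidates: int, fp_rate: float, n_somatic: int,
                   n_untestable: int = 0, n_fp_observed: Optional[int] = None
                   ) -> Tuple[int, int, int]:
    """Corrected germline de novo SNV count: (point, minimum, maximum).

    point    = n - round(n * fp_rate) - n_somatic
    minimum  = all untestable candidates assumed false positives
    maximum  = all untestable candidates assumed true
    """
    if not 0.0 <= fp_rate <= 1.0:
        raise ValueError("fp_rate must be in [0, 1]")
    n_fp = int(round(n_candidates * fp_rate))
    point = n_candidates - n_fp - n_somatic
    if n_fp_observed is None:
        n_fp_observed = n_fp
    lo = n_candidates - n_untestable - n_fp_observed - n_somatic
    hi = n_candidates - n_fp_observed - n_somatic
    if point < 0 or lo < 0:
        raise ValueError("corrections exceed the candidate count")
    return point, lo, hi


def per_generation_rate(n_germline: int, target_size_bp: float) -> float:
    """mu_g = n_germline / (2 * T): de novo SNVs per site per generation."""
    if target_size_bp <= 0:
        raise ValueError("target size must be positive")
    return n_germline / (2.0 * target_size_bp)


def per_year_rate(mu_g: float, parental_age_years: float) -> float:
    """mu_y = mu_g / a, with a = mean parental age at conception (years)."""
    if parental_age_years <= 0:
        raise ValueError("parental age must be positive")
    return mu_g / parental_age_years


def alternative_rate_with_exclusions(n_candidates: int, n_excluded: int,
                                     n_fp: int, target_size_adjusted_bp: float
                                     ) -> float:
    """Rate after excluding candidates (e.g. in segmental duplications).

    mu_g = (n_candidates - n_excluded - n_fp) / (2 * T_adjusted); the FP
    count is carried over unchanged from the primary analysis.
    """
    if n_excluded > n_candidates:
        raise ValueError("cannot exclude more candidates than exist")
    numerator = n_candidates - n_excluded - n_fp
    if numerator < 0:
        raise ValueError("corrections exceed the candidate count")
    return numerator / (2.0 * target_size_adjusted_bp)


@dataclass
class RateEstimate:
    """Corrected counts and derived per-generation / per-year rates."""

    n_candidates: int
    fp_rate: float
    n_somatic: int
    target_size_bp: float
    parental_age_years: float = 24.0
    fn_rate: float = 0.0
    n_untestable: int = 0
    n_fp_observed: Optional[int] = None

    n_fp: int = field(init=False)
    n_germline: int = field(init=False)
    n_germline_min: int = field(init=False)
    n_germline_max: int = field(init=False)
    mu_g: float = field(init=False)
    mu_g_min: float = field(init=False)
    mu_g_max: float = field(init=False)
    mu_y: float = field(init=False)

    def __post_init__(self):
        if not 0.0 <= self.fn_rate < 1.0:
            raise ValueError("fn_rate must be in [0, 1)")
        self.n_fp = int(round(self.n_candidates * self.fp_rate))
        self.n_germline, self.n_germline_min, self.n_germline_max = germline_count(
            self.n_candidates, self.fp_rate, self.n_somatic,
            self.n_untestable, self.n_fp_observed)
        correction = 1.0 - self.fn_rate
        self.mu_g = per_generation_rate(self.n_germline, self.target_size_bp) / correction
        self.mu_g_min = per_generation_rate(self.n_germline_min, self.target_size_bp) / correction
        self.mu_g_max = per_generation_rate(self.n_germline_max, self.target_size_bp) / correction
        self.mu_y = per_year_rate(self.mu_g, self.parental_age_years)

    def to_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "fp_rate": self.fp_rate,
            "n_fp": self.n_fp,
            "n_somatic": self.n_somatic,
            "n_germline": self.n_germline,
            "n_germline_min": self.n_germline_min,
            "n_germline_max": self.n_germline_max,
            "target_size_bp": self.target_size_bp,
            "parental_age_years": self.parental_age_years,
            "mu_per_generation": self.mu_g,
            "mu_per_generation_min": self.mu_g_min,
            "mu_per_generation_max": self.mu_g_max,
            "mu_per_year": self.mu_y,
        }


@dataclass(frozen=True)
class PhyloParams:
    """Inputs for the phylogenetic (divergence-based) rate."""

    d: float          # pairwise divergence, substitutions per site
    t: float          # divergence time, years
    g: float          # generation time, years
    ne: float         # ancestral effective population size (diploids)

    def __post_init__(self):
        if min(self.d, self.t, self.g) <= 0 or self.ne < 0:
            raise ValueError("d, t, g must be positive and Ne non-negative")


def phylogenetic_rate(params: PhyloParams) -> Tuple[float, float]:
    """(per-year, per-generation) rate from divergence with ancestral
    polymorphism: mu_y = d / (2t + 4*Ne*g), mu_g = mu_y * g."""
    mu_y = params.d / (2.0 * params.t + 4.0 * params.ne * params.g)
    return mu_y, mu_y * params.g


def cpg_fraction(denovo_sites: pd.DataFrame, context: pd.DataFrame
                 ) -> Tuple[int, int, float]:
    """(n_cpg, n_with_context, fraction) of de novo SNVs on CpG sites.

    ``context`` maps pos -> (prev, base, next) reference bases; a site is
    CpG when its reference dinucleotide reads CG on either strand
    (base='C' with next='G', or base='G' with prev='C').  Sites missing
    from the context table are excluded from the denominator.
    """
    ctx = context.set_index("pos")
    n_cpg = n_ctx = 0
    for pos in denovo_sites["pos"].astype(int):
        if pos not in ctx.index:
            continue
        row = ctx.loc[pos]
        n_ctx += 1
        if (row["base"] == "C" and row["next"] == "G") or \
           (row["base"] == "G" and row["prev"] == "C"):
            n_cpg += 1
    frac = n_cpg / n_ctx if n_ctx else float("nan")
    return n_cpg, n_ctx, frac
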