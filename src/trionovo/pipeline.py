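"""End-to-end analysis: simulate -> filter -> classify -> cluster -> phase -> rate.

`run_analysis` is the in-memory engine (used by tests and the acceptance
script); `run_pipeline` wraps it with file outputs, logging and a summary
JSON.  All randomness derives from the simulation config seed, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as tio
from .conversion import (DistanceNull, bootstrap_distance_ci, cluster_cnivs,
                         events_to_frame)
from .intervals import RegionSet, union_all
from .mie import (MieCategory, MieDetectionResult, classify_mies, detect_mies,
                  segment_half_depth)
from .phasing import assign_origin, calls_to_frame, informative_sites, paternal_fraction
from .rates import RateEstimate
from .regions import (DEFAULT_PREMAX, DEFAULT_PREMIN, build_target_regions,
                      compute_depth_bounds, filter_allele_strand_bias,
                      filter_depth, filter_indels, filter_read_balance,
                      filter_read_ends)
from .simulate import (FATHER, MOTHER, OFFSPRING, HOM_REF, SimConfig, TrioSim,
                       call_genotypes, simulate_depth_track, simulate_fragments,
                       simulate_observations, simulate_trio,
                       subsample_observations)

log = logging.getLogger("trionovo")

INDIVIDUALS = (FATHER, MOTHER, OFFSPRING)


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the analysis stages."""

    premin: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PREMIN))
    premax: int = DEFAULT_PREMAX
    min_per_strand: int = 10
    indel_pad: int = 50
    bias_pad: int = 10
    end_pad: int = 10
    het_pl_threshold: float = 200.0
    hom_pl_threshold: float = 100.0
    window_bp: int = 1000
    half_depth_threshold: float = 0.75
    cluster_reps: int = 2000
    cluster_level: float = 0.99
    cluster_threshold: Optional[float] = None
    phase_max_distance: int = 500
    fragments_per_site: float = 30.0
    parental_age_years: float = 24.0
    fp_rate: float = 0.0
    fn_rate: float = 0.0


@dataclass
class AnalysisResult:
    """Everything the pipeline computed for one simulated trio."""

    sim: TrioSim
    trio_table: pd.DataFrame
    target_regions: RegionSet
    filter_report: "object"
    mies: MieDetectionResult
    conversion_null: Optional[DistanceNull]
    conversion_events: pd.DataFrame
    origin_calls: pd.DataFrame
    rate: RateEstimate
    n_somatic_detected: int
    deletion_segments: Dict[str, RegionSet]

    @property
    def mie_table(self) -> pd.DataFrame:
        return self.mies.to_frame()

    def category_counts(self) -> Dict[str, int]:
        counts = {c.value: 0 for c in MieCategory}
        for r in self.mies.records:
            counts[r.category.value] += 1
        return counts

    def summary(self) -> dict:
        counts = self.category_counts()
        out = {
            "seed": self.sim.config.seed,
            "n_sites_tested": self.mies.n_sites_tested,
            "n_skipped_missing": self.mies.n_skipped_missing,
            "n_mies": len(self.mies.records),
            "category_counts": counts,
            "n_conversion_events": int(len(self.conversion_events)),
            "n_somatic_detected": self.n_somatic_detected,
            "filter_report": self.filter_report.to_dict(),
            "rate": self.rate.to_dict(),
            "conversion_null": (self.conversion_null.to_dict()
                                if self.conversion_null else None),
        }
        assigned = self.origin_calls[self.origin_calls["origin"] != "unassigned"] \
            if len(self.origin_calls) else self.origin_calls
        out["n_origin_assigned"] = int(len(assigned))
        if len(assigned):
            n_f = int((assigned["origin"] == "father").sum())
            out["paternal_fraction"] = n_f / len(assigned)
        return out


def build_trio_table(sim: TrioSim, params: AnalysisParams,
                     coverage_fraction: float = 1.0) -> pd.DataFrame:
    """Simulate observations for the trio and call genotypes at every site."""
    cfg = sim.config
    ss = np.random.SeedSequence([cfg.seed, 7])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    table = sim.site_table.copy()
    for ind, seed in zip(INDIVIDUALS, seeds):
        genome = sim.genome(ind, tissue="blood")
        obs = simulate_observations(genome, sim.site_table, cfg.coverage_of(ind),
                                    cfg.base_error, seed, cfg.read_length)
        if coverage_fraction < 1.0:
            obs = subsample_observations(obs, coverage_fraction, seed + 1)
        obs = call_genotypes(obs, cfg.base_error, params.het_pl_threshold,
                             params.hom_pl_threshold)
        for col in ("depth", "rf", "rr", "af", "ar", "end_dist", "gt", "qual",
                    "status"):
            table[f"{col}_{ind}"] = obs[col].to_numpy()
    return table


def run_analysis(sim: TrioSim, params: AnalysisParams = AnalysisParams(),
                 coverage_fraction: float = 1.0) -> AnalysisResult:
    cfg = sim.config
    ss = np.random.SeedSequence([cfg.seed, 11])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]

    # depth tracks (coverage titration scales the track coverage directly)
    tracks = {}
    for ind, seed in zip(INDIVIDUALS, seeds[:3]):
        cov = cfg.coverage_of(ind) * coverage_fraction
        tracks[ind] = simulate_depth_track(sim, ind, seed, coverage=cov)

    trio_table = build_trio_table(sim, params, coverage_fraction)

    # target regions
    bounds = {ind: compute_depth_bounds(tracks[ind], params.premin[ind],
                                        params.premax) for ind in INDIVIDUALS}
    removals = {
        "depth": filter_depth(tracks, bounds),
        "read_balance": filter_read_balance(tracks, params.min_per_strand),
        "indels": filter_indels(sim.indel_positions, params.indel_pad),
        "allele_strand_bias": filter_allele_strand_bias(trio_table, params.bias_pad),
        "read_ends": filter_read_ends(trio_table, params.end_pad),
    }
    target, report = build_target_regions(cfg.chrom_lengths, removals,
                                          sim.repeat_mask)

    # MIE detection + classification
    mies = detect_mies(trio_table, target)
    classify_mies(mies, tracks, params.window_bp, params.half_depth_threshold)

    # conversion clustering
    cniv_pos: Dict[str, List[int]] = {}
    for r in mies.records:
        if r.category is MieCategory.CNIV:
            cniv_pos.setdefault(r.chrom, []).append(r.pos)
    n_cniv = sum(len(v) for v in cniv_pos.values())
    null = None
    threshold = params.cluster_threshold
    if threshold is None and n_cniv >= 2:
        null = bootstrap_distance_ci(n_cniv, target.total_length,
                                     params.cluster_reps, params.cluster_level,
                                     seed=seeds[3])
        threshold = null.lower
    events = (events_to_frame(cluster_cnivs(cniv_pos, threshold))
              if threshold is not None and n_cniv
              else events_to_frame([]))

    # de novo SNV candidates: somatic triage via the hair-follicle tissue
    candidates = [r for r in mies.records if r.category is MieCategory.DENOVO_SNV]
    n_somatic = 0
    if candidates:
        cand_tbl = pd.DataFrame({
            "chrom": [r.chrom for r in candidates],
            "pos": [r.pos for r in candidates],
            "ref": [r.ref for r in candidates],
            "alt": [r.alt for r in candidates]})
        hair_obs = simulate_observations(sim.offspring_hair, cand_tbl,
                                         cfg.coverage_offspring * coverage_fraction,
                                         cfg.base_error, seeds[4], cfg.read_length)
        hair_gt = call_genotypes(hair_obs, cfg.base_error,
                                 params.het_pl_threshold, params.hom_pl_threshold)
        for rec, gt, status in zip(candidates, hair_gt["gt"], hair_gt["status"]):
            if status == "pass" and gt == HOM_REF and rec.gt_offspring > HOM_REF:
                n_somatic += 1

    # parental-origin phasing
    calls = []
    if candidates:
        pos_by_chrom: Dict[str, List[int]] = {}
        for r in candidates:
            pos_by_chrom.setdefault(r.chrom, []).append(r.pos)
        fragments = simulate_fragments(sim, pos_by_chrom, seeds[5],
                                       params.fragments_per_site)
        for r in candidates:
            info = informative_sites(trio_table, r.chrom, r.pos,
                                     params.phase_max_distance)
            call = assign_origin(r.chrom, r.pos, r.alt, fragments, info)
            r.origin = call.origin
            calls.append(call)
    origin_df = calls_to_frame(calls)

    rate = RateEstimate(n_candidates=len(candidates), fp_rate=params.fp_rate,
                        n_somatic=n_somatic, target_size_bp=target.total_length,
                        parental_age_years=params.parental_age_years,
                        fn_rate=params.fn_rate)

    segments = {ind: segment_half_depth(tracks[ind], params.window_bp,
                                        params.half_depth_threshold)
                for ind in INDIVIDUALS}

    return AnalysisResult(sim, trio_table, target, report, mies, null, events,
                          origin_df, rate, n_somatic, segments)


def run_pipeline(config: SimConfig, out_dir, params: AnalysisParams = AnalysisParams()
                 ) -> dict:
    """Simulate a trio, run the full analysis and write all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("simulating trio: seed=%d genome=%d bp x %d chrom",
             config.seed, config.genome_length, config.n_chromosomes)
    sim = simulate_trio(config)
    result = run_analysis(sim, params)
    log.info("detected %d MIEs in %d tested sites", len(result.mies.records),
             result.mies.n_sites_tested)

    tio.write_vcf(result.trio_table, out / "trio.vcf", config.chrom_lengths)
    tio.write_bed(result.target_regions, out / "target_regions.bed")
    tio.write_bed(sim.repeat_mask, out / "repeat_mask.bed")
    tio.write_table(result.mie_table, out / "mie_table.tsv")
    tio.write_table(result.conversion_events, out / "conversion_events.tsv")
    tio.write_table(result.origin_calls, out / "origin_calls.tsv")
    tio.write_table(sim.truth.denovo_snvs, out / "truth_denovo_snvs.tsv")
    for name, segs in result.deletion_segments.items():
        tio.write_bed(segs, out / f"half_depth_segments_{name}.bed")
    summary = result.summary()
    summary["config"] = _config_dict(config)
    tio.write_json(summary, out / "summary.json")
    return summary


def _config_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["hemizygous_deletions"] = [list(x) for x in d["hemizygous_deletions"]]
    d["denovo_deletions"] = list(d["denovo_deletions"])
    return d
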