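"""Target-region filters: depth bounds, strand balance, pads, assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trionovo import (DepthBounds, RegionSet, build_target_regions,
                      compute_depth_bounds, filter_allele_strand_bias,
                      filter_depth, filter_indels, filter_read_balance,
                      filter_read_ends)
from trionovo.regions import EmptyTargetError, UnconfigurableBoundsError
from trionovo.simulate import DepthTrack, HET, HOM_REF, HOM_ALT
from trionovo.intervals import union_all


def track_from(depth, fwd=None):
    depth = np.asarray(depth, dtype=np.int32)
    if fwd is None:
        fwd = depth // 2
    return DepthTrack({"chr1": depth}, {"chr1": np.asarray(fwd, dtype=np.int32)})


# -- depth bounds ------------------------------------------------------------

def test_constant_depth_gives_degenerate_bounds():
    b = compute_depth_bounds(track_from(np.full(1000, 100)), premin=15)
    assert (b.mean, b.sd, b.lower, b.upper) == (100.0, 0.0, 100.0, 100.0)


def test_preclamp_excludes_pathological_pileups():
    depth = np.concatenate([np.full(999, 90), [10_000]])
    b = compute_depth_bounds(track_from(depth), premin=15, premax=512)
    assert b.mean == 90.0 and b.sd == 0.0


def test_poisson_bounds_match_closed_form():
    rng = np.random.default_rng(0)
    depth = rng.poisson(150, size=100_000)
    b = compute_depth_bounds(track_from(depth), premin=15, premax=512)
    assert b.mean == pytest.approx(150, rel=0.02)
    assert b.lower == pytest.approx(150 - 3 * np.sqrt(150), rel=0.02)
    assert b.upper == pytest.approx(150 + 3 * np.sqrt(150), rel=0.02)


def test_empty_preclamp_range_errors():
    with pytest.raises(UnconfigurableBoundsError):
        compute_depth_bounds(track_from(np.full(100, 5)), premin=15)


# -- per-site filters --------------------------------------------------------

def _bounds(mean, sd):
    return DepthBounds.from_moments(mean, sd, 15, 512)


def test_filter_depth_at_mean_retains_and_outlier_removes():
    tracks = {"father": track_from(np.full(100, 150)),
              "mother": track_from(np.full(100, 150)),
              "offspring": track_from(np.full(100, 150))}
    bounds = {k: _bounds(150, 10) for k in tracks}
    assert filter_depth(tracks, bounds).total_length == 0
    bad = np.full(100, 150)
    bad[42] = int(bounds["offspring"].upper) + 1
    tracks["offspring"] = track_from(bad)
    removed = filter_depth(tracks, bounds)
    assert list(removed) == [("chr1", 42, 43)]


def test_filter_depth_removal_fraction_matches_poisson_oracle():
    rng = np.random.default_rng(1)
    n = 200_000
    tracks = {k: track_from(rng.poisson(150, n)) for k in ("father", "mother", "offspring")}
    bounds = {k: _bounds(150, np.sqrt(150)) for k in tracks}
    removed = filter_depth(tracks, bounds).total_length / n
    lo, hi = 150 - 3 * np.sqrt(150), 150 + 3 * np.sqrt(150)
    p_one = stats.poisson.cdf(lo, 150) + stats.poisson.sf(hi, 150)
    expected = 1 - (1 - p_one) ** 3
    assert removed == pytest.approx(expected, abs=3 * np.sqrt(expected / n) + 5e-4)


def test_read_balance_boundary_inclusive():
    n = 3
    mk = lambda fwd, rev: track_from(np.full(n, fwd + rev), np.full(n, fwd))
    tracks = {"father": mk(10, 10), "mother": mk(10, 10), "offspring": mk(10, 10)}
    assert filter_read_balance(tracks).total_length == 0
    tracks["father"] = mk(9, 50)
    assert filter_read_balance(tracks).total_length == n


def test_indel_pad_and_merge():
    assert list(filter_indels({"chr1": np.array([1000])})) == [("chr1", 950, 1051)]
    assert list(filter_indels({"chr1": np.array([1000, 1040])})) == [("chr1", 950, 1091)]
    # isolated indels remove exactly 101 bp each
    pos = np.arange(10) * 500 + 100
    assert filter_indels({"chr1": pos}).total_length == 101 * len(pos)


def _bias_row(gt, rf, rr, af, ar, pos=5000):
    row = {"chrom": "chr1", "pos": pos, "ref": "A", "alt": "G"}
    for ind in ("father", "mother", "offspring"):
        row.update({f"gt_{ind}": HOM_REF, f"rf_{ind}": 20, f"rr_{ind}": 20,
                    f"af_{ind}": 0, f"ar_{ind}": 0})
    row.update({"gt_offspring": gt, "rf_offspring": rf, "rr_offspring": rr,
                "af_offspring": af, "ar_offspring": ar})
    return row


def test_strand_bias_examples():
    # ref allele A seen on 18 forward / 0 reverse reads: biased, removed +/-10
    biased = pd.DataFrame([_bias_row(HET, 18, 0, 19, 22)])
    assert list(filter_allele_strand_bias(biased)) == [("chr1", 4990, 5011)]
    # both alleles on both strands: retained
    clean = pd.DataFrame([_bias_row(HET, 20, 12, 15, 18)])
    assert filter_allele_strand_bias(clean).total_length == 0
    # homozygous-alt: no reference reads expected, AF/AR >= 1 suffices
    hom_alt = pd.DataFrame([_bias_row(HOM_ALT, 0, 0, 70, 75)])
    assert filter_allele_strand_bias(hom_alt).total_length == 0
    hom_alt_biased = pd.DataFrame([_bias_row(HOM_ALT, 0, 0, 140, 0)])
    assert filter_allele_strand_bias(hom_alt_biased).total_length == 21


def test_read_end_filter_boundary():
    def row(dist):
        r = _bias_row(HET, 40, 40, 35, 35)
        for ind in ("father", "mother", "offspring"):
            r[f"end_dist_{ind}"] = 25.0
        r["end_dist_offspring"] = dist
        return pd.DataFrame([r])
    assert filter_read_ends(row(5.0)).total_length == 21
    assert filter_read_ends(row(10.0)).total_length == 21   # boundary inclusive
    assert filter_read_ends(row(11.0)).total_length == 0


# -- assembly ----------------------------------------------------------------

def test_build_target_identity_and_mask():
    lengths = {"chr1": 1_000_000}
    target, report = build_target_regions(lengths, {})
    assert target.total_length == 1_000_000
    assert report.retained_pct == 100.0
    mask = RegionSet([("chr1", 0, 100_000)])
    target, report = build_target_regions(lengths, {}, repeat_mask=mask)
    assert target.total_length == 900_000
    assert report.per_filter_bp["repeat_mask"] == 100_000


def test_build_target_overlapping_removals_union_arithmetic():
    lengths = {"chr1": 10_000}
    removals = {"a": RegionSet([("chr1", 0, 2_000)]),
                "b": RegionSet([("chr1", 1_000, 3_000)])}
    target, report = build_target_regions(lengths, removals)
    union = union_all(removals.values())
    assert target.total_length + union.total_length == 10_000
    # per-filter bp counted per filter, so the sum exceeds the union
    assert sum(report.per_filter_bp.values()) == 4_000 > union.total_length


def test_build_target_idempotent_and_order_independent():
    lengths = {"chr1": 10_000}
    removals = {"a": RegionSet([("chr1", 100, 500)]),
                "b": RegionSet([("chr1", 400, 900)]),
                "c": RegionSet([("chr1", 5_000, 5_001)])}
    t1, _ = build_target_regions(lengths, removals)
    t2, _ = build_target_regions(lengths, dict(reversed(list(removals.items()))))
    assert t1 == t2
    # subtracting the removals again changes nothing
    assert t1.subtract(union_all(removals.values())) == t1


def test_build_target_monotone_in_filters():
    lengths = {"chr1": 10_000}
    a = {"a": RegionSet([("chr1", 0, 1_000)])}
    ab = dict(a, b=RegionSet([("chr1", 2_000, 2_500)]))
    t_a, _ = build_target_regions(lengths, a)
    t_ab, _ = build_target_regions(lengths, ab)
    assert t_ab.total_length <= t_a.total_length


def test_empty_target_is_an_error():
    with pytest.raises(EmptyTargetError):
        build_target_regions({"chr1": 100}, {"all": RegionSet([("chr1", 0, 100)])})
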