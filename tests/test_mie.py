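"""MIE detection against a brute-force assortment oracle; classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from trionovo import (MieCategory, MieRecord, RegionSet, classify_mie,
                      classify_mies, depth_ratio, detect_mies,
                      mendelian_consistent, offspring_novel_allele,
                      segment_half_depth)
from trionovo.simulate import DepthTrack, HOM_REF, HET, HOM_ALT

GENOTYPES = (HOM_REF, HET, HOM_ALT)
ALLELES = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}


def assortment_oracle(gf, gm, go):
    """Brute force: can any (paternal, maternal) allele pair give the child?"""
    child = tuple(sorted(ALLELES[go]))
    return any(tuple(sorted((a, b))) == child
               for a in ALLELES[gf] for b in ALLELES[gm])


def test_detection_matches_assortment_oracle_all_27_trios():
    for gf, gm, go in itertools.product(GENOTYPES, repeat=3):
        assert bool(mendelian_consistent(gf, gm, go)) == assortment_oracle(gf, gm, go), \
            (gf, gm, go)


def test_known_mie_and_mendelian_cases():
    # both parents hom-ref, offspring het: the textbook de novo configuration
    assert not mendelian_consistent(HOM_REF, HOM_REF, HET)
    # het father can donate the alternate allele
    assert mendelian_consistent(HET, HOM_REF, HET)


def trio_row(gf, gm, go, pos=100, status="pass"):
    row = {"chrom": "chr1", "pos": pos, "ref": "A", "alt": "G",
           "gt_father": gf, "gt_mother": gm, "gt_offspring": go}
    for ind in ("father", "mother", "offspring"):
        row[f"status_{ind}"] = status
    return row


def test_detect_mies_skips_missing_and_respects_target():
    df = pd.DataFrame([
        trio_row(HOM_REF, HOM_REF, HET, pos=100),
        trio_row(HOM_REF, HOM_REF, HET, pos=200, status="filtered"),
        trio_row(HOM_REF, HOM_REF, HET, pos=10_000),  # outside target
        trio_row(HET, HOM_REF, HET, pos=300),         # Mendelian
    ])
    res = detect_mies(df, RegionSet([("chr1", 0, 1_000)]))
    assert [r.pos for r in res.records] == [100]
    assert res.n_skipped_missing == 1


# -- depth ratios ------------------------------------------------------------

def _const_track(value, n=10_000):
    d = np.full(n, value, dtype=np.int32)
    return DepthTrack({"chr1": d}, {"chr1": d // 2})


def test_depth_ratio_identity_and_half():
    a = _const_track(150)
    assert depth_ratio("chr1", 0, 1000, a, _const_track(150)) == pytest.approx(1.0)
    # offspring at half coverage in the window (deletion), same genome mean
    d = np.full(10_000, 150, dtype=np.int32)
    d[:1000] = 75
    b = DepthTrack({"chr1": d}, {"chr1": d // 2})
    r = depth_ratio("chr1", 0, 1000, a, b)
    assert r == pytest.approx(0.5 * 150 / b.genome_mean * 1, rel=0.01)


def test_depth_ratio_poisson_noise_tolerance():
    rng = np.random.default_rng(2)
    n, cov, win = 400_000, 150, 1000
    a = DepthTrack({"chr1": rng.poisson(cov, n).astype(np.int32)}, {"chr1": np.zeros(n, np.int32)})
    b = DepthTrack({"chr1": rng.poisson(cov, n).astype(np.int32)}, {"chr1": np.zeros(n, np.int32)})
    ratios = [depth_ratio("chr1", s, s + win, a, b) for s in range(0, n, win)]
    within = np.mean([abs(r - 1.0) <= 0.1 for r in ratios])
    assert within >= 0.95


# -- classification ----------------------------------------------------------

def mk_record(gf, gm, go):
    return MieRecord("chr1", 100, "A", "G", gf, gm, go)


@pytest.mark.parametrize("gf,gm,go,half,expected", [
    (HOM_REF, HOM_REF, HET, (False, False, False), MieCategory.DENOVO_SNV),
    (HET, HOM_ALT, HOM_REF, (False, False, False), MieCategory.CNIV),
    (HOM_REF, HOM_ALT, HOM_REF, (False, True, True), MieCategory.HDIV),
    (HOM_REF, HOM_ALT, HOM_REF, (True, False, True), MieCategory.HDIV),
    (HOM_REF, HOM_ALT, HOM_REF, (False, False, True), MieCategory.DENOVO_CNV),
    (HOM_REF, HOM_ALT, HOM_REF, (True, True, True), MieCategory.UNCLASSIFIED),
    (HOM_REF, HOM_ALT, HOM_REF, (True, False, False), MieCategory.UNCLASSIFIED),
])
def test_classification_decision_table(gf, gm, go, half, expected):
    rec = classify_mie(mk_record(gf, gm, go), *half)
    assert rec.category is expected


def test_every_flag_combination_gets_exactly_one_category():
    for gf, gm, go in itertools.product(GENOTYPES, repeat=3):
        if assortment_oracle(gf, gm, go):
            continue
        for flags in itertools.product([False, True], repeat=3):
            rec = classify_mie(mk_record(gf, gm, go), *flags)
            assert rec.category in MieCategory


def test_novel_allele_definition():
    assert offspring_novel_allele(HOM_REF, HOM_REF, HET)
    assert offspring_novel_allele(HOM_ALT, HOM_ALT, HET)   # back-mutation to ref
    assert not offspring_novel_allele(HET, HOM_ALT, HOM_REF)  # inherited alleles


def test_classify_mies_uses_depth_windows(rich_sim, rich_result, rich_truth):
    """Per-category agreement with truth inside the target regions."""
    res = rich_result
    pred = {(r.chrom, r.pos): r.category.value for r in res.mies.records}
    in_target = rich_truth[
        res.target_regions.contains("chr1", rich_truth["pos"].to_numpy())]
    agree = sum(pred.get((c, p)) == cat for c, p, cat in
                zip(in_target["chrom"], in_target["pos"], in_target["category"]))
    assert agree / len(in_target) >= 0.9


# -- half-depth segmentation -------------------------------------------------

def test_segment_half_depth_recovers_injected_deletion():
    rng = np.random.default_rng(3)
    n, cov, win = 200_000, 150, 1000
    d = rng.poisson(cov, n)
    d[50_000:85_000] = rng.poisson(cov / 2, 35_000)   # 35-kb hemizygous deletion
    track = DepthTrack({"chr1": d.astype(np.int32)}, {"chr1": np.zeros(n, np.int32)})
    segs = list(segment_half_depth(track, window_bp=win))
    assert len(segs) == 1
    _, s, e = segs[0]
    assert abs(s - 50_000) <= win and abs(e - 85_000) <= win


def test_segment_half_depth_no_deletions_no_segments():
    rng = np.random.default_rng(4)
    track = DepthTrack({"chr1": rng.poisson(150, 100_000).astype(np.int32)},
                       {"chr1": np.zeros(100_000, np.int32)})
    assert len(segment_half_depth(track, window_bp=1000)) == 0


def test_segment_half_depth_offspring_only_deletion():
    """An 11-kb offspring-only deletion flags a de novo CNV segment."""
    rng = np.random.default_rng(5)
    n = 100_000
    tracks = {}
    for ind in ("father", "mother", "offspring"):
        d = rng.poisson(150, n)
        if ind == "offspring":
            d[40_000:51_000] = rng.poisson(75, 11_000)
        tracks[ind] = DepthTrack({"chr1": d.astype(np.int32)},
                                 {"chr1": np.zeros(n, np.int32)})
    segs = {ind: segment_half_depth(t, window_bp=1000) for ind, t in tracks.items()}
    assert len(segs["father"]) == 0 and len(segs["mother"]) == 0
    assert len(segs["offspring"]) == 1


def test_no_mie_inside_repeat_mask(rich_sim, rich_result):
    mask = rich_sim.repeat_mask
    for r in rich_result.mies.records:
        assert not mask.contains(r.chrom, np.array([r.pos]))[0]
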