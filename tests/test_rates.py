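"""Validation bookkeeping and rate arithmetic."""

import numpy as np
import pandas as pd
import pytest

from trionovo import (PhyloParams, RateEstimate, alternative_rate_with_exclusions,
                      cpg_fraction, germline_count, per_generation_rate,
                      per_year_rate, phylogenetic_rate, reference_context,
                      validate_candidates)
from trionovo.rates import UnknownSiteError


def _candidates(n):
    return pd.DataFrame({"chrom": "chr1", "pos": np.arange(n) * 1000,
                         "ref": "A", "alt": "G"})


def _confirmation(cand, fp_rows=(), somatic_rows=()):
    rows = []
    for row in cand.itertuples():
        base = {"chrom": row.chrom, "pos": row.pos,
                "sanger_father": "A/A", "sanger_mother": "A/A",
                "sanger_blood": "A/G", "sanger_hair": "A/G"}
        if row.Index in fp_rows:
            base["sanger_blood"] = "A/A"
            base["sanger_hair"] = "A/A"
        elif row.Index in somatic_rows:
            base["sanger_hair"] = "A/A"
        rows.append(base)
    return pd.DataFrame(rows)


def test_fp_rate_eight_of_forty():
    cand = _candidates(45)
    conf = _confirmation(cand.iloc[:40], fp_rows=set(range(8)), somatic_rows={40 - 1})
    records, fp_rate = validate_candidates(cand, conf)
    assert fp_rate == pytest.approx(8 / 40)
    verdicts = pd.Series([r.verdict for r in records]).value_counts()
    assert verdicts["false_positive"] == 8
    assert verdicts["somatic"] == 1
    assert verdicts["untestable"] == 5
    assert verdicts["confirmed_germline"] == 31


def test_blood_hair_discordance_is_somatic():
    cand = _candidates(1)
    conf = _confirmation(cand, somatic_rows={0})
    records, fp_rate = validate_candidates(cand, conf)
    assert records[0].verdict == "somatic"
    assert fp_rate == 0.0


def test_parent_carrying_allele_is_false_positive():
    cand = _candidates(1)
    conf = _confirmation(cand)
    conf.loc[0, "sanger_father"] = "A/G"
    records, fp_rate = validate_candidates(cand, conf)
    assert records[0].verdict == "false_positive" and fp_rate == 1.0


def test_unknown_confirmation_site_is_an_error():
    cand = _candidates(2)
    conf = _confirmation(cand)
    conf.loc[0, "pos"] = 999_999
    with pytest.raises(UnknownSiteError):
        validate_candidates(cand, conf)


def test_germline_count_corrections():
    assert germline_count(45, 0.2, 1)[0] == 35
    assert germline_count(45, 0.0, 0) == (45, 45, 45)
    # 40 fully-testable candidates with the exact 8/40 rate
    assert germline_count(40, 8 / 40, 1)[0] == 31
    # the full accounting: 5 untestable, 8 observed FPs, 1 somatic
    assert germline_count(45, 0.2, 1, n_untestable=5, n_fp_observed=8) == (35, 31, 36)
    with pytest.raises(ValueError):
        germline_count(5, 1.0, 1)


def test_per_generation_rate_printed_values():
    assert per_generation_rate(35, 1.182e9) == pytest.approx(1.48e-8, rel=5e-3)
    assert per_generation_rate(31, 1.182e9) == pytest.approx(1.31e-8, rel=5e-3)
    assert per_generation_rate(36, 1.182e9) == pytest.approx(1.52e-8, rel=5e-3)
    assert per_generation_rate(0, 1e9) == 0.0


def test_per_year_rate():
    mu_g = per_generation_rate(35, 1.182e9)
    # 6.17e-10 rounds to 0.62e-9 at the 2-significant-figure display precision
    assert float(f"{per_year_rate(mu_g, 24):.2g}") == 0.62e-9
    assert per_year_rate(mu_g, 1) == mu_g
    assert per_year_rate(1.2e-8, 20) == pytest.approx(0.60e-9, rel=1e-9)


def test_alternative_rate_with_exclusions():
    # two candidates in segmental duplications excluded, smaller target
    assert alternative_rate_with_exclusions(45, 2, 9, 1.170e9) == \
        pytest.approx(1.45e-8, rel=5e-3)
    assert alternative_rate_with_exclusions(45, 0, 0, 1.182e9) == \
        per_generation_rate(45, 1.182e9)
    with pytest.raises(ValueError):
        alternative_rate_with_exclusions(45, 46, 0, 1e9)
    with pytest.raises(ValueError):
        alternative_rate_with_exclusions(10, 5, 6, 1e9)


def test_rate_estimate_invariants():
    est = RateEstimate(n_candidates=45, fp_rate=0.2, n_somatic=1,
                       target_size_bp=1.182e9, parental_age_years=24,
                       n_untestable=5, n_fp_observed=8)
    assert est.n_germline == est.n_candidates - est.n_fp - est.n_somatic == 35
    assert est.mu_g == pytest.approx(est.n_germline / (2 * est.target_size_bp))
    assert est.mu_y == pytest.approx(est.mu_g / 24)
    assert (est.n_germline_min, est.n_germline_max) == (31, 36)
    # a nonzero FN rate scales the rate up by 1/(1-FN)
    est_fn = RateEstimate(n_candidates=45, fp_rate=0.2, n_somatic=1,
                          target_size_bp=1.182e9, fn_rate=0.1)
    assert est_fn.mu_g == pytest.approx(est.mu_g / 0.9)


def test_phylogenetic_rate_both_scenarios_and_limits():
    mu_y, mu_g = phylogenetic_rate(PhyloParams(d=0.012, t=6e6, g=20, ne=1e4))
    assert mu_g == pytest.approx(1.88e-8, rel=5e-3)
    assert mu_y == pytest.approx(0.94e-9, rel=5e-3)
    mu_y, mu_g = phylogenetic_rate(PhyloParams(d=0.012, t=6e6, g=20, ne=1e5))
    assert mu_g == pytest.approx(1.20e-8, rel=5e-3)
    assert mu_y == pytest.approx(0.60e-9, rel=5e-3)
    # no ancestral polymorphism: mu_y -> d / 2t
    mu_y, _ = phylogenetic_rate(PhyloParams(d=0.012, t=6e6, g=20, ne=0))
    assert mu_y == pytest.approx(0.012 / 1.2e7)


def test_phylogenetic_rate_monotone_decreasing():
    base = dict(d=0.012, t=6e6, g=20, ne=1e4)
    mu0 = phylogenetic_rate(PhyloParams(**base))[0]
    for key, factor in (("t", 2), ("g", 2), ("ne", 10)):
        mod = dict(base, **{key: base[key] * factor})
        assert phylogenetic_rate(PhyloParams(**mod))[0] < mu0


def test_cpg_fraction():
    # 31 sites, 9 on CpG: context built by hand
    rows = []
    for i in range(31):
        if i < 9:
            rows.append({"pos": i, "prev": "A", "base": "C", "next": "G"})
        else:
            rows.append({"pos": i, "prev": "A", "base": "A", "next": "T"})
    sites = pd.DataFrame({"pos": range(31)})
    n_cpg, n_ctx, frac = cpg_fraction(sites, pd.DataFrame(rows))
    assert (n_cpg, n_ctx) == (9, 31)
    assert frac == pytest.approx(9 / 31, abs=1e-12)
    # reverse strand: G preceded by C is also CpG
    ctx = pd.DataFrame([{"pos": 0, "prev": "C", "base": "G", "next": "T"}])
    assert cpg_fraction(pd.DataFrame({"pos": [0]}), ctx)[0] == 1


def test_cpg_fraction_matches_positional_scan():
    """Hash-generated reference: fraction equals a direct dinucleotide scan."""
    seed, gc = 17, 0.5
    pos = np.arange(2, 5_000, 7)
    ctx = reference_context(pos, seed, gc)
    n_cpg, n_ctx, frac = cpg_fraction(pd.DataFrame({"pos": pos}), ctx)
    from trionovo import reference_base
    bases = reference_base(np.arange(0, 5_002), seed, gc)
    brute = sum(1 for p in pos
                if (bases[p] == "C" and bases[p + 1] == "G")
                or (bases[p] == "G" and bases[p - 1] == "C"))
    assert n_cpg == brute and n_ctx == len(pos)
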