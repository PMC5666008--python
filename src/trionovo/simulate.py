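"""Synthetic parent-offspring trio generator.

Produces diploid parental genomes with realistic autosomal SNV density,
heterozygosity and Ti/Tv, transmits haplotypes to an offspring under
Mendelian assortment, and injects the event classes the downstream
analysis is designed to recover:

* germline de novo SNVs (per-haploid-transmission rate ``mu_denovo``),
* somatic de novo SNVs (present in the blood tissue only),
* allelic-conversion tracts (one offspring allele overwritten by its
  homolog, producing loss-of-heterozygosity clusters),
* inherited hemizygous deletions (one parental haplotype lost and
  transmitted to the offspring),
* de novo microdeletions (one offspring haplotype lost).

Sequencing observations are simulated site-wise: Poisson depth (halved
over hemizygous intervals), even forward/reverse strand split, and a
symmetric ref<->alt base-miscall probability.  Ground truth for every
injected event is recorded so parameter recovery can be tested.

The reference sequence is implicit: each position's reference base is a
deterministic hash of (seed, position) under a configurable GC content,
so contexts (e.g. CpG) are reproducible without storing a sequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import RegionSet

BASES = np.array(["A", "C", "G", "T"])
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}

# genotype codes
HOM_REF, HET, HOM_ALT = 0, 1, 2
GT_MISSING = -1

FATHER, MOTHER, OFFSPRING = "father", "mother", "offspring"


class UnplaceableEventError(RuntimeError):
    """Raised when injected intervals cannot be placed without overlap."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic trio.

    Defaults follow the sequenced chimpanzee trio: autosomal SNV density
    0.118%, heterozygosity 0.076%, Ti/Tv 1.98, ultra-deep (~150x)
    coverage, paired-end 101-bp reads, genotype-quality (PL-gap)
    thresholds of 200 (het) / 100 (hom).
    """

    genome_length: int = 10_000_000
    n_chromosomes: int = 1
    snv_density: float = 0.00118
    heterozygosity: float = 0.00076
    titv_ratio: float = 1.98
    mu_denovo: float = 1.48e-8
    n_somatic: int = 1
    conversion_events: int = 3
    conversion_tract_mean_bp: float = 170.0
    hemizygous_deletions: Tuple[Tuple[str, int], ...] = ((MOTHER, 35_000),)
    denovo_deletions: Tuple[int, ...] = (4_000,)
    coverage_father: float = 150.0
    coverage_mother: float = 150.0
    coverage_offspring: float = 150.0
    base_error: float = 1e-3
    read_length: int = 101
    depth_cv: float = 0.25
    repeat_fraction: float = 0.2
    indel_density: float = 2.3e-4
    gc_content: float = 0.41
    seed: int = 0

    def __post_init__(self):
        for name in ("snv_density", "heterozygosity", "mu_denovo", "base_error",
                     "repeat_fraction", "indel_density", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.heterozygosity > self.snv_density:
            raise ValueError("heterozygosity cannot exceed snv_density")
        if min(self.coverage_father, self.coverage_mother, self.coverage_offspring) <= 0:
            raise ValueError("coverage must be positive")
        lengths = [ln for _, ln in self.hemizygous_deletions] + list(self.denovo_deletions)
        if lengths and self.genome_length < 10 * max(lengths):
            raise ValueError("genome_length must be >= 10x the largest deletion")
        if self.titv_ratio <= 0:
            raise ValueError("titv_ratio must be positive")
        if self.depth_cv < 0:
            raise ValueError("depth_cv must be non-negative")

    @property
    def chrom_names(self) -> Tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: self.genome_length for c in self.chrom_names}

    def coverage_of(self, individual: str) -> float:
        return {FATHER: self.coverage_father, MOTHER: self.coverage_mother,
                OFFSPRING: self.coverage_offspring}[individual]


def reference_base(positions: np.ndarray, seed: int, gc_content: float = 0.41) -> np.ndarray:
    """Deterministic per-position reference base (implicit reference).

    A 64-bit multiplicative hash of (seed, position) is mapped to A/C/G/T
    with P(C)=P(G)=gc/2.  The same (seed, gc) always yields the same base,
    so dinucleotide contexts are consistent across queries.
    """
    pos = np.asarray(positions, dtype=np.uint64)
    seed_mix = ((seed & 0xFFFFFFFFFFFFFFFF) * 0xC2B2AE3D27D4EB4F) & 0xFFFFFFFFFFFFFFFF
    h = (pos + np.uint64(1)) * np.uint64(0x9E3779B97F4A7C15)
    h ^= np.uint64(seed_mix)
    h = (h >> np.uint64(33)) ^ h
    u = h.astype(np.float64) / float(2**64)
    at = (1.0 - gc_content) / 2.0
    cuts = np.array([at, at + gc_content / 2.0, at + gc_content])
    return BASES[np.searchsorted(cuts, u)]


def reference_context(positions: np.ndarray, seed: int, gc_content: float = 0.41) -> pd.DataFrame:
    """(prev, base, next) reference bases for each position."""
    positions = np.asarray(positions, dtype=np.int64)
    return pd.DataFrame({
        "pos": positions,
        "prev": reference_base(positions - 1, seed, gc_content),
        "base": reference_base(positions, seed, gc_content),
        "next": reference_base(positions + 1, seed, gc_content),
    })


def _draw_alt(ref: np.ndarray, titv_ratio: float, rng: np.random.Generator) -> np.ndarray:
    """Alternate alleles with P(transition) = titv / (1 + titv)."""
    n = len(ref)
    is_ti = rng.random(n) < titv_ratio / (1.0 + titv_ratio)
    tv_pick = rng.integers(0, 2, n)
    alt = np.empty(n, dtype=object)
    for b in "ACGT":
        m = ref == b
        alt[m & is_ti] = TRANSITION[b]
        for k in (0, 1):
            alt[m & ~is_ti & (tv_pick == k)] = TRANSVERSIONS[b][k]
    return alt.astype("U1")


def is_transition(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    purine = np.isin(ref, ["A", "G"])
    alt_purine = np.isin(alt, ["A", "G"])
    return purine == alt_purine


def ti_tv_ratio(ref: np.ndarray, alt: np.ndarray) -> float:
    """Transition/transversion ratio of a variant set."""
    ti = int(is_transition(np.asarray(ref), np.asarray(alt)).sum())
    tv = len(ref) - ti
    if tv == 0:
        raise ValueError("no transversions; Ti/Tv undefined")
    return ti / tv


@dataclass
class DiploidGenome:
    """Variant-only representation of a diploid genome.

    ``variants`` holds, per variant position, the base carried by each
    haplotype (equal to ``ref`` where that haplotype is reference).
    ``deletions`` lists hemizygous intervals: ``(chrom, start, end, hap)``
    means haplotype ``hap`` is absent over ``[start, end)``.
    """

    variants: pd.DataFrame  # columns: chrom, pos, ref, alt, hap0, hap1
    deletions: List[Tuple[str, int, int, int]] = field(default_factory=list)
    tissue: str = "germline"

    def deleted_haps(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Per position: -1 if diploid, else index of the missing haplotype."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(len(positions), -1, dtype=np.int8)
        for c, s, e, hap in self.deletions:
            if c == chrom:
                out[(positions >= s) & (positions < e)] = hap
        return out

    def genotype_codes(self, chrom: str, positions: np.ndarray,
                       alt: np.ndarray) -> np.ndarray:
        """Apparent genotype codes (hemizygous sites appear homozygous)."""
        positions = np.asarray(positions, dtype=np.int64)
        sub = self.variants[self.variants["chrom"] == chrom]
        lut: Dict[int, Tuple[str, str]] = {
            int(p): (h0, h1)
            for p, h0, h1 in zip(sub["pos"], sub["hap0"], sub["hap1"])
        }
        ref_seed, ref_gc = _REF_SEED_CACHE.get(id(self), (0, 0.41))
        refs = reference_base(positions, ref_seed, ref_gc)
        deleted = self.deleted_haps(chrom, positions)
        codes = np.empty(len(positions), dtype=np.int8)
        for i, (p, a) in enumerate(zip(positions, alt)):
            h0, h1 = lut.get(int(p), (None, None))
            if h0 is None:
                h0 = h1 = refs[i]
            alleles = []
            if deleted[i] != 0:
                alleles.append(h0)
            if deleted[i] != 1:
                alleles.append(h1)
            n_alt = sum(x == a for x in alleles)
            if len(alleles) == 1:
                codes[i] = HOM_ALT if n_alt == 1 else HOM_REF
            else:
                codes[i] = (HOM_REF, HET, HOM_ALT)[n_alt]
        return codes

    def alt_dosage(self, chrom: str, positions: np.ndarray, alt: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray]:
        """(number of haplotypes carrying alt, ploidy) per position."""
        positions = np.asarray(positions, dtype=np.int64)
        sub = self.variants[self.variants["chrom"] == chrom]
        lut = {int(p): (h0, h1) for p, h0, h1 in zip(sub["pos"], sub["hap0"], sub["hap1"])}
        deleted = self.deleted_haps(chrom, positions)
        dosage = np.zeros(len(positions), dtype=np.int8)
        ploidy = np.where(deleted >= 0, 1, 2).astype(np.int8)
        for i, (p, a) in enumerate(zip(positions, alt)):
            pair = lut.get(int(p))
            if pair is None:
                continue
            for hap in (0, 1):
                if deleted[i] == hap:
                    continue
                if pair[hap] == a:
                    dosage[i] += 1
        return dosage, ploidy


# genotype_codes needs the reference-hash (seed, gc) of the simulation that
# made the genome; simulate_trio registers it here.
_REF_SEED_CACHE: Dict[int, Tuple[int, float]] = {}


@dataclass
class SimTruth:
    """Ground-truth event tables for a simulated trio."""

    denovo_snvs: pd.DataFrame       # chrom, pos, ref, alt, origin, somatic
    conversion_tracts: pd.DataFrame  # chrom, start, end, donor_hap
    hemizygous_deletions: pd.DataFrame  # parent, chrom, start, end
    denovo_deletions: pd.DataFrame  # chrom, start, end


@dataclass
class TrioSim:
    """A simulated trio: genomes per tissue, truth, masks and annotations."""

    config: SimConfig
    father: DiploidGenome
    mother: DiploidGenome
    offspring_blood: DiploidGenome
    offspring_hair: DiploidGenome
    truth: SimTruth
    repeat_mask: RegionSet
    indel_positions: Dict[str, np.ndarray]
    site_table: pd.DataFrame  # union of variant sites: chrom, pos, ref, alt

    def genome(self, individual: str, tissue: str = "blood") -> DiploidGenome:
        if individual == FATHER:
            return self.father
        if individual == MOTHER:
            return self.mother
        return self.offspring_blood if tissue == "blood" else self.offspring_hair


def _sample_positions(rng: np.random.Generator, L: int, n: int,
                      forbidden: Optional[set] = None) -> np.ndarray:
    """n distinct uniform positions in [0, L), avoiding ``forbidden``."""
    out: set = set()
    for _ in range(100):
        need = n - len(out)
        if need <= 0:
            break
        draw = rng.integers(0, L, size=int(need * 1.2) + 8)
        for p in draw:
            p = int(p)
            if forbidden is not None and p in forbidden:
                continue
            out.add(p)
            if len(out) == n:
                break
    if len(out) < n:
        raise UnplaceableEventError("could not place requested positions")
    return np.sort(np.fromiter(out, dtype=np.int64, count=n))


def _place_interval(rng: np.random.Generator, L: int, length: int,
                    reserved: List[Tuple[int, int]], retries: int = 200) -> Tuple[int, int]:
    for _ in range(retries):
        s = int(rng.integers(0, L - length))
        e = s + length
        if all(e <= rs or s >= re for rs, re in reserved):
            reserved.append((s, e))
            return s, e
    raise UnplaceableEventError(f"could not place a {length}-bp interval after {retries} tries")


def _parent_variants(rng: np.random.Generator, cfg: SimConfig, chrom: str,
                     shared: Optional[pd.DataFrame]) -> pd.DataFrame:
    L = cfg.genome_length
    n = rng.binomial(L, cfg.snv_density)
    pos = _sample_positions(rng, L, n)
    ref = reference_base(pos, cfg.seed, cfg.gc_content)
    alt = _draw_alt(ref, cfg.titv_ratio, rng)
    if shared is not None and len(shared):
        # positions already variant in the other parent share its alternate
        # allele (a shared ancestral polymorphism keeps sites biallelic)
        lut = dict(zip(shared["pos"].to_numpy(), shared["alt"].to_numpy()))
        for i, p in enumerate(pos):
            a = lut.get(int(p))
            if a is not None:
                alt[i] = a
    het = rng.random(n) < (cfg.heterozygosity / cfg.snv_density if cfg.snv_density else 0.0)
    het_hap = rng.integers(0, 2, n)
    hap0 = np.where(het, np.where(het_hap == 0, alt, ref), alt)
    hap1 = np.where(het, np.where(het_hap == 1, alt, ref), alt)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                         "hap0": hap0, "hap1": hap1})


def simulate_trio(config: SimConfig) -> TrioSim:
    """Generate a trio with Mendelian transmission plus injected events."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rngs = {name: np.random.default_rng(child) for name, child in
            zip(("parents", "transmit", "denovo", "events", "mask"), ss.spawn(5))}

    father_frames, mother_frames, off_frames = [], [], []
    denovo_rows, somatic_rows = [], []
    tract_rows, hemi_rows, dndel_rows = [], [], []
    father_dels, mother_dels, off_dels, off_dn_dels = [], [], [], []
    mask_frames: List[RegionSet] = []
    indel_positions: Dict[str, np.ndarray] = {}
    L = cfg.genome_length

    # distribute configured event counts across chromosomes (round-robin)
    chroms = cfg.chrom_names
    per_chrom_events: Dict[str, Dict[str, list]] = {c: {"conv": [], "hemi": [], "dndel": []}
                                                    for c in chroms}
    for k in range(cfg.conversion_events):
        per_chrom_events[chroms[k % len(chroms)]]["conv"].append(None)
    for k, spec in enumerate(cfg.hemizygous_deletions):
        per_chrom_events[chroms[k % len(chroms)]]["hemi"].append(spec)
    for k, length in enumerate(cfg.denovo_deletions):
        per_chrom_events[chroms[k % len(chroms)]]["dndel"].append(length)
    n_somatic_per_chrom = np.zeros(len(chroms), dtype=int)
    for k in range(cfg.n_somatic):
        n_somatic_per_chrom[k % len(chroms)] += 1

    for ci, chrom in enumerate(chroms):
        rng_p, rng_t = rngs["parents"], rngs["transmit"]
        rng_d, rng_e = rngs["denovo"], rngs["events"]

        fvars = _parent_variants(rng_p, cfg, chrom, None)
        mvars = _parent_variants(rng_p, cfg, chrom, fvars)
        reserved: List[Tuple[int, int]] = []

        # hemizygous deletions: parent loses one haplotype; the deleted
        # haplotype is the one transmitted, so the offspring is hemizygous too
        for parent, length in per_chrom_events[chrom]["hemi"]:
            s, e = _place_interval(rng_e, L, length, reserved)
            hap = int(rng_e.integers(0, 2))
            if parent == FATHER:
                father_dels.append((chrom, s, e, hap))
                off_dels.append((chrom, s, e, 0))
            elif parent == MOTHER:
                mother_dels.append((chrom, s, e, hap))
                off_dels.append((chrom, s, e, 1))
            else:
                raise ValueError(f"unknown parent {parent!r}")
            hemi_rows.append((parent, chrom, s, e))

        # de novo deletions: offspring loses one haplotype
        for length in per_chrom_events[chrom]["dndel"]:
            s, e = _place_interval(rng_e, L, length, reserved)
            hap = int(rng_e.integers(0, 2))
            off_dn_dels.append((chrom, s, e, hap))
            dndel_rows.append((chrom, s, e))

        # Mendelian transmission: offspring hap0 paternal, hap1 maternal.
        # Within a hemizygous deletion the parent's surviving haplotype is
        # the one NOT transmitted (the offspring inherited the deletion).
        def transmit(vars_df: pd.DataFrame, dels: list, rng: np.random.Generator
                     ) -> Dict[int, str]:
            pick = rng.integers(0, 2, len(vars_df))
            h0 = vars_df["hap0"].to_numpy()
            h1 = vars_df["hap1"].to_numpy()
            allele = np.where(pick == 0, h0, h1)
            return dict(zip(vars_df["pos"].astype(int), allele))

        pat = transmit(fvars, father_dels, rng_t)
        mat = transmit(mvars, mother_dels, rng_t)

        # germline de novo SNVs: Poisson(mu * L) per transmitted haplotype
        parental_pos = set(fvars["pos"].astype(int)) | set(mvars["pos"].astype(int))
        blocked = set()
        for s, e in reserved:
            blocked.update(range(s, e))
        forbidden = parental_pos | blocked
        n_pat = rng_d.poisson(cfg.mu_denovo * L)
        n_mat = rng_d.poisson(cfg.mu_denovo * L)
        dn_pos: List[Tuple[int, str]] = []
        if n_pat + n_mat:
            ps = _sample_positions(rng_d, L, n_pat + n_mat, forbidden)
            rng_d.shuffle(ps)
            dn_pos = [(int(p), FATHER) for p in ps[:n_pat]] + \
                     [(int(p), MOTHER) for p in ps[n_pat:]]
            forbidden |= {p for p, _ in dn_pos}
        for p, origin in dn_pos:
            r = reference_base(np.array([p]), cfg.seed, cfg.gc_content)[0]
            a = _draw_alt(np.array([r]), cfg.titv_ratio, rng_d)[0]
            if origin == FATHER:
                pat[p] = a
            else:
                mat[p] = a
            denovo_rows.append((chrom, p, r, a, origin, False))

        # somatic de novo SNVs: blood only
        som_alleles: Dict[int, str] = {}
        n_som = int(n_somatic_per_chrom[ci])
        if n_som:
            ps = _sample_positions(rng_d, L, n_som, forbidden)
            for p in ps:
                p = int(p)
                r = reference_base(np.array([p]), cfg.seed, cfg.gc_content)[0]
                a = _draw_alt(np.array([r]), cfg.titv_ratio, rng_d)[0]
                som_alleles[p] = a
                somatic_rows.append((chrom, p, r, a, "soma", True))
                forbidden.add(p)

        # allelic-conversion tracts: overwrite one offspring allele with its
        # homolog over a short tract, anchored on an offspring-het site so
        # every tract has at least one potential marker
        het_sites = sorted(p for p in (set(pat) | set(mat))
                           if pat.get(p, _refb(p, cfg)) != mat.get(p, _refb(p, cfg))
                           and p not in blocked)
        n_conv = len(per_chrom_events[chrom]["conv"])
        for _ in range(n_conv):
            if not het_sites:
                raise UnplaceableEventError("no heterozygous site to anchor a conversion tract")
            tract_len = max(2, int(rng_e.exponential(cfg.conversion_tract_mean_bp)))
            for _try in range(200):
                anchor = int(het_sites[int(rng_e.integers(0, len(het_sites)))])
                s = max(0, anchor - int(rng_e.integers(0, tract_len)))
                e = min(L, s + tract_len)
                if all(e <= rs or s >= re for rs, re in reserved):
                    break
            else:
                raise UnplaceableEventError("could not place conversion tract")
            reserved.append((s, e))
            donor = int(rng_e.integers(0, 2))  # 0: paternal allele wins
            for p in list(pat.keys() | mat.keys()):
                if s <= p < e:
                    src = pat if donor == 0 else mat
                    dst = mat if donor == 0 else pat
                    dst[p] = src.get(p, _refb(p, cfg))
            tract_rows.append((chrom, s, e, donor))

        # assemble offspring variant table (germline)
        all_pos = np.array(sorted(set(pat) | set(mat)), dtype=np.int64)
        ref_all = reference_base(all_pos, cfg.seed, cfg.gc_content)
        h0 = np.array([pat.get(int(p), r) for p, r in zip(all_pos, ref_all)])
        h1 = np.array([mat.get(int(p), r) for p, r in zip(all_pos, ref_all)])
        keep = (h0 != ref_all) | (h1 != ref_all)
        ovars = pd.DataFrame({"chrom": chrom, "pos": all_pos[keep], "ref": ref_all[keep],
                              "alt": "", "hap0": h0[keep], "hap1": h1[keep]})

        father_frames.append(fvars)
        mother_frames.append(mvars)
        off_frames.append((ovars, som_alleles))

        # repeat mask: fixed-length blocks placed uniformly, merged
        block = 500
        n_blocks = int(cfg.repeat_fraction * L / block)
        if n_blocks:
            starts = rngs["mask"].integers(0, L - block, n_blocks)
            mask_frames.append(RegionSet({chrom: np.stack([starts, starts + block], 1)}))
        n_indels = rngs["mask"].binomial(L, cfg.indel_density)
        indel_positions[chrom] = (_sample_positions(rngs["mask"], L, n_indels)
                                  if n_indels else np.empty(0, dtype=np.int64))

    def finalize_parent(frames, dels, tissue="germline"):
        df = pd.concat(frames, ignore_index=True)
        return DiploidGenome(df, dels, tissue)

    father = finalize_parent(father_frames, father_dels)
    mother = finalize_parent(mother_frames, mother_dels)

    off_parts, som_all = [], {}
    for ovars, som in off_frames:
        off_parts.append(ovars)
        chrom = ovars["chrom"].iloc[0] if len(ovars) else None
        for p, a in som.items():
            som_all[(chrom, p)] = a
    germline = pd.concat(off_parts, ignore_index=True)
    hair = DiploidGenome(germline.copy(), off_dels + off_dn_dels, "hair")
    blood_vars = germline.copy()
    if som_all:
        extra = []
        for (chrom, p), a in som_all.items():
            r = reference_base(np.array([p]), cfg.seed, cfg.gc_content)[0]
            # somatic variants modelled on the paternal haplotype
            extra.append({"chrom": chrom, "pos": p, "ref": r, "alt": a,
                          "hap0": a, "hap1": r})
        blood_vars = pd.concat([blood_vars, pd.DataFrame(extra)],
                               ignore_index=True).sort_values(["chrom", "pos"],
                                                              ignore_index=True)
    blood = DiploidGenome(blood_vars, off_dels + off_dn_dels, "blood")

    denovo = pd.DataFrame(denovo_rows + somatic_rows,
                          columns=["chrom", "pos", "ref", "alt", "origin", "somatic"])
    truth = SimTruth(
        denovo_snvs=denovo.sort_values(["chrom", "pos"], ignore_index=True),
        conversion_tracts=pd.DataFrame(tract_rows, columns=["chrom", "start", "end", "donor_hap"]),
        hemizygous_deletions=pd.DataFrame(hemi_rows, columns=["parent", "chrom", "start", "end"]),
        denovo_deletions=pd.DataFrame(dndel_rows, columns=["chrom", "start", "end"]),
    )

    mask = RegionSet()
    for rs in mask_frames:
        mask = mask.union(rs)

    site_table = _build_site_table(cfg, father, mother, blood)
    sim = TrioSim(cfg, father, mother, blood, hair, truth, mask, indel_positions, site_table)
    for g in (father, mother, blood, hair):
        _REF_SEED_CACHE[id(g)] = (cfg.seed, cfg.gc_content)
    return sim


def _refb(pos: int, cfg: SimConfig) -> str:
    return reference_base(np.array([pos]), cfg.seed, cfg.gc_content)[0]


def _build_site_table(cfg: SimConfig, *genomes: DiploidGenome) -> pd.DataFrame:
    """Union of variant sites across genomes, with one alt allele per site."""
    frames = []
    for g in genomes:
        v = g.variants
        alt = np.where(v["hap0"] != v["ref"], v["hap0"], v["hap1"])
        frames.append(pd.DataFrame({"chrom": v["chrom"], "pos": v["pos"],
                                    "ref": v["ref"], "alt": alt}))
    df = pd.concat(frames, ignore_index=True)
    df = df[df["alt"] != df["ref"]]
    df = df.drop_duplicates(subset=["chrom", "pos"], keep="first")
    return df.sort_values(["chrom", "pos"], ignore_index=True)


# ---------------------------------------------------------------------------
# sequencing observations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteObservation:
    """Strand-resolved read counts at one site for one individual."""

    chrom: str
    pos: int
    depth: int
    rf: int  # reference-forward
    rr: int  # reference-reverse
    af: int  # alternate-forward
    ar: int  # alternate-reverse
    gt: int = GT_MISSING
    qual: float = 0.0

    def __post_init__(self):
        if self.rf + self.rr + self.af + self.ar != self.depth:
            raise ValueError("depth must equal RF+RR+AF+AR")


def simulate_observations(genome: DiploidGenome, site_table: pd.DataFrame,
                          coverage: float, base_error: float, seed: int,
                          read_length: int = 101) -> pd.DataFrame:
    """Simulate per-site strand-resolved allele counts for one individual.

    Depth is Poisson(coverage), halved over hemizygous intervals.  Reads
    split evenly between strands; each read miscalls ref<->alt with
    probability ``base_error``.  A ``end_dist`` column carries the mean
    distance from each supporting read's nearer end (uniform placement
    within ``read_length``-bp reads).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, sub in site_table.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(np.int64)
        alt = sub["alt"].to_numpy()
        dosage, ploidy = genome.alt_dosage(chrom, pos, alt)
        ploidy = ploidy.astype(np.float64)
        depth = rng.poisson(coverage * ploidy / 2.0)
        p_alt_true = np.where(ploidy > 0, dosage / ploidy, 0.0)
        n_alt = rng.binomial(depth, p_alt_true)
        n_ref = depth - n_alt
        # symmetric miscall between the two observed alleles
        n_alt_obs = n_alt - rng.binomial(n_alt, base_error) + rng.binomial(n_ref, base_error)
        n_ref_obs = depth - n_alt_obs
        af = rng.binomial(n_alt_obs, 0.5)
        rf = rng.binomial(n_ref_obs, 0.5)
        # mean distance of the covering reads from their nearer read end
        total = int(depth.sum())
        offs = rng.integers(0, read_length, total)
        dist = np.minimum(offs, read_length - 1 - offs).astype(np.float64)
        bounds = np.concatenate(([0], np.cumsum(depth)))
        sums = np.add.reduceat(np.concatenate((dist, [0.0])), bounds[:-1])
        sums[depth == 0] = 0.0
        mean_dist = np.where(depth > 0, sums / np.maximum(depth, 1), np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": sub["ref"].to_numpy(), "alt": alt,
            "depth": depth, "rf": rf, "rr": n_ref_obs - rf,
            "af": af, "ar": n_alt_obs - af, "end_dist": mean_dist,
        }))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "depth", "rf", "rr", "af", "ar", "end_dist"])
    return out


def call_genotypes(observations: pd.DataFrame, base_error: float = 1e-3,
                   het_pl_threshold: float = 200.0,
                   hom_pl_threshold: float = 100.0) -> pd.DataFrame:
    """Genotype each site from a binomial mixture over {hom-ref, het, hom-alt}.

    The call is the maximum-likelihood genotype; ``qual`` is the
    phred-scaled gap between the best and second-best genotype (the PL of
    the runner-up).  Calls whose gap falls below the genotype-appropriate
    threshold (200 heterozygous / 100 homozygous by default) are marked
    ``filtered``; zero-depth sites are ``missing``.
    """
    if het_pl_threshold < 0 or hom_pl_threshold < 0:
        raise ValueError("PL thresholds must be >= 0")
    obs = observations.copy()
    n = obs["depth"].to_numpy(np.int64)
    k = (obs["af"] + obs["ar"]).to_numpy(np.int64)
    e = min(max(base_error, 1e-12), 0.5)
    ll = np.stack([stats.binom.logpmf(k, n, p) for p in (e, 0.5, 1.0 - e)], axis=1)
    order = np.argsort(ll, axis=1)
    best = order[:, -1]
    second = order[:, -2]
    rows = np.arange(len(ll))
    qual = 10.0 / np.log(10.0) * (ll[rows, best] - ll[rows, second])
    thresh = np.where(best == HET, het_pl_threshold, hom_pl_threshold)
    status = np.where(n == 0, "missing", np.where(qual < thresh, "filtered", "pass"))
    obs["gt"] = np.where(n == 0, GT_MISSING, best).astype(np.int8)
    obs["qual"] = np.round(qual, 2)
    obs["status"] = status
    return obs


def subsample_observations(observations: pd.DataFrame, fraction: float,
                           seed: int) -> pd.DataFrame:
    """Binomially thin every read count by ``fraction`` (coverage titration)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return observations.copy()
    rng = np.random.default_rng(seed)
    out = observations.copy()
    for col in ("rf", "rr", "af", "ar"):
        out[col] = rng.binomial(observations[col].to_numpy(np.int64), fraction)
    out["depth"] = out[["rf", "rr", "af", "ar"]].sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------

@dataclass
class DepthTrack:
    """Per-site read depth (and forward-strand depth) for one individual."""

    depth: Dict[str, np.ndarray]
    fwd: Dict[str, np.ndarray]

    @property
    def genome_mean(self) -> float:
        if not hasattr(self, "_genome_mean"):
            tot = sum(int(a.sum()) for a in self.depth.values())
            n = sum(len(a) for a in self.depth.values())
            self._genome_mean = tot / n if n else float("nan")
        return self._genome_mean

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        arr = self.depth[chrom]
        start, end = max(0, start), min(len(arr), end)
        if end <= start:
            raise ValueError("empty window")
        return float(arr[start:end].mean())


def simulate_depth_track(sim: TrioSim, individual: str, seed: int,
                         coverage: Optional[float] = None) -> DepthTrack:
    """Overdispersed per-site depth, halved over hemizygous intervals.

    Depth is gamma-mixed Poisson (negative binomial): real short-read
    depth tracks are far noisier than Poisson (GC bias, mappability), and
    the extra-Poisson coefficient of variation ``depth_cv`` sets the
    realistic width of the +/- 3 sigma depth filter.  ``depth_cv = 0``
    gives a pure Poisson track.
    """
    cfg = sim.config
    cov = coverage if coverage is not None else cfg.coverage_of(individual)
    genome = sim.genome(individual)
    rng = np.random.default_rng(seed)
    def draw(mean: float, size: int) -> np.ndarray:
        if cfg.depth_cv <= 0:
            return rng.poisson(mean, size).astype(np.int32)
        # gamma-Poisson mixture == negative binomial with r = 1/cv^2
        r = 1.0 / cfg.depth_cv**2
        return rng.negative_binomial(r, r / (r + mean), size).astype(np.int32)

    depth, fwd = {}, {}
    for chrom, L in cfg.chrom_lengths.items():
        d = draw(cov, L)
        for c, s, e, _h in genome.deletions:
            if c == chrom:
                d[s:e] = draw(cov / 2.0, e - s)
        depth[chrom] = d
        fwd[chrom] = rng.binomial(d, 0.5).astype(np.int32)
    return DepthTrack(depth, fwd)


# ---------------------------------------------------------------------------
# read-pair fragments (for parental-origin phasing)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """A sequenced fragment of the offspring genome.

    Carries the observed allele at every variant site the fragment spans;
    ``hap`` records the true haplotype of origin (0 paternal, 1 maternal)
    for simulation bookkeeping only.
    """

    id: int
    chrom: str
    start: int
    end: int
    hap: int
    alleles: Mapping[int, str]


def simulate_fragments(sim: TrioSim, positions_by_chrom: Mapping[str, Sequence[int]],
                       seed: int, fragments_per_site: float = 30.0,
                       insert_sizes: Tuple[int, ...] = (300, 500)) -> List[Fragment]:
    """Fragments of the offspring blood genome covering the given positions."""
    rng = np.random.default_rng(seed)
    genome = sim.offspring_blood
    site_lut: Dict[str, pd.DataFrame] = {
        c: sub for c, sub in sim.site_table.groupby("chrom")
    }
    out: List[Fragment] = []
    fid = 0
    for chrom, targets in positions_by_chrom.items():
        sub = site_lut.get(chrom)
        if sub is None:
            continue
        vpos = sub["pos"].to_numpy(np.int64)
        v = genome.variants[genome.variants["chrom"] == chrom]
        hap_allele = {0: dict(zip(v["pos"].astype(int), v["hap0"])),
                      1: dict(zip(v["pos"].astype(int), v["hap1"]))}
        ref_lut = dict(zip(sub["pos"].astype(int), sub["ref"]))
        for target in targets:
            n = rng.poisson(fragments_per_site)
            for _ in range(n):
                insert = int(insert_sizes[int(rng.integers(0, len(insert_sizes)))])
                start = int(target) - int(rng.integers(0, insert))
                end = start + insert
                hap = int(rng.integers(0, 2))
                lo, hi = np.searchsorted(vpos, [start, end])
                alleles = {}
                for p in vpos[lo:hi]:
                    p = int(p)
                    alleles[p] = hap_allele[hap].get(p, ref_lut[p])
                out.append(Fragment(fid, chrom, start, end, hap, alleles))
                fid += 1
    return out


# ---------------------------------------------------------------------------
# ground-truth Mendelian-error table
# ---------------------------------------------------------------------------

def true_mie_table(sim: TrioSim) -> pd.DataFrame:
    """True-genotype Mendelian errors with their causal event category.

    Evaluates Mendelian consistency on the noiseless apparent genotypes
    (hemizygous sites appear homozygous) and labels each inconsistent site
    by the injected event that produced it.
    """
    from .mie import mendelian_consistent  # local import to avoid a cycle

    rows = []
    truth = sim.truth
    dn = truth.denovo_snvs
    dn_idx = set(zip(dn["chrom"], dn["pos"]))
    for chrom, sub in sim.site_table.groupby("chrom"):
        pos = sub["pos"].to_numpy(np.int64)
        alt = sub["alt"].to_numpy()
        gf = sim.father.genotype_codes(chrom, pos, alt)
        gm = sim.mother.genotype_codes(chrom, pos, alt)
        go = sim.offspring_blood.genotype_codes(chrom, pos, alt)
        bad = ~mendelian_consistent(gf, gm, go)
        for i in np.flatnonzero(bad):
            p = int(pos[i])
            if (chrom, p) in dn_idx:
                cat = "DENOVO_SNV"
            elif _in_intervals(truth.conversion_tracts, chrom, p):
                cat = "CNIV"
            elif _in_intervals(truth.hemizygous_deletions, chrom, p):
                cat = "HDIV"
            elif _in_intervals(truth.denovo_deletions, chrom, p):
                cat = "DENOVO_CNV"
            else:
                cat = "OTHER"
            rows.append((chrom, p, int(gf[i]), int(gm[i]), int(go[i]), cat))
    return pd.DataFrame(rows, columns=["chrom", "pos", "gt_father", "gt_mother",
                                       "gt_offspring", "category"])


def _in_intervals(df: pd.DataFrame, chrom: str, pos: int) -> bool:
    if not len(df):
        return False
    sub = df[df["chrom"] == chrom]
    return bool(((sub["start"] <= pos) & (pos < sub["end"])).any())


def config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["hemizygous_deletions"] = [list(x) for x in d["hemizygous_deletions"]]
    d["denovo_deletions"] = list(d["denovo_deletions"])
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    if "hemizygous_deletions" in d:
        d["hemizygous_deletions"] = tuple((p, int(n)) for p, n in d["hemizygous_deletions"])
    if "denovo_deletions" in d:
        d["denovo_deletions"] = tuple(int(x) for x in d["denovo_deletions"])
    return SimConfig(**d)
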