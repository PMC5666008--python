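# Methods

This note documents the models, defaults and numerical choices behind
the package, and what its simulation-based validation does and does not
establish.

## The analysis model

A biallelic trio site carries genotype codes (hom-ref, het, hom-alt) for
father, mother and offspring. The site is a Mendelian inheritance error
(MIE) when no pair of one paternal and one maternal allele reproduces
the offspring genotype; detection is an exhaustive check over the 27
genotype configurations, precomputed once from allele assortment.

Each MIE is explained by one of four mechanisms, decided in a fixed
order from (a) whether the offspring carries an allele seen in neither
parent and (b) windowed depth states:

1. novel allele, no half-depth flag → **de novo SNV**;
2. inherited alleles only, no half-depth flag → **CNIV**
   (copy-number-neutral inherited variant; the expected signature of an
   allelic conversion that overwrote an obligate allele);
3. offspring plus exactly one parent at half depth → **HDIV**
   (transmitted hemizygous deletion);
4. offspring-only half depth → **de novo CNV** (new deletion).

Any other flag combination (e.g. both parents at half depth) is reported
as UNCLASSIFIED rather than forced into a category. The novel-allele
test runs before the depth tests so a genuine de novo SNV cannot be
shadowed by a noisy depth ratio.

**Half-depth call.** The depth of each individual in a window (default
1 kb) centred on the site is normalized by that individual's genome-wide
mean; a normalized value ≤ 0.75 — the midpoint between the one-copy
(0.5) and two-copy (1.0) expectations — reads as "one copy". The
original depth-comparison software for this step published no threshold,
so the midpoint rule is this package's documented substitute, exposed as
`half_depth_threshold`. Pairwise father–offspring and mother–offspring
depth ratios (each normalized by genome-wide means) are recorded on
every MIE for inspection.

## Target-region filters

All coordinates are 0-based half-open internally; VCF positions are
converted at the I/O boundary. The five filters:

* **(i) depth**: per-individual mean ± 3σ, with mean and σ computed only
  from sites whose depth lies within a pre-clamp range (defaults: lower
  15×/15×/18× for father/mother/offspring, upper 512×) so pathological
  pileups cannot distort the moments. A site is removed if *any* member
  is out of its own bounds.
* **(ii) strand balance**: ≥ 10 forward and ≥ 10 reverse reads in every
  member (boundary inclusive).
* **(iii) indels**: annotated indel positions ± 50 bp (indel calling
  itself is out of scope; positions come from an annotation table).
* **(iv) allelic/strand bias**: at a variant site, every allele the
  carrier shows must appear on both strands (heterozygote: RF, RR, AF,
  AR all ≥ 1). A homozygous-alternate carrier has no reference reads by
  construction, so only AF ≥ 1 and AR ≥ 1 are required — the literal
  all-four rule would discard every hom-alt site. Failures are removed
  ± 10 bp.
* **(v) read ends**: a variant whose supporting reads lie on average
  ≤ 10 bp from a read end is removed ± 10 bp. "Average distance to the
  read end" is interpreted as the mean over supporting reads of the
  distance to the *nearer* end; this is one reading of an ambiguous
  prescription and is stated here as the package's choice.

"Adjacent N bp" is symmetric padding of the site position. Per-filter
removals are reported individually against the whole genome (so their
sum can exceed the union); the final target is genome − union(removals)
− repeat mask, and its size T is the rate denominator.

## Conversion clustering

If n CNIVs fell uniformly on the target length L, adjacent spacings
would be ≈ Exp(n/L) with mean L/n (the package uses L/n rather than
L/(n+1); at the study's scale the two differ in the third significant
figure). The bootstrap null scatters n points per replicate, pools the
n−1 adjacent gaps over replicates (default 10,000) and takes the central
percentile interval (default 99%). CNIVs whose gap is at most the lower
bound chain into one event by single linkage; chromosomes never chain.
The lower bound behaves like the exponential 0.5th percentile
(−ln(1−0.005)·L/n) and the implementation is validated against that
closed form rather than against any particular printed threshold, since
pooled-percentile bootstraps at this tail are sensitive to procedural
details; a known threshold can be supplied directly via `--threshold`.

## Origin phasing

An informative site is one where the offspring is heterozygous and the
parents are opposite homozygotes, so each offspring allele has exactly
one possible source. Fragments covering both the de novo site (with the
de novo allele) and an informative site vote for a parent; assignment
requires a unanimous non-empty vote (any conflict → unassigned). This
conservative policy is a package choice; requiring a minimum number of
supporting fragments is possible via the recorded support counts. The
default search distance (500 bp) matches the larger simulated insert
size.

## Rate estimation

With n candidates, a false-positive rate f estimated from confirmation
genotyping (FP = the confirmation genotypes contradict the de novo
call), and s somatic calls (offspring blood ≠ hair at a confirmed site):

* n_fp = round(n·f); n_germline = n − n_fp − s;
* bounds: all untestable candidates assumed FP (minimum) or true
  (maximum), with the *observed* FP count;
* μ_g = n_germline / 2T; μ_y = μ_g / a with a the mean parental age at
  conception (default 24 years; per-parent ages are averaged);
* a nonzero false-negative rate divides the rate by (1 − FN); FN
  defaults to 0;
* rates are displayed at 3 significant figures, rounded half away from
  zero (`round_sig`), after stripping binary floating-point noise — the
  phylogenetic per-generation value is exactly 1.875 × 10⁻⁸ and prints
  as 1.88 × 10⁻⁸.

The phylogenetic calculator inverts the expected pairwise divergence
d = 2 μ_y t + 4 N_e g μ_y (the second term is the expected coalescence
lead in the ancestral population), giving μ_y = d/(2t + 4 N_e g) and
μ_g = μ_y g. It is monotone decreasing in t, g and N_e for fixed d.

## The simulator

Defaults are the study conditions of a deeply sequenced chimpanzee trio:
SNV density 0.118%, heterozygosity 0.076%, Ti/Tv 1.98, ~150× coverage
per individual, 101-bp reads with 300/500-bp insert sizes,
genotype-quality (phred-scaled likelihood gap) thresholds 200 (het) /
100 (hom), depth pre-clamp 15×/15×/18×–512×, one somatic de novo SNV,
germline μ = 1.48 × 10⁻⁸ per site per haploid transmission, parental
age 24 years.

Values the study conditions do not fix, chosen once:

* **base_error = 10⁻³** (a Q30 error profile), applied as a symmetric
  ref↔alt miscall so that depth = RF+RR+AF+AR holds exactly;
* **depth_cv = 0.25**: genome-track depth is a gamma-mixed Poisson
  (negative binomial). Real depth tracks are far noisier than Poisson
  (GC bias, mappability); the printed per-individual ±3σ depth windows
  of deep trio data imply a coefficient of variation near 0.25, and with
  pure Poisson tracks a ±3σ filter would remove every hemizygous
  deletion region outright. Per-site observations used for genotyping
  remain Poisson;
* **repeat_fraction = 0.2** of the genome masked as 500-bp blocks — a
  deliberately reduced repeat load that keeps synthetic targets focused
  on filter logic rather than primate repeat content;
* **indel density 2.3 × 10⁻⁴** per bp (the genome-wide indel/SNV
  proportions of deep mammalian resequencing), annotation-only;
* **conversion tract length ~ Exp(170 bp)**, inside the 55–290 bp range
  of published mean tract estimates; tracts are anchored on an offspring
  heterozygous site so every simulated event has at least one potential
  marker (an unmarked tract is undetectable in principle, which is why
  conversion-rate estimates from marker data are lower bounds);
* **GC content 0.41**. The reference is implicit: each position's base
  is a deterministic hash of (seed, position), so dinucleotide (CpG)
  contexts are reproducible without storing sequence.

Mendelian transmission draws one haplotype per parent per site
(offspring haplotype 0 paternal, 1 maternal). A hemizygous deletion
removes one parental haplotype and is always transmitted (real meiosis
would transmit it half the time; the simulator's purpose is to produce
the inherited-deletion signature, not deletion population genetics). A
de novo deletion removes one offspring haplotype. Somatic SNVs exist
only in the blood-tissue genome, never hair, mirroring a
mesoderm/ectoderm two-tissue design; the pipeline's triage calls hair
genotypes at candidate sites and subtracts discordant ones. When both
parents are independently variant at the same position they share the
alternate allele (a shared ancestral polymorphism), keeping every site
biallelic.

### What the simulator does not model

Read mapping and its artifacts (multi-mapping, reference gaps, soft
clips), indel alleles, linkage disequilibrium between parental variants,
GC-dependent coverage *trends* (only unstructured overdispersion), and
recurrent mutation. Consequently the pipeline's simulated false-positive
load is far below that of real data — with binomial errors, the PL-gap
genotype filter removes essentially all miscalls at any depth — so
passing recovery tests demonstrates the correctness of the logic
(filters, detection, classification, arithmetic) and its calibration
under the stated noise model, not robustness to alignment artifacts.
The coverage-titration property (false-positive de novo candidates do
not increase with depth) is directional for the same reason: at low
depth the filters mostly abstain rather than err.

## Numerical and degenerate-input choices

* Interval sets are merged half-open arrays; adjacent intervals coalesce;
  set algebra is verified against a per-base bitmap oracle.
* Zero-depth sites are "missing" (distinct from "filtered"); either
  status excludes the site from MIE testing, and skips are counted.
* Depth-ratio windows with zero coverage raise an error rather than
  returning infinity; empty pre-clamp depth ranges and empty targets are
  hard errors.
* Genotype likelihoods are binomial over alt-read counts with
  p ∈ {e, 1/2, 1−e}; quality is the phred gap to the runner-up genotype.
  Ties (possible only at tiny depth) resolve by the fixed genotype order
  and fall below any sensible gap threshold anyway.
* All randomness flows from one master seed through named child
  seed-sequences per stage; reruns are byte-identical.

## Validation scales

The test suite exercises 1-Mb trios for unit-level recovery and 10-Mb
trios for the classification-accuracy, rate-recovery (20 seeds,
μ = 10⁻⁶) and coverage-titration properties; these sizes give tens to
hundreds of truth events per class while keeping the full suite to a few
minutes. Rate recovery is judged against the pooled 95% Poisson interval
of 2μT summed over seeds.

## Known limitations

* CNIV recall is bounded by marker availability: conversion tracts
  without an obligate-allele site are invisible, as in real data.
* HDIV/de novo CNV classification degrades within half a window of a
  deletion boundary, where the depth window straddles the edge.
* The strand-resolved depth field (SD) is a custom VCF FORMAT tag;
  standard AD readers will see only DP and GT.
* The bootstrap lower bound at the 0.5th percentile has noticeable
  Monte-Carlo spread at 10,000 replicates; downstream event counts for a
  published threshold should set `--threshold` explicitly.
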