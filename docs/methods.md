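# Methods

## The problem

Strand-specific whole-genome bisulfite sequencing (WGBS) reports CpG
methylation independently for the two strands of each CpG dyad
`[pos, pos+2)`.  Because bisulfite conversion turns an unmethylated C into
T on the read, a SNP at the CpG cytosine contaminates the methylation
signal in an allele-specific way, and open-access methylation tracks then
carry genotype — re-identifiable DNA sequence information — disguised as
epigenetic signal.  `methleak` implements the full audit loop: a generative
model of the contamination, detection screens, a genotype caller that
recovers the variants from the strand evidence, and a sanitizer that
removes them before release.

## Strand read-accounting model

For a diploid genotype at the forward-strand C with true methylation `m`
(assumed symmetric across the dyad), each allele contributes per-read:

| allele | forward strand | reverse strand |
|---|---|---|
| C | scored methylated w.p. `m` | dyad's reverse C in CpG context: `m` |
| T | indistinguishable from converted C: scored unmethylated | reverse C now in CpH context: `cph` |
| A / G | no cytosine at the site — read dropped (coverage factor loss) | reverse C in CpH context: `cph` |

Expected strand rates are allele averages over the counted reads; the
forward coverage factor is the fraction of alleles contributing forward
reads (1, 0.5 or 0).  Consequences that drive the rest of the package:

* C/A and C/G heterozygotes at a methylated site show ~50 percentage
  points more methylation on the forward than the reverse strand — the
  strand-discordance signature.
* C/T heterozygotes are concordant at ~`m/2` on both strands and are
  invisible to strand comparison; only the reverse-strand base counts
  (complement of the allele, intact under bisulfite) reveal them.
* A/A and G/G homozygotes are unmeasurable on the forward strand; the
  simulator emits a zero-coverage forward record so "unmeasurable" stays
  distinguishable from "unsequenced".

The reverse-strand rate of a het is `(m + cph)/2` for **all three** alt
alleles: on any alt allele the dyad's reverse-strand cytosine sits in a CpH
context, so its residual CpH methylation (`cph_methylation_rate`, default
1 %) is what reverse reads measure.  This uniform treatment follows from
the read accounting itself; setting `cph = 0` recovers the idealized
"alt reverse reads are unmethylated" description.

### Error model

`non_conversion_rate` (default 0.5 %) is modeled as a *symmetric*
conversion-error rate — failure to convert an unmethylated C and
inappropriate conversion of a methylated C are both rare and one rate
captures both, so a fully methylated site reads `1 − nc` (0.995 by
default).  `sequencing_error_rate` (default 0.1 %) flips a read base
uniformly over the other three bases, crossing the methylated/unmethylated
boundary with probability `e/3`.  Both mix into the expected strand rate
after the allele accounting.

## Synthetic cohorts

The generator emulates the structure of the datasets the analysis assumes:
multiple tissues per individual (default 5 individuals × 10 tissues ≈ 50
tracks), purified-cell cohorts with matched genotypes, and MZ/DZ twin
pairs for the array-style analysis.  Defaults and rationale:

* **Baseline methylation**: two-component Beta mixture, 70 % mass near 1
  (Beta(10, 0.5)) and 30 % near 0 (Beta(0.5, 10)) — somatic WGBS
  methylomes are strongly bimodal.
* **Coverage**: per-strand Poisson with mean `coverage_mean_per_strand`
  (default 15), matching the coverage regimes the screens threshold on
  (≥4, ≥10, ≥15 reads) without read-level simulation.
* **Genotypes**: Hardy–Weinberg sampling with MAF ~ Beta(1, 3).  MZ twins
  copy genotypes; DZ twins draw two parental genotypes and inherit one
  allele from each parent independently (each parental allele shared with
  probability 1/2).
* **Indirect meQTLs**: a fraction of intact CpGs (default 5 %) is linked
  to a SNP placed within ±10 kb; the effect is additive in alt-allele
  dosage with a random sign (default magnitude 0.2 in proportion units)
  and the resulting methylation is clipped to [0, 1] — mirroring the
  linear model the correlation module fits.
* **Tissue and residual noise**: Gaussian per-tissue offsets
  (`tissue_effect_sd`, default 0.02) and per-sample residuals
  (`residual_sd`, default 0.02).  The tissue model is a smooth Gaussian
  perturbation; it does **not** emulate the focal, large-effect
  tissue-specific DMRs of real methylomes.  Scenario runs that need
  substantial tissue-driven differential methylation (the pair-type
  ordering analysis) raise `tissue_effect_sd` to ~0.12 so that a few
  percent of sites differ by >0.30 between tissues.

What passing tests on these cohorts do *not* show: robustness to
alignment artifacts, read-level biases (overhang repair, adapter
underconversion), hydroxymethylation, or realistic linkage disequilibrium
— none of which the generator models.

## Leakage screen

A dyad×sample matrix of pooled-strand rates (samples below `min_coverage`
= 4 pooled reads are missing) is screened for sites that are static within
individuals but variable between them: strictly more than half of the
assessable individuals (≥3 measured samples each) must have
within-individual SD < 0.07, and the range over all measured samples must
be ≥ 0.15.  Choices where the convention was open:

* SD is the population SD (divisor n), fixed for exact reproducibility.
* "Over half" is strict and is evaluated over *assessable* individuals at
  that site, not all individuals.
* The range uses all measured samples, after low-coverage exclusion.
* A percentile mode (`calibrate_thresholds`) derives both thresholds from
  an empirical reference matrix (bottom 70 % of SDs, top 35 % of ranges).

The screen is deliberately sensitive; its false-positive floor is
quantified by permuting the sample→individual assignment
(`permutation_null_yield`).  The genotype-driven excess over that null is
what downstream stages confirm and remove.

## Genotype–methylation correlation

Each SNP allele is viewed as carrying a mean methylation rate; a diploid
sample's methylation is the average over its two alleles, i.e. linear in
dosage.  `fit_cpg_snp` is ordinary least squares with Pearson r and the
exact two-sided t-test on n−2 df (via `scipy.stats.linregress`).  The
fitted line is evaluated at dosages {0, 1, 2} even when a dosage class is
absent, and genotype is re-predicted as the nearest fitted mean (ties to
the smaller dosage).  Conventions: window at ±10 kb inclusive; accuracy is
resubstitution (a leave-one-out mode exists but is off by default, since
no held-out scheme is part of the analysis being reproduced); p-values are
reported raw with fixed thresholds (r > 0.5, p < 0.05 for "correlated",
additionally accuracy > 0.98 for "highly predictive"); per CpG the best
SNP is max |r| with ties by proximity then id.

## Genotype caller

A count-level simplification of a bisulfite-aware caller (Bis-SNP-style):
per dyad, the posterior over the 10 unordered diploid genotypes combines

* a multinomial likelihood of the reverse-strand base counts (each read
  reports the complement of a uniformly drawn allele, error `e` spread
  over the other three bases),
* binomial likelihoods of the forward/reverse methylation counts with the
  expected rates given by the strand accounting, the unknown methylation
  marginalized over a uniform grid {0, 0.5, 1} (configurable), and
* a prior: *rare* mode puts 1−θ on C/C (θ = 0.001, a standard human
  heterozygosity scale) and splits θ over the nine variant genotypes —
  the worst-case "no catalog" assumption; *catalog* mode uses
  Hardy–Weinberg priors from the catalog allele frequency, with the het
  and hom-alt mass split evenly over the three possible alt bases
  (point catalogs do not record the alt identity).

Genotypes with forward coverage factor 0 have zero likelihood whenever
forward reads exist.  Constant combinatorial coefficients cancel in the
posterior and are dropped.  Calls are filtered `LOW_COV` below 10 total
reads (low coverage is the dominant source of mislabeling), `AMBIGUOUS`
below a 0.9 posterior, else `PASS`.  No base-quality recalibration or
realignment: the caller audits leakage in count summaries, it does not
replace a production caller.  Only the forward-C position is genotyped;
the dyad's G is symmetric by construction.

## Differential-methylation audit

Differentially methylated dyads between two samples require pooled
coverage ≥15 in both and |Δrate| > 0.30 (strict), pooling strands before
the coverage cut.  A differential dyad is attributed to genetics when a
non-reference PASS call exists at it in one or both samples.  Pairs are
grouped by design (same individual/different tissue, same
tissue/different individual, both differing); the fraction attributed
separates tissue epigenetics from genotype leakage.

## Sanitizer

Removal is at dyad level (a variant at either base compromises the pair),
with one reason per dyad under the fixed precedence `called_variant >
catalog > unclear_context`:

* `detected` policy: dyads with a non-reference PASS call; plus unclear
  cytosine contexts, defined here as an AMBIGUOUS call or
  strand-discordant methylation (|Δ| > 0.2 and exact test p < 0.01) with
  no resolving PASS genotype.
* `catalog` policy: dyads overlapped by a known-SNP catalog entry — the
  only option for non-stranded platforms.
* `both`: the union (removals are supersets of either policy alone).

Retained records are bit-identical to the input; sanitization is
idempotent and `verify_sanitized` re-checks a track as a release gate.

## Numerical and I/O conventions

Coordinates are 0-based half-open internally; conversion happens only at
file boundaries, and reverse-strand cytosine-report records are re-keyed
to the dyad's forward-C position at ingest.  bedGraph values are
percentages (0–100) per track-hub convention.  Likelihoods are computed in
log space with a −10⁶ floor standing in for log 0 in the base-count
matmul; posteriors are normalized by logsumexp.  All randomness flows
through `numpy.random.default_rng` seeded from a single design/pipeline
seed; identical seeds reproduce byte-identical outputs.

## Problem sizes

Tests and the reproduction script run desk-scale cohorts chosen to make
the statistical properties measurable with comfortable margins: hundreds
to a few thousand CpGs, 4–48 individuals, 15–30× per-strand coverage, and
60 individuals for the single-site strand-asymmetry measurements.  The
genome-scale counts of real multi-tissue compendia are outside what these
cohorts (or this generator) can or should reproduce.

## Known limitations

* The methylation nuisance grid {0, 0.5, 1} slightly miscalibrates
  posteriors at intermediate methylation; a finer grid is configurable.
* The simulator draws sites independently — no linkage disequilibrium, no
  regional methylation correlation, no DMR structure.
* The catalog prior ignores the alt-allele identity and any strand/indel
  complexity; indels and multi-allelic sites are out of scope throughout.
* `evaluate_calls` scores exact-genotype matches; partial credit (right
  position, wrong alt) counts as an incorrect variant call.
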