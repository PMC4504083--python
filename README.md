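# methleak

Detect, audit and remove **genotype leakage** in DNA methylation data.

Open-access methylation tracks are supposed to carry epigenetic signal
only, but whole-genome bisulfite sequencing (WGBS) silently encodes
genotype wherever a SNP disrupts a CpG.  Bisulfite conversion reads an
unmethylated C as T, so at a CpG whose cytosine is mutated:

* **C→A / C→G** — alt-allele forward reads carry no cytosine and are
  dropped, while reverse reads still score the dyad's reverse C (now in a
  CpH context) as unmethylated.  A heterozygote shows ~50 percentage
  points more methylation on the forward than the reverse strand.
* **C→T** — alt forward reads are indistinguishable from converted
  (unmethylated) cytosines, so both strands agree at ~m/2 and the variant
  is invisible to strand comparison; only the base-paired evidence in
  reverse-strand reads reveals it.

The result: sites whose "methylation" is really the carrier's genotype —
static across tissues of one individual, variable between individuals,
linearly ordered by allele dosage, and a re-identification risk when
tracks are released openly.  `methleak` is for epigenomics data producers
and stewards who need to quantify and eliminate that channel before
release, and for methods work that needs ground-truthed cohorts of
contaminated methylomes.

## What's in the box

| module | role |
|---|---|
| `methleak.synthetic_cohort` | ground-truthed stranded WGBS cohorts (individuals × tissues, MZ/DZ twins) with CpG-disrupting SNPs and indirect meQTLs under the strand read-accounting model |
| `methleak.methio` | Bismark-style cytosine reports, bedGraph, VCF (via pysam), BED SNP catalogs, sample sheets; 0-based half-open internally |
| `methleak.leakage_screen` | static-within / variable-between-individual screen (SD < 0.07 in a strict majority of individuals with ≥3 samples, range ≥ 0.15) with a permutation null |
| `methleak.genotype_correlation` | OLS of methylation on alt-allele dosage per CpG–SNP pair within ±10 kb; r > 0.5, p < 0.05 "correlated", accuracy > 0.98 "highly predictive"; twin pairwise correlations |
| `methleak.strand_audit` | strand-discordance test and a Bayesian genotype caller over the 10 diploid genotypes from strand counts + reverse-strand base evidence |
| `methleak.diffmeth_audit` | fraction of differential methylation (|Δ| > 30 %, ≥15×) explained by called variants, by pair design |
| `methleak.sanitizer` | dyad-level removal of detected/catalogued variants and unclear contexts, with an accounting report and a release gate |
| `methleak.pipeline` / CLI `methleak` | seeded simulate → screen → correlate → callgeno → diffaudit → sanitize with a JSON summary |

## The model in brief

Methylation at an intact CpG linked to a nearby SNP is treated as linear
in alt-allele dosage d ∈ {0, 1, 2}: each allele carries its own mean
methylation and a diploid sample averages them, `meth = β₀ + β₁·d + ε`.
Genotype is re-predicted as the dosage whose fitted mean is nearest the
observed methylation.  The genotype caller combines a multinomial on
reverse-strand base counts with binomials on the per-strand methylation
counts (expected rates from the read accounting, methylation marginalized
over a grid) under rare-variant or Hardy–Weinberg catalog priors.  See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

```python
from methleak import CohortDesign, simulate_cohort
from methleak.methio import build_meth_matrix
from methleak.leakage_screen import screen_static_cpgs, permutation_null_yield
from methleak.strand_audit import call_genotypes_for_sample
from methleak.sanitizer import sanitize_track

design = CohortDesign(n_individuals=5, tissues=("blood", "muscle", "bone"),
                      n_cpgs=1000, n_snps=400, fraction_cpg_disrupting=0.1, seed=42)
cohort = simulate_cohort(design)

calls = {sid: cohort.stranded_calls(sid) for sid in cohort.evidence}
matrix = build_meth_matrix(calls, min_coverage=4)
sample_map = dict(zip(cohort.samples["sample_id"], cohort.samples["individual_id"]))

screen = screen_static_cpgs(matrix, sample_map)
null = permutation_null_yield(matrix, sample_map, n_perm=10, seed=0)
print(int(screen["is_candidate"].sum()), "candidates; null yield", null["mean_yield"])

sid = "ind000_blood"
geno = call_genotypes_for_sample(cohort.evidence[sid], sample_id=sid)
clean, report, log = sanitize_track(calls[sid], variant_calls=geno, policy="detected")
print(f"retained {report.n_retained}/{report.n_total_sites} "
      f"({report.retention_fraction:.1%})")
```

prints

```
393 candidates; null yield 363.7
retained 985/1000 (98.5%)
```

The screen flags 393 of 1000 dyads, but its permutation null — the same
screen run with individual labels shuffled — already yields ~364, so the
genotype-driven excess is ~29 sites; exactly 29 of the candidates overlap
a simulated CpG-disrupting SNP.  For the single sample shown, the caller
finds 15 dyads where this individual carries a variant allele, and the
detected-policy sanitizer removes precisely those, retaining 98.5 % of the
track.

The same flow from the shell:

```sh
methleak simulate --outdir sim --seed 42
methleak screen --reports sim/reports --samples sim/sample_sheet.tsv --out candidates.tsv
methleak callgeno --evidence sim/evidence/ind000_tissue00.evidence.tsv --out calls.vcf
methleak sanitize --report sim/reports/ind000_tissue00.cytosine_report.tsv \
    --calls calls.vcf --catalog sim/snp_catalog.bed --policy both \
    --out clean.bedGraph --report-out report.json
methleak run --config pipeline.yaml --outdir run1   # the whole pipeline
```

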