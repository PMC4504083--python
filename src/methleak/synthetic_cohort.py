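"""Ground-truthed synthetic WGBS cohorts with embedded genetic variants.

Strand-specific whole-genome bisulfite sequencing (WGBS) measures CpG
methylation on the forward and reverse strands independently.  A SNP that
replaces the forward-strand C of a CpG dyad breaks that symmetry in an
allele-specific way:

* ``C>A`` / ``C>G``: forward-strand reads from the alt allele no longer carry
  a cytosine at the site and are dropped by the methylation extractor, while
  reverse-strand reads still carry the dyad's reverse C — now in a CpH
  context — and are scored (essentially) unmethylated.  A heterozygote
  therefore shows ~50 percentage points more methylation on the forward than
  the reverse strand at a fully methylated site.
* ``C>T``: alt-allele forward reads look exactly like bisulfite-converted
  (unmethylated) cytosines and are miscounted as such; reverse reads measure
  CpH methylation of the mutated allele.  Both strands agree at ~m/2, so the
  variant is invisible to strand comparison and only the base-paired evidence
  in reverse-strand reads reveals it.

This module simulates cohorts (individuals x tissues, optional MZ/DZ twin
pairs) of per-strand CpG read counts under that accounting, with indirect
meQTL effects (a nearby SNP shifting true methylation at an intact CpG),
bimodal baseline methylation, non-conversion / sequencing error, and
per-strand Poisson coverage.  Ground truth (variants, dosages, true
methylation) is retained so downstream detection can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "CohortDesign",
    "SimulatedTruth",
    "CohortResult",
    "apply_disruption_accounting",
    "simulate_reverse_base_evidence",
    "simulate_cohort",
    "emit_array_like_betas",
]

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: window within which an indirect meQTL SNP is placed, in bp
MEQTL_WINDOW_BP = 10_000


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of a simulated cohort.

    Defaults emulate a multi-tissue reference-epigenome design: five
    individuals sampled across ten tissues (~50 tracks), bimodal baseline
    methylation, 15x per-strand coverage and typical WGBS error rates.
    """

    n_individuals: int = 5
    tissues: Sequence[str] = tuple(f"tissue{i:02d}" for i in range(10))
    #: (individual_a, individual_b, kind) with kind in {"MZ", "DZ", "unrelated"}
    relationships: Sequence[tuple[int, int, str]] = ()
    n_cpgs: int = 2000
    n_snps: int = 400
    fraction_cpg_disrupting: float = 0.10
    #: probabilities over the three disrupting substitutions (C>A, C>G, C>T)
    disruption_allele_probs: tuple[float, float, float] = (0.25, 0.25, 0.50)
    fraction_indirect_meqtl: float = 0.05
    meqtl_effect: float = 0.20
    maf_beta_params: tuple[float, float] = (1.0, 3.0)
    coverage_mean_per_strand: float = 15.0
    non_conversion_rate: float = 0.005
    sequencing_error_rate: float = 0.001
    cph_methylation_rate: float = 0.01
    tissue_effect_sd: float = 0.02
    residual_sd: float = 0.02
    #: (weight_of_methylated_mode, (a_meth, b_meth), (a_unmeth, b_unmeth))
    baseline_mixture: tuple[float, tuple[float, float], tuple[float, float]] = (
        0.70,
        (10.0, 0.5),
        (0.5, 10.0),
    )
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first invalid field."""
        for name in ("n_individuals", "n_cpgs", "n_snps"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if len(self.tissues) < 1:
            raise ConfigurationError("tissues must contain at least one label")
        if len(set(self.tissues)) != len(self.tissues):
            raise ConfigurationError("tissues labels must be unique")
        for name in (
            "fraction_cpg_disrupting",
            "fraction_indirect_meqtl",
            "non_conversion_rate",
            "sequencing_error_rate",
            "cph_methylation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.disruption_allele_probs) - 1.0) > 1e-9 or min(self.disruption_allele_probs) < 0:
            raise ConfigurationError(
                f"disruption_allele_probs must be non-negative and sum to 1, got {self.disruption_allele_probs}"
            )
        if self.coverage_mean_per_strand < 0:
            raise ConfigurationError("coverage_mean_per_strand must be >= 0")
        for name in ("tissue_effect_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not -1.0 <= self.meqtl_effect <= 1.0:
            raise ConfigurationError("meqtl_effect must lie in [-1, 1]")
        a, b = self.maf_beta_params
        if a <= 0 or b <= 0:
            raise ConfigurationError("maf_beta_params must be positive")
        w, (am, bm), (au, bu) = self.baseline_mixture
        if not 0.0 <= w <= 1.0 or min(am, bm, au, bu) <= 0:
            raise ConfigurationError("baseline_mixture weight must lie in [0,1] with positive Beta parameters")
        seen: set[int] = set()
        for i, (x, y, kind) in enumerate(self.relationships):
            if kind not in ("MZ", "DZ", "unrelated"):
                raise ConfigurationError(f"relationships[{i}] kind must be MZ|DZ|unrelated, got {kind!r}")
            if not (0 <= x < self.n_individuals and 0 <= y < self.n_individuals) or x == y:
                raise ConfigurationError(f"relationships[{i}] refers to invalid individuals ({x}, {y})")
            if kind != "unrelated" and (x in seen or y in seen):
                raise ConfigurationError(f"relationships[{i}]: individual appears in more than one twin pair")
            if kind != "unrelated":
                seen.update((x, y))
        n_disrupt = round(self.fraction_cpg_disrupting * self.n_snps)
        n_meqtl = round(self.fraction_indirect_meqtl * self.n_cpgs)
        if n_disrupt + n_meqtl > self.n_snps:
            raise ConfigurationError(
                "n_snps too small for requested fraction_cpg_disrupting and fraction_indirect_meqtl "
                f"({n_disrupt} disrupting + {n_meqtl} meQTL > {self.n_snps})"
            )
        if n_disrupt > self.n_cpgs or n_meqtl > self.n_cpgs - n_disrupt:
            raise ConfigurationError("n_cpgs too small for requested disrupting/meQTL fractions")

    def with_(self, **kwargs) -> "CohortDesign":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SimulatedTruth:
    """Ground truth for one simulated cohort.

    Attributes
    ----------
    cpgs : per-CpG table (cpg_id, chrom, pos of the forward-strand C, 0-based;
        disrupt_snp/disrupt_alt for a variant at the C; linked_snp/linked_effect
        for an indirect meQTL).
    snps : per-SNP table (snp_id, chrom, pos, ref, alt, maf, kind).
    dosages : alt-allele dosage matrix, SNPs x individuals, values in {0,1,2}.
    baseline : baseline methylation, CpGs x tissues.
    true_meth : true (pre-sequencing) methylation, CpGs x samples.
    """

    cpgs: pd.DataFrame
    snps: pd.DataFrame
    dosages: pd.DataFrame
    baseline: pd.DataFrame
    true_meth: pd.DataFrame

    def disrupted_cpg_ids(self) -> list[str]:
        return list(self.cpgs.loc[self.cpgs["disrupt_snp"].notna(), "cpg_id"])


@dataclass
class CohortResult:
    """Everything :func:`simulate_cohort` produces."""

    design: CohortDesign
    truth: SimulatedTruth
    #: sample sheet: sample_id, individual_id, tissue, relationship_group
    samples: pd.DataFrame
    #: per-sample wide evidence: chrom, pos, fwd_meth, fwd_unmeth, rev_meth,
    #: rev_unmeth, rev_A, rev_C, rev_G, rev_T
    evidence: dict[str, pd.DataFrame]

    def stranded_calls(self, sample_id: str) -> pd.DataFrame:
        """Long-format per-strand calls (two records per dyad, '+' then '-').

        A forward record with zero coverage marks a dyad that is unmeasurable
        on the forward strand (homozygous C>A/C>G), as distinct from missing.
        """
        ev = self.evidence[sample_id]
        fwd = pd.DataFrame(
            {
                "chrom": ev["chrom"],
                "pos": ev["pos"],
                "strand": "+",
                "meth_count": ev["fwd_meth"],
                "unmeth_count": ev["fwd_unmeth"],
            }
        )
        rev = fwd.copy()
        rev["strand"] = "-"
        rev["meth_count"] = ev["rev_meth"].to_numpy()
        rev["unmeth_count"] = ev["rev_unmeth"].to_numpy()
        out = pd.concat([fwd, rev], ignore_index=True)
        out["sample_id"] = sample_id
        return out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def _observed_rate(raw: np.ndarray | float, non_conversion: float, seq_error: float):
    """Mix error terms into a true per-read methylation probability.

    ``non_conversion`` is modeled as a symmetric conversion-error rate: an
    unmethylated C escaping conversion (scored methylated) and a methylated C
    converting inappropriately (scored unmethylated) are both rare and one
    rate captures both, so a fully methylated site reads ``1 - nc``.  A
    sequencing error flips the read base uniformly over the other three
    bases, crossing the methylated/unmethylated boundary with probability
    ``seq_error / 3``.
    """
    raw = np.asarray(raw, dtype=float)
    q = raw * (1.0 - non_conversion) + (1.0 - raw) * non_conversion
    e3 = seq_error / 3.0
    return q * (1.0 - e3) + (1.0 - q) * e3


def apply_disruption_accounting(
    genotype: str | Sequence[str],
    true_meth: float,
    *,
    non_conversion_rate: float = 0.0,
    sequencing_error_rate: float = 0.0,
    cph_methylation_rate: float = 0.0,
) -> tuple[float, float, float]:
    """Expected per-strand measured methylation rates at a CpG whose forward C
    may carry a variant.

    Per-read accounting, applied to each of the two alleles:

    * forward strand — a ``C`` read reports methylation ``m``; a ``T`` read is
      indistinguishable from a converted C and is scored unmethylated; ``A``
      and ``G`` reads carry no cytosine and are dropped (they reduce forward
      coverage instead of contributing a call).
    * reverse strand — the dyad's reverse-strand C is present on every allele
      (the dyad's G is not the mutated base); on a ``C`` allele it sits in a
      CpG context and reports ``m``, on any alt allele the context is CpH and
      it reports the residual CpH methylation rate.

    Returns ``(expected_forward_rate, expected_reverse_rate,
    forward_coverage_factor)``; the forward rate is ``nan`` when no allele
    contributes forward reads (homozygous C>A / C>G, coverage factor 0).
    Error terms (non-conversion, sequencing error) are mixed in afterwards.
    """
    if not 0.0 <= true_meth <= 1.0:
        raise ValueError(f"true_meth must lie in [0, 1], got {true_meth}")
    alleles = tuple(genotype)
    if len(alleles) != 2 or any(a not in BASES for a in alleles):
        raise ValueError(f"genotype must be two bases from ACGT, got {genotype!r}")
    m = float(true_meth)

    fwd_contrib = [m if a == "C" else 0.0 for a in alleles if a in ("C", "T")]
    coverage_factor = len(fwd_contrib) / 2.0
    rev_raw = float(np.mean([m if a == "C" else cph_methylation_rate for a in alleles]))

    if not fwd_contrib:
        fwd = float("nan")
    else:
        fwd_raw = float(np.mean(fwd_contrib))
        fwd = float(_observed_rate(fwd_raw, non_conversion_rate, sequencing_error_rate))
    rev = float(_observed_rate(rev_raw, non_conversion_rate, sequencing_error_rate))
    return fwd, rev, coverage_factor


def reverse_base_probs(genotype: str | Sequence[str], sequencing_error_rate: float) -> np.ndarray:
    """Probability over {A,C,G,T} of the base observed on a reverse-strand
    read at the forward-C position: the complement of a uniformly drawn
    allele, with per-read error spread uniformly over the other three bases.
    """
    alleles = tuple(genotype)
    p = np.zeros(4)
    for a in alleles:
        comp = BASES.index(COMPLEMENT[a])
        vec = np.full(4, sequencing_error_rate / 3.0)
        vec[comp] = 1.0 - sequencing_error_rate
        p += 0.5 * vec
    return p


def simulate_reverse_base_evidence(
    genotype: str | Sequence[str],
    coverage: int,
    sequencing_error_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> dict[str, int]:
    """Draw the reverse-strand base counts at the forward-C position."""
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = np.random.default_rng(rng)
    counts = rng.multinomial(int(coverage), reverse_base_probs(genotype, sequencing_error_rate))
    return dict(zip(BASES, (int(c) for c in counts)))


# ---------------------------------------------------------------------------
# cohort simulation


def _genotype_categories() -> list[tuple[str, int]]:
    """(alt_base, dosage) categories; alt '.' means no variant at the C."""
    cats = [(".", 0)]
    for alt in ("A", "G", "T"):
        cats.extend([(alt, 0), (alt, 1), (alt, 2)])
    return cats


def _category_alleles(alt: str, dosage: int) -> str:
    if alt == "." or dosage == 0:
        return "CC"
    return "C" + alt if dosage == 1 else alt + alt


def _sample_allele_matrix(design: CohortDesign, maf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Alleles (n_snps, n_individuals, 2) respecting twin structure."""
    n_snps, n_ind = len(maf), design.n_individuals
    hap = rng.random((n_snps, n_ind, 2)) < maf[:, None, None]
    for a, b, kind in design.relationships:
        if kind == "MZ":
            hap[:, b, :] = hap[:, a, :]
        elif kind == "DZ":
            mother = rng.random((n_snps, 2)) < maf[:, None]
            father = rng.random((n_snps, 2)) < maf[:, None]
            for child in (a, b):
                mi = rng.integers(0, 2, size=n_snps)
                fi = rng.integers(0, 2, size=n_snps)
                hap[:, child, 0] = mother[np.arange(n_snps), mi]
                hap[:, child, 1] = father[np.arange(n_snps), fi]
    return hap.astype(np.int8)


def simulate_cohort(design: CohortDesign) -> CohortResult:
    """Simulate a full cohort of strand-specific CpG calls with ground truth.

    Deterministic for a fixed ``design.seed``: identical designs reproduce
    byte-identical tables.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    chrom = "chrS"
    n_cpgs, n_snps = design.n_cpgs, design.n_snps

    # CpG dyads on one synthetic chromosome, spaced so dyads never overlap
    gaps = rng.integers(50, 200, size=n_cpgs)
    cpg_pos = 1000 + np.cumsum(gaps)
    cpg_ids = np.array([f"cpg{i:06d}" for i in range(n_cpgs)])
    dyad_positions = set(cpg_pos.tolist()) | set((cpg_pos + 1).tolist())

    # SNP placement: disrupting (at the forward C), indirect meQTL (<=10 kb
    # from an intact CpG), background
    n_disrupt = round(design.fraction_cpg_disrupting * n_snps)
    n_meqtl = round(design.fraction_indirect_meqtl * n_cpgs)
    n_background = n_snps - n_disrupt - n_meqtl

    disrupted_idx = rng.choice(n_cpgs, size=n_disrupt, replace=False)
    free = np.setdiff1d(np.arange(n_cpgs), disrupted_idx)
    meqtl_idx = rng.choice(free, size=n_meqtl, replace=False)

    snp_rows: list[dict] = []
    taken = set(dyad_positions)

    disrupt_alts = rng.choice(["A", "G", "T"], size=n_disrupt, p=list(design.disruption_allele_probs))
    for k, ci in enumerate(disrupted_idx):
        snp_rows.append(
            {"pos": int(cpg_pos[ci]), "ref": "C", "alt": str(disrupt_alts[k]), "kind": "cpg_disrupting"}
        )

    span_lo, span_hi = int(cpg_pos[0]) - MEQTL_WINDOW_BP, int(cpg_pos[-1]) + MEQTL_WINDOW_BP
    for ci in meqtl_idx:
        while True:
            pos = int(cpg_pos[ci]) + int(rng.integers(-MEQTL_WINDOW_BP, MEQTL_WINDOW_BP + 1))
            if pos > 0 and pos not in taken:
                break
        taken.add(pos)
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        snp_rows.append({"pos": pos, "ref": str(ref), "alt": str(alt), "kind": "meqtl"})

    for _ in range(n_background):
        while True:
            pos = int(rng.integers(max(1, span_lo), span_hi))
            if pos not in taken:
                break
        taken.add(pos)
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        snp_rows.append({"pos": pos, "ref": str(ref), "alt": str(alt), "kind": "background"})

    snps = pd.DataFrame(snp_rows)
    snps.insert(0, "chrom", chrom)
    snps["maf"] = rng.beta(*design.maf_beta_params, size=len(snps))
    snps.insert(0, "snp_id", [f"snp{i:06d}" for i in range(len(snps))])

    individuals = [f"ind{i:03d}" for i in range(design.n_individuals)]
    hap = _sample_allele_matrix(design, snps["maf"].to_numpy(), rng)
    dosage_mat = hap.sum(axis=2)
    dosages = pd.DataFrame(dosage_mat, index=snps["snp_id"], columns=individuals)

    # per-CpG annotation
    disrupt_snp = np.full(n_cpgs, None, dtype=object)
    disrupt_alt = np.full(n_cpgs, None, dtype=object)
    linked_snp = np.full(n_cpgs, None, dtype=object)
    linked_effect = np.zeros(n_cpgs)
    for k, ci in enumerate(disrupted_idx):
        disrupt_snp[ci] = snps["snp_id"].iloc[k]
        disrupt_alt[ci] = snps["alt"].iloc[k]
    meqtl_signs = rng.choice([-1.0, 1.0], size=n_meqtl)
    for k, ci in enumerate(meqtl_idx):
        row = n_disrupt + k
        linked_snp[ci] = snps["snp_id"].iloc[row]
        linked_effect[ci] = meqtl_signs[k] * design.meqtl_effect

    cpgs = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "chrom": chrom,
            "pos": cpg_pos,
            "disrupt_snp": disrupt_snp,
            "disrupt_alt": disrupt_alt,
            "linked_snp": linked_snp,
            "linked_effect": linked_effect,
        }
    )

    # baseline methylation: bimodal Beta mixture, plus per-tissue offsets
    w, (am, bm), (au, bu) = design.baseline_mixture
    methylated_mode = rng.random(n_cpgs) < w
    base = np.where(methylated_mode, rng.beta(am, bm, size=n_cpgs), rng.beta(au, bu, size=n_cpgs))
    tissue_offsets = rng.normal(0.0, design.tissue_effect_sd, size=(n_cpgs, len(design.tissues)))
    baseline = pd.DataFrame(
        np.clip(base[:, None] + tissue_offsets, 0.0, 1.0), index=cpg_ids, columns=list(design.tissues)
    )

    # sample sheet
    group = {}
    for gi, (a, b, kind) in enumerate(design.relationships):
        if kind != "unrelated":
            group[a] = group[b] = f"{kind}{gi:02d}"
    samples = pd.DataFrame(
        [
            {
                "sample_id": f"{ind}_{tissue}",
                "individual_id": ind,
                "tissue": tissue,
                "relationship_group": group.get(i, "none"),
            }
            for i, ind in enumerate(individuals)
            for tissue in design.tissues
        ]
    )

    # true methylation per sample: baseline(tissue) + meQTL shift + residual
    has_link = pd.notna(linked_snp)
    link_rows = np.array(
        [snps.index[snps["snp_id"] == s][0] if s is not None else -1 for s in linked_snp], dtype=int
    )
    true_meth = {}
    for _, srow in samples.iterrows():
        ind_i = individuals.index(srow["individual_id"])
        m = baseline[srow["tissue"]].to_numpy().copy()
        shift = np.zeros(n_cpgs)
        shift[has_link] = linked_effect[has_link] * dosage_mat[link_rows[has_link], ind_i]
        m = m + shift + rng.normal(0.0, design.residual_sd, size=n_cpgs)
        true_meth[srow["sample_id"]] = np.clip(m, 0.0, 1.0)
    true_meth = pd.DataFrame(true_meth, index=cpg_ids)

    # per-CpG genotype category per individual
    alt_code = np.where(pd.isna(disrupt_alt), ".", disrupt_alt).astype(str)
    disrupt_rows = np.array(
        [snps.index[snps["snp_id"] == s][0] if s is not None else -1 for s in disrupt_snp], dtype=int
    )
    cpg_dosage = np.zeros((n_cpgs, design.n_individuals), dtype=int)
    mask = disrupt_rows >= 0
    cpg_dosage[mask, :] = dosage_mat[disrupt_rows[mask], :]

    # strand-rate coefficients per category, affine in m (from the scalar op)
    coef = {}
    for alt, d in _genotype_categories():
        gt = _category_alleles(alt, d)
        f0, r0, cf = apply_disruption_accounting(gt, 0.0, cph_methylation_rate=design.cph_methylation_rate)
        f1, r1, _ = apply_disruption_accounting(gt, 1.0, cph_methylation_rate=design.cph_methylation_rate)
        coef[(alt, d)] = (
            (0.0, 0.0) if cf == 0.0 else (f0, f1 - f0),
            (r0, r1 - r0),
            cf,
            reverse_base_probs(gt, design.sequencing_error_rate),
        )

    evidence: dict[str, pd.DataFrame] = {}
    cov_mean = design.coverage_mean_per_strand
    for _, srow in samples.iterrows():
        sid = srow["sample_id"]
        ind_i = individuals.index(srow["individual_id"])
        m = true_meth[sid].to_numpy()
        fwd_rate = np.zeros(n_cpgs)
        rev_rate = np.zeros(n_cpgs)
        covfac = np.ones(n_cpgs)
        base_p = np.zeros((n_cpgs, 4))
        for (alt, d), ((fa, fb), (ra, rb), cf, pvec) in coef.items():
            sel = (alt_code == alt) & (cpg_dosage[:, ind_i] == d) if alt != "." else (alt_code == ".")
            if not sel.any():
                continue
            fwd_rate[sel] = fa + fb * m[sel]
            rev_rate[sel] = ra + rb * m[sel]
            covfac[sel] = cf
            base_p[sel] = pvec
        fwd_obs = _observed_rate(fwd_rate, design.non_conversion_rate, design.sequencing_error_rate)
        rev_obs = _observed_rate(rev_rate, design.non_conversion_rate, design.sequencing_error_rate)

        fwd_cov = rng.poisson(cov_mean * covfac)
        rev_cov = rng.poisson(cov_mean, size=n_cpgs)
        fwd_meth = rng.binomial(fwd_cov, fwd_obs)
        rev_meth = rng.binomial(rev_cov, rev_obs)
        rev_bases = np.zeros((n_cpgs, 4), dtype=int)
        # multinomial draws grouped by shared probability vector
        for (alt, d), (_, _, _, pvec) in coef.items():
            sel = (alt_code == alt) & (cpg_dosage[:, ind_i] == d) if alt != "." else (alt_code == ".")
            if not sel.any():
                continue
            rev_bases[sel] = rng.multinomial(rev_cov[sel], pvec)
        evidence[sid] = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": cpg_pos,
                "fwd_meth": fwd_meth,
                "fwd_unmeth": fwd_cov - fwd_meth,
                "rev_meth": rev_meth,
                "rev_unmeth": rev_cov - rev_meth,
                "rev_A": rev_bases[:, 0],
                "rev_C": rev_bases[:, 1],
                "rev_G": rev_bases[:, 2],
                "rev_T": rev_bases[:, 3],
            }
        )

    truth = SimulatedTruth(cpgs=cpgs, snps=snps, dosages=dosages, baseline=baseline, true_meth=true_meth)
    return CohortResult(design=design, truth=truth, samples=samples, evidence=evidence)


def expected_pooled_rate(
    genotype: str | Sequence[str], true_meth: float, cph_methylation_rate: float = 0.0
) -> float:
    """Coverage-weighted pooled-strand expected rate (no error terms).

    Weights are the forward coverage factor and 1 for the reverse strand, so
    a C/A heterozygote at m pools to 2m/3 and a homozygous alt A/A dyad
    reports only reverse-strand CpH methylation.
    """
    fwd, rev, cf = apply_disruption_accounting(genotype, true_meth, cph_methylation_rate=cph_methylation_rate)
    if cf == 0.0:
        return rev
    return (cf * fwd + rev) / (cf + 1.0)


def emit_array_like_betas(
    truth: SimulatedTruth,
    sample_ids: Sequence[str] | None = None,
    *,
    cpg_ids: Sequence[str] | None = None,
    sample_to_individual: Mapping[str, str] | None = None,
    noise_sd: float = 0.03,
    cph_methylation_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Non-stranded, array-like methylation betas (CpGs x samples).

    Each beta is the pooled-strand expected rate under the disruption
    accounting plus Gaussian noise, clipped to [0, 1] — a deliberate
    simplification of bead-array measurement.  CpGs whose "methylation" is
    genotype produce three dosage-separated beta clusters.
    """
    rng = np.random.default_rng(rng)
    if sample_ids is None:
        sample_ids = list(truth.true_meth.columns)
    if cpg_ids is None:
        cpg_ids = list(truth.true_meth.index)
    cpgs = truth.cpgs.set_index("cpg_id").loc[list(cpg_ids)]
    if sample_to_individual is None:
        # default sample ids are "<individual>_<tissue>"
        sample_to_individual = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    ind_of = sample_to_individual

    out = np.empty((len(cpg_ids), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        ind = ind_of[sid]
        for i, cg in enumerate(cpg_ids):
            m = float(truth.true_meth.at[cg, sid])
            snp = cpgs.at[cg, "disrupt_snp"]
            if pd.isna(snp):
                rate = m
            else:
                d = int(truth.dosages.at[snp, ind])
                gt = _category_alleles(str(cpgs.at[cg, "disrupt_alt"]), d)
                rate = expected_pooled_rate(gt, m, cph_methylation_rate)
            out[i, j] = rate
    out = out + rng.normal(0.0, noise_sd, size=out.shape) if noise_sd > 0 else out
    return pd.DataFrame(np.clip(out, 0.0, 1.0), index=list(cpg_ids), columns=list(sample_ids))
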