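"""Strand-discordance detection and genotype calling from bisulfite evidence.

Bisulfite conversion destroys the distinction between an unmethylated C and
a T on the read strand, but it leaves the *opposite* strand's base intact:
a reverse-strand read at the forward-C position reports the base-paired
complement of whichever allele the fragment came from.  Combining

* the reverse-strand base counts (multinomial over {A,C,G,T}), and
* the forward/reverse methylation read counts (binomials whose expected
  rates under each genotype follow the strand read-accounting model),

gives a posterior over the 10 unordered diploid genotypes at the forward C.
The unknown true methylation is a nuisance parameter marginalized over a
small grid (default {0, 0.5, 1}).  Priors are either "rare" (mass 1-theta
on C/C, theta split over variant genotypes — the worst case of no external
catalog) or "catalog" (Hardy-Weinberg from a known-SNP catalog's allele
frequency).  This is a deliberately simplified count-level caller in the
spirit of Bis-SNP: no base-quality recalibration or realignment — it audits
genotype leakage, it does not replace a production caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import MethleakError
from .methio import SnpCatalog
from .synthetic_cohort import BASES, apply_disruption_accounting, reverse_base_probs

__all__ = [
    "StrandEvidence",
    "GenotypeCall",
    "GENOTYPES",
    "strand_asymmetry",
    "call_genotype",
    "call_genotypes_for_sample",
    "evaluate_calls",
]

#: the 10 unordered diploid genotypes over {A,C,G,T}
GENOTYPES: tuple[str, ...] = tuple("".join(p) for p in combinations_with_replacement(BASES, 2))
_REF_IDX = GENOTYPES.index("CC")


@dataclass
class StrandEvidence:
    chrom: str
    pos: int
    fwd_meth: int
    fwd_unmeth: int
    rev_meth: int
    rev_unmeth: int
    rev_base_counts: Mapping[str, int]
    sample_id: str | None = None

    @property
    def depth(self) -> int:
        return self.fwd_meth + self.fwd_unmeth + self.rev_meth + self.rev_unmeth


@dataclass
class GenotypeCall:
    chrom: str
    pos: int
    genotype: str
    posterior: float
    filter: str  # PASS | LOW_COV | AMBIGUOUS
    depth: int
    sample_id: str | None = None


@dataclass
class AsymmetryResult:
    difference: float
    p_value: float
    discordant: bool
    assessable: bool


def strand_asymmetry(
    fwd_meth: int,
    fwd_unmeth: int,
    rev_meth: int,
    rev_unmeth: int,
    min_diff: float = 0.2,
    p_max: float = 0.01,
) -> AsymmetryResult:
    """Test a dyad for strand-discordant methylation.

    Discordant iff |forward rate - reverse rate| > ``min_diff`` AND the
    exact two-proportion (Fisher) test on the 2x2 methylated/unmethylated x
    strand table gives p < ``p_max``.  A strand with zero coverage makes the
    site NOT_ASSESSABLE (assessable=False, no verdict).
    """
    nf, nr = fwd_meth + fwd_unmeth, rev_meth + rev_unmeth
    if nf == 0 or nr == 0:
        return AsymmetryResult(float("nan"), float("nan"), False, False)
    diff = fwd_meth / nf - rev_meth / nr
    _, p = stats.fisher_exact([[fwd_meth, fwd_unmeth], [rev_meth, rev_unmeth]])
    return AsymmetryResult(float(diff), float(p), bool(abs(diff) > min_diff and p < p_max), True)


# ---------------------------------------------------------------------------
# genotype calling


def _model_tables(
    meth_grid: Sequence[float],
    error_rate: float,
    non_conversion_rate: float,
    cph_methylation_rate: float,
):
    """Per-genotype base probabilities and per-(genotype, m) strand rates."""
    base_p = np.stack([reverse_base_probs(g, error_rate) for g in GENOTYPES])  # (10, 4)
    n_m = len(meth_grid)
    fwd_p = np.zeros((len(GENOTYPES), n_m))
    rev_p = np.zeros((len(GENOTYPES), n_m))
    covfac = np.zeros(len(GENOTYPES))
    for gi, g in enumerate(GENOTYPES):
        for mi, m in enumerate(meth_grid):
            f, r, cf = apply_disruption_accounting(
                g,
                m,
                non_conversion_rate=non_conversion_rate,
                sequencing_error_rate=error_rate,
                cph_methylation_rate=cph_methylation_rate,
            )
            fwd_p[gi, mi] = 0.0 if np.isnan(f) else f
            rev_p[gi, mi] = r
            covfac[gi] = cf
    return base_p, fwd_p, rev_p, covfac


def _log_priors_rare(theta: float) -> np.ndarray:
    lp = np.full(len(GENOTYPES), np.log(theta / (len(GENOTYPES) - 1)))
    lp[_REF_IDX] = np.log1p(-theta)
    return lp


def _log_priors_catalog(freq: float, eps: float = 1e-6) -> np.ndarray:
    """Hardy-Weinberg prior for a catalog SNP of unknown alt identity.

    Het and hom-alt mass is split evenly over the three possible alt bases;
    a small epsilon covers genotypes without the reference allele pairing.
    """
    p = np.full(len(GENOTYPES), eps / len(GENOTYPES))
    hw_cc = (1.0 - freq) ** 2
    hw_het = 2.0 * freq * (1.0 - freq)
    hw_hom = freq**2
    for gi, g in enumerate(GENOTYPES):
        if g == "CC":
            p[gi] += hw_cc
        elif "C" in g:
            p[gi] += hw_het / 3.0
        elif g[0] == g[1]:
            p[gi] += hw_hom / 3.0
    return np.log(p / p.sum())


def _loglik(
    fwd_meth: np.ndarray,
    fwd_unmeth: np.ndarray,
    rev_meth: np.ndarray,
    rev_unmeth: np.ndarray,
    base_counts: np.ndarray,  # (N, 4)
    tables,
) -> np.ndarray:
    """Log-likelihood matrix (N sites, 10 genotypes), methylation marginalized.

    Constant combinatorial coefficients are dropped (they cancel in the
    posterior).  Genotypes with forward coverage factor 0 have likelihood 0
    whenever forward reads were observed.
    """
    base_p, fwd_p, rev_p, covfac = tables
    with np.errstate(divide="ignore"):
        # floor instead of -inf so 0-count * log(0) contributes 0 in the matmul
        log_base_p = np.where(base_p > 0, np.log(np.clip(base_p, 1e-300, None)), -1e6)
        log_fwd_p = np.log(fwd_p)  # (10, M)
        log_fwd_q = np.log1p(-fwd_p)
        log_rev_p = np.log(rev_p)
        log_rev_q = np.log1p(-rev_p)

    # reverse-strand base evidence, independent of m
    ll_bases = base_counts @ log_base_p.T  # (N, 10)

    # strand methylation evidence per grid point m
    fm, fu = fwd_meth[:, None, None], fwd_unmeth[:, None, None]
    rm, ru = rev_meth[:, None, None], rev_unmeth[:, None, None]
    with np.errstate(invalid="ignore"):
        ll_fwd = fm * log_fwd_p[None] + fu * log_fwd_q[None]  # (N, 10, M)
        ll_rev = rm * log_rev_p[None] + ru * log_rev_q[None]
    # 0 * -inf -> nan means "no reads at an impossible rate": contributes 0
    ll_fwd = np.nan_to_num(ll_fwd, nan=0.0, neginf=-np.inf)
    ll_rev = np.nan_to_num(ll_rev, nan=0.0, neginf=-np.inf)
    # genotypes that produce no forward reads are impossible given any
    zero_cf = covfac == 0.0
    fwd_total = (fwd_meth + fwd_unmeth)[:, None, None]
    ll_fwd = np.where(zero_cf[None, :, None] & (fwd_total > 0), -np.inf, np.where(zero_cf[None, :, None], 0.0, ll_fwd))

    ll_m = logsumexp(ll_fwd + ll_rev, axis=2) - np.log(ll_fwd.shape[2])  # uniform grid weight
    return ll_bases + ll_m


def call_genotypes_for_sample(
    evidence: pd.DataFrame,
    prior_mode: str = "rare",
    theta: float = 0.001,
    error_rate: float = 0.001,
    non_conversion_rate: float = 0.005,
    cph_methylation_rate: float = 0.01,
    min_depth: int = 10,
    posterior_min: float = 0.9,
    meth_grid: Sequence[float] = (0.0, 0.5, 1.0),
    catalog: SnpCatalog | None = None,
    default_catalog_freq: float = 0.05,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Call genotypes at every dyad of a per-sample evidence table.

    ``evidence`` has columns chrom, pos, fwd_meth, fwd_unmeth, rev_meth,
    rev_unmeth, rev_A, rev_C, rev_G, rev_T (as produced by the simulator).
    Returns a frame with chrom, pos, genotype, posterior, filter, depth.
    Sites with zero total evidence are filtered LOW_COV with no call.
    """
    if prior_mode not in ("rare", "catalog"):
        raise MethleakError(f"prior_mode must be 'rare' or 'catalog', got {prior_mode!r}")
    if prior_mode == "catalog" and catalog is None:
        raise MethleakError("prior_mode='catalog' requires a SNP catalog")
    tables = _model_tables(meth_grid, error_rate, non_conversion_rate, cph_methylation_rate)

    fm = evidence["fwd_meth"].to_numpy(dtype=float)
    fu = evidence["fwd_unmeth"].to_numpy(dtype=float)
    rm = evidence["rev_meth"].to_numpy(dtype=float)
    ru = evidence["rev_unmeth"].to_numpy(dtype=float)
    bases = evidence[["rev_A", "rev_C", "rev_G", "rev_T"]].to_numpy(dtype=float)
    depth = (fm + fu + rm + ru).astype(int)

    ll = _loglik(fm, fu, rm, ru, bases, tables)

    if prior_mode == "rare":
        lp = np.broadcast_to(_log_priors_rare(theta), ll.shape)
    else:
        rare = _log_priors_rare(theta)
        lp = np.empty_like(ll)
        for i, (chrom, pos) in enumerate(zip(evidence["chrom"], evidence["pos"])):
            if catalog.overlaps_dyad(chrom, int(pos)):
                f = catalog.frequency(chrom, int(pos))
                if np.isnan(f):
                    f = default_catalog_freq
                lp[i] = _log_priors_catalog(f)
            else:
                lp[i] = rare
    post_log = ll + lp
    norm = logsumexp(post_log, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        post = np.exp(post_log - norm)
    degenerate = ~np.isfinite(norm[:, 0])
    post[degenerate] = 0.0

    best = np.argmax(post, axis=1)
    best_p = post[np.arange(len(post)), best]
    genotype = np.array(GENOTYPES, dtype=object)[best]
    filt = np.where(depth < min_depth, "LOW_COV", np.where(best_p >= posterior_min, "PASS", "AMBIGUOUS"))
    filt = np.where(degenerate, "AMBIGUOUS", filt)
    out = pd.DataFrame(
        {
            "chrom": evidence["chrom"].to_numpy(),
            "pos": evidence["pos"].to_numpy(),
            "genotype": genotype,
            "posterior": best_p,
            "filter": filt,
            "depth": depth,
        }
    )
    if sample_id is not None:
        out["sample_id"] = sample_id
    return out


def call_genotype(
    evidence: StrandEvidence,
    prior_mode: str = "rare",
    theta: float = 0.001,
    error_rate: float = 0.001,
    non_conversion_rate: float = 0.005,
    cph_methylation_rate: float = 0.01,
    min_depth: int = 10,
    posterior_min: float = 0.9,
    meth_grid: Sequence[float] = (0.0, 0.5, 1.0),
    catalog: SnpCatalog | None = None,
    catalog_freq: float | None = None,
) -> GenotypeCall:
    """Call the diploid genotype at one dyad (see module docstring).

    ``catalog_freq`` may supply the allele frequency directly in catalog
    mode, bypassing the catalog lookup.  Raises on all-zero evidence.
    """
    if evidence.depth == 0 and sum(evidence.rev_base_counts.values()) == 0:
        raise MethleakError(f"no evidence at {evidence.chrom}:{evidence.pos}")
    df = pd.DataFrame(
        [
            {
                "chrom": evidence.chrom,
                "pos": evidence.pos,
                "fwd_meth": evidence.fwd_meth,
                "fwd_unmeth": evidence.fwd_unmeth,
                "rev_meth": evidence.rev_meth,
                "rev_unmeth": evidence.rev_unmeth,
                **{f"rev_{b}": evidence.rev_base_counts.get(b, 0) for b in BASES},
            }
        ]
    )
    if prior_mode == "catalog" and catalog_freq is not None:
        catalog = SnpCatalog(
            pd.DataFrame({"chrom": [evidence.chrom], "pos": [evidence.pos], "freq": [catalog_freq]})
        )
    calls = call_genotypes_for_sample(
        df,
        prior_mode=prior_mode,
        theta=theta,
        error_rate=error_rate,
        non_conversion_rate=non_conversion_rate,
        cph_methylation_rate=cph_methylation_rate,
        min_depth=min_depth,
        posterior_min=posterior_min,
        meth_grid=meth_grid,
        catalog=catalog,
    )
    row = calls.iloc[0]
    return GenotypeCall(
        chrom=evidence.chrom,
        pos=evidence.pos,
        genotype=str(row["genotype"]),
        posterior=float(row["posterior"]),
        filter=str(row["filter"]),
        depth=int(row["depth"]),
        sample_id=evidence.sample_id,
    )


def genotype_posteriors(evidence: StrandEvidence, **kwargs) -> pd.Series:
    """Full normalized posterior over the 10 genotypes for one dyad."""
    prior_mode = kwargs.get("prior_mode", "rare")
    theta = kwargs.get("theta", 0.001)
    tables = _model_tables(
        kwargs.get("meth_grid", (0.0, 0.5, 1.0)),
        kwargs.get("error_rate", 0.001),
        kwargs.get("non_conversion_rate", 0.005),
        kwargs.get("cph_methylation_rate", 0.01),
    )
    bases = np.array([[evidence.rev_base_counts.get(b, 0) for b in BASES]], dtype=float)
    ll = _loglik(
        np.array([evidence.fwd_meth], dtype=float),
        np.array([evidence.fwd_unmeth], dtype=float),
        np.array([evidence.rev_meth], dtype=float),
        np.array([evidence.rev_unmeth], dtype=float),
        bases,
        tables,
    )
    if prior_mode == "catalog":
        lp = _log_priors_catalog(kwargs["catalog_freq"])
    else:
        lp = _log_priors_rare(theta)
    post_log = ll[0] + lp
    post = np.exp(post_log - logsumexp(post_log))
    return pd.Series(post, index=list(GENOTYPES))


def evaluate_calls(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    require_pass: bool = True,
) -> dict:
    """Score calls against truth genotypes at shared dyads.

    ``truth`` has chrom, pos, genotype (unordered two-base strings).
    ``het_sensitivity`` is the fraction of true C/x heterozygotes whose exact
    genotype was called (PASS only by default); ``false_variant_rate`` is the
    fraction of genotyped positions with a spurious or incorrect variant
    call (a non-reference call that does not match the truth).
    """
    t = truth.copy()
    t["genotype"] = t["genotype"].map(lambda g: "".join(sorted(g)))
    c = calls.copy()
    c["genotype"] = c["genotype"].map(lambda g: "".join(sorted(g)))
    merged = t.merge(c, on=["chrom", "pos"], suffixes=("_true", "_called"), how="inner")
    if merged.empty:
        raise MethleakError("calls and truth share no sites")

    called_ok = (merged["filter"] == "PASS") if require_pass else np.ones(len(merged), dtype=bool)

    is_het = merged["genotype_true"].map(lambda g: "C" in g and g != "CC")
    detected = called_ok & (merged["genotype_called"] == merged["genotype_true"])
    het_sensitivity = float((detected & is_het).sum() / is_het.sum()) if is_het.sum() else float("nan")

    variant_called = called_ok & (merged["genotype_called"] != "CC")
    false_variant = variant_called & (merged["genotype_called"] != merged["genotype_true"])
    false_variant_rate = float(false_variant.sum() / len(merged))

    confusion = pd.crosstab(merged["genotype_true"], merged["genotype_called"])
    return {
        "het_sensitivity": het_sensitivity,
        "false_variant_rate": false_variant_rate,
        "n_sites": int(len(merged)),
        "n_true_het": int(is_het.sum()),
        "confusion": confusion,
    }
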