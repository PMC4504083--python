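"""Linear genotype-methylation modelling and twin pairwise correlation.

Each SNP allele is viewed as carrying its own mean methylation rate at a
nearby CpG; a diploid individual's methylation is the average of its two
allelic rates, i.e. linear in the alt-allele dosage d in {0, 1, 2}:

    meth = intercept + slope * d + noise

An ordinary least-squares fit gives slope/intercept, Pearson r and a
two-sided p from the t statistic on n-2 df.  The fitted line is evaluated
at d = 0, 1, 2 (even for dosages absent from the data) and a sample's
genotype is re-predicted as the dosage whose fitted mean is closest to its
observed methylation; the fraction re-predicted correctly is the site's
predictive accuracy.  CpGs with r > 0.5 and p < 0.05 against some SNP
within 10 kb are "genotype-correlated"; those whose best SNP also
re-predicts >98 % of samples are "highly predictive" — methylation there is
effectively a genotyping assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedFitError
from .methio import SnpCatalog

__all__ = [
    "CorrelationResult",
    "fit_cpg_snp",
    "scan_window",
    "predict_genotype",
    "classify_candidates",
    "direct_overlap",
    "pairwise_sample_correlation",
]

DEFAULT_WINDOW_BP = 10_000


@dataclass
class CorrelationResult:
    cpg_id: str
    snp_id: str
    n_samples: int
    slope: float
    intercept: float
    r: float
    p_value: float
    fitted_means: tuple[float, float, float]
    accuracy: float
    direct_overlap: bool | None = None
    distance_bp: int | None = None


def predict_genotype(meth_value: float, fitted_means: Sequence[float]) -> int:
    """Dosage whose fitted mean methylation is closest to the observation.

    Ties break toward the smaller dosage.
    """
    d = np.abs(np.asarray(fitted_means, dtype=float) - float(meth_value))
    return int(np.argmin(d))  # argmin returns the first (smallest dosage) on ties


def fit_cpg_snp(
    meth: Sequence[float],
    dosage: Sequence[int],
    cpg_id: str = "cpg",
    snp_id: str = "snp",
    *,
    loo_accuracy: bool = False,
) -> CorrelationResult:
    """OLS fit of methylation on alt-allele dosage for one CpG-SNP pair.

    Accuracy is resubstitution by default (fit and re-predict on the same
    samples); ``loo_accuracy=True`` switches to leave-one-out refitting.
    Raises :class:`UndefinedFitError` for constant dosage or methylation, or
    fewer than 3 paired observations.
    """
    meth = np.asarray(meth, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    keep = ~(np.isnan(meth) | np.isnan(dosage))
    meth, dosage = meth[keep], dosage[keep]
    n = len(meth)
    if n < 3:
        raise UndefinedFitError(f"{cpg_id}~{snp_id}: need >= 3 paired observations, have {n}")
    if np.ptp(dosage) == 0:
        raise UndefinedFitError(f"{cpg_id}~{snp_id}: dosage is constant")
    if np.ptp(meth) == 0:
        raise UndefinedFitError(f"{cpg_id}~{snp_id}: methylation is constant")

    fit = stats.linregress(dosage, meth)
    fitted = (fit.intercept, fit.intercept + fit.slope, fit.intercept + 2.0 * fit.slope)

    if loo_accuracy:
        correct = 0
        idx = np.arange(n)
        for i in idx:
            m = np.delete(meth, i)
            d = np.delete(dosage, i)
            if np.ptp(d) == 0 or len(m) < 2:
                continue
            f = stats.linregress(d, m)
            fm = (f.intercept, f.intercept + f.slope, f.intercept + 2.0 * f.slope)
            correct += predict_genotype(meth[i], fm) == int(dosage[i])
        accuracy = correct / n
    else:
        pred = np.array([predict_genotype(m, fitted) for m in meth])
        accuracy = float(np.mean(pred == dosage.astype(int)))

    return CorrelationResult(
        cpg_id=cpg_id,
        snp_id=snp_id,
        n_samples=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        fitted_means=tuple(float(x) for x in fitted),
        accuracy=float(accuracy),
    )


def scan_window(
    cpg_id: str,
    cpg_pos: int,
    snp_sites: pd.DataFrame,
    dosages: pd.DataFrame,
    meth: Mapping[str, float] | pd.Series,
    window_bp: int = DEFAULT_WINDOW_BP,
    chrom: str | None = None,
) -> list[CorrelationResult]:
    """Fit every SNP within ±``window_bp`` (inclusive) of a CpG's forward C.

    ``snp_sites`` needs snp_id/chrom/pos; ``dosages`` is snp x individual;
    ``meth`` maps individual -> methylation rate at the CpG.  SNPs with an
    undefined fit (monomorphic in the cohort) are skipped.  Results are
    sorted by |r| descending, ties by distance then snp_id.
    """
    meth = pd.Series(meth)
    sites = snp_sites
    if chrom is not None:
        sites = sites[sites["chrom"] == chrom]
    sel = sites[(sites["pos"] - cpg_pos).abs() <= window_bp]
    results = []
    for _, row in sel.iterrows():
        d = dosages.loc[row["snp_id"], meth.index]
        try:
            res = fit_cpg_snp(meth.to_numpy(), d.to_numpy(), cpg_id=cpg_id, snp_id=row["snp_id"])
        except UndefinedFitError:
            continue
        res.distance_bp = int(abs(int(row["pos"]) - cpg_pos))
        results.append(res)
    results.sort(key=lambda r: (-abs(r.r), r.distance_bp, r.snp_id))
    return results


def direct_overlap(cpg_pos: int, catalog: SnpCatalog, chrom: str) -> bool:
    """True iff a catalog SNP lies within the CpG dyad [pos, pos+2)."""
    return catalog.overlaps_dyad(chrom, cpg_pos)


def classify_candidates(
    results: Iterable[CorrelationResult],
    r_min: float = 0.5,
    p_max: float = 0.05,
    accuracy_min: float = 0.98,
) -> pd.DataFrame:
    """Label CpGs as genotype-correlated and/or highly predictive.

    Each CpG keeps its best SNP (max |r|, ties by proximity then snp_id).
    ``correlated`` requires r > r_min and p < p_max (strict); the
    ``highly_predictive`` class additionally requires accuracy > accuracy_min.
    """
    best: dict[str, CorrelationResult] = {}
    for res in results:
        cur = best.get(res.cpg_id)
        key = (-abs(res.r), res.distance_bp if res.distance_bp is not None else 0, res.snp_id)
        cur_key = None if cur is None else (
            -abs(cur.r), cur.distance_bp if cur.distance_bp is not None else 0, cur.snp_id
        )
        if cur is None or key < cur_key:
            best[res.cpg_id] = res
    rows = []
    for cpg_id, res in best.items():
        correlated = res.r > r_min and res.p_value < p_max
        rows.append(
            {
                "cpg_id": cpg_id,
                "snp_id": res.snp_id,
                "r": res.r,
                "p_value": res.p_value,
                "accuracy": res.accuracy,
                "direct_overlap": res.direct_overlap,
                "correlated": correlated,
                "highly_predictive": correlated and res.accuracy > accuracy_min,
            }
        )
    return pd.DataFrame(rows, columns=[
        "cpg_id", "snp_id", "r", "p_value", "accuracy", "direct_overlap", "correlated", "highly_predictive",
    ])


def pairwise_sample_correlation(
    betas: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation between sample pairs over a CpG beta panel.

    ``betas`` is CpGs x samples; ``pairs`` holds (sample_a, sample_b,
    relationship) with relationship in {MZ, DZ, unrelated}.  Pairs sharing
    fewer than 2 CpGs with non-missing betas are skipped and counted.
    Returns (per-pair table, per-group summary with mean and quartiles).
    """
    rows, n_skipped = [], 0
    for a, b, rel in pairs:
        va = betas[a].to_numpy(dtype=float)
        vb = betas[b].to_numpy(dtype=float)
        keep = ~(np.isnan(va) | np.isnan(vb))
        if keep.sum() < 2:
            n_skipped += 1
            continue
        r = float(np.corrcoef(va[keep], vb[keep])[0, 1])
        rows.append({"sample_a": a, "sample_b": b, "relationship": rel, "n_cpgs": int(keep.sum()), "r": r})
    per_pair = pd.DataFrame(rows, columns=["sample_a", "sample_b", "relationship", "n_cpgs", "r"])
    per_pair.attrs["n_skipped"] = n_skipped
    if per_pair.empty:
        summary = pd.DataFrame(columns=["relationship", "n_pairs", "mean_r", "q25", "median", "q75"])
    else:
        summary = (
            per_pair.groupby("relationship")["r"]
            .agg(n_pairs="size", mean_r="mean", q25=lambda x: x.quantile(0.25),
                 median="median", q75=lambda x: x.quantile(0.75))
            .reset_index()
        )
    return per_pair, summary
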