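"""Audit how much pairwise differential methylation is genetic in origin.

Differentially methylated CpGs between two samples (pooled-strand rate
difference > 30 percentage points at >= 15x coverage in both) are
intersected with the dyads where a sequence variant was called in one or
both samples.  Aggregated over sample pairs grouped by design — same
individual / different tissue, same tissue / different individual, both
differing — the fraction of differential CpGs explained by variants
separates true tissue epigenetics (low fraction) from genotype leakage
(high fraction when only the individual changes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MethleakError
from .methio import pooled_rates

__all__ = ["PairAudit", "differential_cpgs", "audit_pair", "classify_pair_type"]


@dataclass
class PairAudit:
    sample_a: str
    sample_b: str
    pair_type: str  # same_individual_diff_tissue | same_tissue_diff_individual | both_differ
    n_diff_cpgs: int
    n_overlapping_snp: int

    @property
    def fraction_overlap(self) -> float:
        if self.n_diff_cpgs == 0:
            return float("nan")
        return self.n_overlapping_snp / self.n_diff_cpgs


def differential_cpgs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    min_cov: int = 15,
    min_diff: float = 0.30,
) -> pd.DataFrame:
    """Dyads differentially methylated between two samples.

    Strands are pooled per dyad (zero-coverage strands contribute nothing);
    a dyad qualifies iff pooled coverage >= ``min_cov`` in BOTH samples and
    |rate_a - rate_b| > ``min_diff`` (strict).  Returns chrom, pos, rate_a,
    rate_b, delta; empty (with a warning in the logs) when no sites are
    shared.
    """
    ra = pooled_rates(calls_a, min_coverage=1)
    rb = pooled_rates(calls_b, min_coverage=1)
    joined = ra.join(rb, how="inner", lsuffix="_a", rsuffix="_b")
    if joined.empty:
        import warnings

        warnings.warn("differential_cpgs: samples share no sites", stacklevel=2)
        return pd.DataFrame(columns=["chrom", "pos", "rate_a", "rate_b", "delta"])
    ok = (joined["coverage_a"] >= min_cov) & (joined["coverage_b"] >= min_cov)
    delta = joined["rate_a"] - joined["rate_b"]
    hit = joined[ok & (delta.abs() > min_diff)]
    out = hit.reset_index()[["chrom", "pos", "rate_a", "rate_b"]]
    out["delta"] = (hit["rate_a"] - hit["rate_b"]).to_numpy()
    return out


def classify_pair_type(meta_a: pd.Series, meta_b: pd.Series) -> str:
    same_ind = meta_a["individual_id"] == meta_b["individual_id"]
    same_tissue = meta_a["tissue"] == meta_b["tissue"]
    if same_ind and not same_tissue:
        return "same_individual_diff_tissue"
    if same_tissue and not same_ind:
        return "same_tissue_diff_individual"
    if not same_ind and not same_tissue:
        return "both_differ"
    return "replicate"


def audit_pair(
    diff_sites: pd.DataFrame,
    variant_calls_a: pd.DataFrame,
    variant_calls_b: pd.DataFrame,
    sample_meta: pd.DataFrame,
    sample_a: str,
    sample_b: str,
) -> PairAudit:
    """Count differential dyads explained by a variant in one or both samples.

    A dyad overlaps a variant when a non-reference PASS genotype call exists
    at it in either sample.  ``sample_meta`` is the sample sheet (indexed or
    keyed by sample_id); a missing sample raises an error naming it.
    """
    meta = sample_meta.set_index("sample_id") if "sample_id" in sample_meta.columns else sample_meta
    for s in (sample_a, sample_b):
        if s not in meta.index:
            raise MethleakError(f"sample {s!r} missing from the sample sheet")
    pair_type = classify_pair_type(meta.loc[sample_a], meta.loc[sample_b])

    variant_keys: set[tuple[str, int]] = set()
    for calls in (variant_calls_a, variant_calls_b):
        if calls is None or calls.empty:
            continue
        hit = calls[(calls["filter"] == "PASS") & (calls["genotype"] != "CC")]
        variant_keys.update(zip(hit["chrom"], hit["pos"].astype(int)))

    n_diff = int(len(diff_sites))
    if n_diff:
        overlap = [
            (c, int(p)) in variant_keys for c, p in zip(diff_sites["chrom"], diff_sites["pos"])
        ]
        n_overlap = int(np.sum(overlap))
    else:
        n_overlap = 0
    return PairAudit(
        sample_a=sample_a,
        sample_b=sample_b,
        pair_type=pair_type,
        n_diff_cpgs=n_diff,
        n_overlapping_snp=n_overlap,
    )


def audit_cohort(
    calls_by_sample: dict[str, pd.DataFrame],
    variant_calls_by_sample: dict[str, pd.DataFrame],
    sample_meta: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    min_cov: int = 15,
    min_diff: float = 0.30,
) -> pd.DataFrame:
    """Run the pairwise audit over a set of sample pairs (all pairs by default)."""
    sids = list(calls_by_sample)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(sids) for b in sids[i + 1 :]]
    rows = []
    for a, b in pairs:
        diff = differential_cpgs(calls_by_sample[a], calls_by_sample[b], min_cov=min_cov, min_diff=min_diff)
        audit = audit_pair(diff, variant_calls_by_sample.get(a), variant_calls_by_sample.get(b), sample_meta, a, b)
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "pair_type": audit.pair_type,
                "n_diff_cpgs": audit.n_diff_cpgs,
                "n_overlapping_snp": audit.n_overlapping_snp,
                "fraction_overlap": audit.fraction_overlap,
            }
        )
    return pd.DataFrame(rows)
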