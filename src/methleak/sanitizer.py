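"""Pre-release sanitization of methylation tracks.

Open-access methylation tracks leak genotype wherever a sequence variant
disrupts a CpG: the "methylation" value at such a dyad is a function of the
carrier's alleles and can be matched against genotype databases.  The
sanitizer removes those dyads before release:

* ``detected`` policy — drop dyads where the strand-evidence genotype
  caller produced a non-reference PASS call, plus dyads whose cytosine
  context is unclear (an AMBIGUOUS call, or strand-discordant methylation
  with no resolving PASS genotype);
* ``catalog`` policy — drop dyads overlapped by a known-SNP catalog entry
  (the only option for non-stranded platforms);
* ``both`` — the union.

Removal is at dyad level (both strand records go), each removal is logged
with a single reason under the fixed precedence ``called_variant >
catalog > unclear_context``, and retained records are bit-identical to the
input.  :func:`verify_sanitized` re-checks a track against the policy and
is the release gate; sanitization is idempotent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .methio import SnpCatalog
from .strand_audit import strand_asymmetry

__all__ = ["SanitizationReport", "sanitize_track", "verify_sanitized"]

POLICIES = ("detected", "catalog", "both")


@dataclass
class SanitizationReport:
    n_total_sites: int
    n_removed_called_variant: int
    n_removed_catalog: int
    n_removed_unclear_context: int
    n_retained: int
    retention_fraction: float
    policy: str

    def to_dict(self) -> dict:
        return asdict(self)


def _removal_reasons(
    dyads: pd.DataFrame,  # unique chrom/pos
    calls: pd.DataFrame,
    variant_calls: pd.DataFrame | None,
    catalog: SnpCatalog | None,
    policy: str,
    min_diff: float,
    p_max: float,
) -> pd.Series:
    """Reason per dyad ('' = retained), applying the fixed precedence."""
    reasons = pd.Series("", index=pd.MultiIndex.from_frame(dyads[["chrom", "pos"]]))

    use_detected = policy in ("detected", "both")
    use_catalog = policy in ("catalog", "both")

    variant_keys: set[tuple[str, int]] = set()
    ambiguous_keys: set[tuple[str, int]] = set()
    resolved_keys: set[tuple[str, int]] = set()
    if use_detected and variant_calls is not None and not variant_calls.empty:
        vc = variant_calls
        nonref_pass = vc[(vc["filter"] == "PASS") & (vc["genotype"] != "CC")]
        variant_keys = set(zip(nonref_pass["chrom"], nonref_pass["pos"].astype(int)))
        amb = vc[vc["filter"] == "AMBIGUOUS"]
        ambiguous_keys = set(zip(amb["chrom"], amb["pos"].astype(int)))
        res = vc[vc["filter"] == "PASS"]
        resolved_keys = set(zip(res["chrom"], res["pos"].astype(int)))

    discordant_keys: set[tuple[str, int]] = set()
    if use_detected and {"strand", "meth_count", "unmeth_count"}.issubset(calls.columns):
        wide = calls.pivot_table(
            index=["chrom", "pos"], columns="strand", values=["meth_count", "unmeth_count"], aggfunc="sum"
        )
        for (chrom, pos), row in wide.iterrows():
            fm = int(row.get(("meth_count", "+"), 0) or 0)
            fu = int(row.get(("unmeth_count", "+"), 0) or 0)
            rm = int(row.get(("meth_count", "-"), 0) or 0)
            ru = int(row.get(("unmeth_count", "-"), 0) or 0)
            res = strand_asymmetry(fm, fu, rm, ru, min_diff=min_diff, p_max=p_max)
            if res.assessable and res.discordant:
                discordant_keys.add((chrom, int(pos)))

    keys = [(c, int(p)) for c, p in zip(dyads["chrom"], dyads["pos"])]
    out = np.full(len(keys), "", dtype=object)
    cat_hit = np.zeros(len(keys), dtype=bool)
    if use_catalog and catalog is not None:
        for chrom, grp in dyads.groupby("chrom", sort=False):
            cat_hit[grp.index] = catalog.overlaps_dyads(chrom, grp["pos"].to_numpy())
    for i, key in enumerate(keys):
        if use_detected and key in variant_keys:
            out[i] = "called_variant"
        elif cat_hit[i]:
            out[i] = "catalog"
        elif use_detected and (key in ambiguous_keys or (key in discordant_keys and key not in resolved_keys)):
            out[i] = "unclear_context"
    reasons[:] = out
    return reasons


def sanitize_track(
    calls: pd.DataFrame,
    variant_calls: pd.DataFrame | None = None,
    catalog: SnpCatalog | None = None,
    policy: str = "both",
    discordance_min_diff: float = 0.2,
    discordance_p_max: float = 0.01,
) -> tuple[pd.DataFrame, SanitizationReport, pd.DataFrame]:
    """Remove genotype-leaking dyads from a methylation track.

    ``calls`` is any frame keyed by chrom/pos at the dyad's forward C
    (per-strand long calls or a pooled track); ``variant_calls`` is a
    per-sample genotype-call table (chrom, pos, genotype, filter).  Returns
    ``(sanitized, report, removal_log)`` where the removal log lists one
    reason per removed dyad.
    """
    if policy not in POLICIES:
        raise ConfigurationError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if policy in ("detected", "both") and variant_calls is None:
        raise ConfigurationError(f"policy={policy!r} requires variant calls")
    if policy in ("catalog", "both") and catalog is None:
        raise ConfigurationError(f"policy={policy!r} requires a SNP catalog")

    dyads = calls[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    reasons = _removal_reasons(
        dyads, calls, variant_calls, catalog, policy, discordance_min_diff, discordance_p_max
    )

    removed = reasons[reasons != ""]
    keys = pd.MultiIndex.from_frame(calls[["chrom", "pos"]])
    keep_mask = ~keys.isin(removed.index)
    sanitized = calls[keep_mask].copy()

    n_total = len(dyads)
    counts = removed.value_counts()
    n_called = int(counts.get("called_variant", 0))
    n_cat = int(counts.get("catalog", 0))
    n_unclear = int(counts.get("unclear_context", 0))
    n_retained = n_total - len(removed)
    report = SanitizationReport(
        n_total_sites=n_total,
        n_removed_called_variant=n_called,
        n_removed_catalog=n_cat,
        n_removed_unclear_context=n_unclear,
        n_retained=n_retained,
        retention_fraction=n_retained / n_total if n_total else float("nan"),
        policy=policy,
    )
    removal_log = removed.rename("reason").reset_index()
    removal_log.columns = ["chrom", "pos", "reason"]
    return sanitized, report, removal_log


def verify_sanitized(
    sanitized: pd.DataFrame,
    variant_calls: pd.DataFrame | None = None,
    catalog: SnpCatalog | None = None,
    policy: str = "both",
    discordance_min_diff: float = 0.2,
    discordance_p_max: float = 0.01,
) -> tuple[bool, pd.DataFrame]:
    """Release gate: fail iff any retained dyad is removable under the policy."""
    if sanitized.empty:
        return True, pd.DataFrame(columns=["chrom", "pos", "reason"])
    dyads = sanitized[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    reasons = _removal_reasons(
        dyads, sanitized, variant_calls, catalog, policy, discordance_min_diff, discordance_p_max
    )
    bad = reasons[reasons != ""].rename("reason").reset_index()
    bad.columns = ["chrom", "pos", "reason"]
    return bad.empty, bad
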