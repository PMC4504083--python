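"""Seeded end-to-end pipeline: simulate -> screen -> correlate -> callgeno
-> diffaudit -> sanitize, with a machine-readable JSON summary.

Each stage writes its outputs under the run directory and feeds the next
stage; rerunning with an identical config and seed reproduces all outputs.
Stage toggles and per-stage parameter blocks mirror the module APIs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffmeth_audit, genotype_correlation, leakage_screen, methio, sanitizer, strand_audit
from .errors import ConfigurationError
from .synthetic_cohort import CohortDesign, simulate_cohort

logger = logging.getLogger("methleak.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": {"enabled": True, "design": {}},
        "screen": {"enabled": True},
        "correlate": {"enabled": True, "window_bp": 10_000, "r_min": 0.5, "p_max": 0.05, "accuracy_min": 0.98},
        "callgeno": {"enabled": True, "prior_mode": "rare", "min_depth": 10},
        "diffaudit": {"enabled": True, "min_cov": 15, "min_diff": 0.30, "max_pairs": 40},
        "sanitize": {"enabled": True, "policy": "detected"},
    },
}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return merge_config(cfg)


def merge_config(cfg: dict) -> dict:
    """Overlay a user config on the defaults (two levels deep)."""
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in cfg.items():
        if k == "stages":
            for stage, block in v.items():
                out["stages"].setdefault(stage, {}).update(block or {})
        else:
            out[k] = v
    return out


def _stage_enabled(cfg: dict, name: str) -> bool:
    return bool(cfg["stages"].get(name, {}).get("enabled", False))


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the configured stages; returns (and writes) the summary dict.

    Partial outputs of a failed run remain on disk together with a
    ``manifest.json`` recording which stages completed.
    """
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    summary: dict = {"seed": seed, "stages": {}}
    manifest = {"completed": [], "failed": None}

    def _finish(stage: str, block: dict) -> None:
        summary["stages"][stage] = block
        manifest["completed"].append(stage)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    try:
        t0 = time.time()
        # ---- simulate -------------------------------------------------
        design = CohortDesign(**{**cfg["stages"]["simulate"].get("design", {}), "seed": seed})
        cohort = simulate_cohort(design)
        truth = cohort.truth
        reports_dir = outdir / "reports"
        reports_dir.mkdir(exist_ok=True)
        calls_by_sample = {}
        for sid in cohort.evidence:
            calls = cohort.stranded_calls(sid)
            calls_by_sample[sid] = calls
            methio.write_cytosine_report(calls, reports_dir / f"{sid}.cytosine_report.tsv")
        methio.write_sample_sheet(cohort.samples, outdir / "sample_sheet.tsv")
        methio.write_genotypes_vcf(truth.snps, truth.dosages, outdir / "genotypes.vcf")
        catalog_df = truth.snps[["chrom", "pos"]].copy()
        catalog_df["freq"] = truth.snps["maf"].to_numpy()
        catalog = methio.SnpCatalog(catalog_df)
        catalog.to_bed(outdir / "snp_catalog.bed")
        _finish(
            "simulate",
            {
                "n_samples": len(cohort.evidence),
                "n_cpgs": int(design.n_cpgs),
                "n_snps": int(design.n_snps),
                "n_disrupted_cpgs": int(truth.cpgs["disrupt_snp"].notna().sum()),
                "elapsed_s": round(time.time() - t0, 2),
            },
        )

        sample_map = dict(zip(cohort.samples["sample_id"], cohort.samples["individual_id"]))

        # ---- screen ---------------------------------------------------
        candidates = None
        if _stage_enabled(cfg, "screen"):
            sp = cfg["stages"]["screen"]
            params = leakage_screen.ScreenParams(
                min_samples_per_individual=int(sp.get("min_samples_per_individual", 3)),
                sd_threshold=float(sp.get("sd_threshold", 0.07)),
                min_range=float(sp.get("min_range", 0.15)),
                min_coverage=int(sp.get("min_coverage", 4)),
            )
            matrix = methio.build_meth_matrix(calls_by_sample, min_coverage=params.min_coverage)
            screen_res = leakage_screen.screen_static_cpgs(matrix, sample_map, params)
            out = screen_res.drop(columns=["individual_sds"]).reset_index()
            out.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
            candidates = screen_res[screen_res["is_candidate"]].index
            _finish(
                "screen",
                {
                    "n_sites": int(len(screen_res)),
                    "n_assessable": int(screen_res["assessable"].sum()),
                    "n_candidates": int(len(candidates)),
                },
            )

        # ---- correlate -----------------------------------------------
        if _stage_enabled(cfg, "correlate"):
            cp = cfg["stages"]["correlate"]
            if candidates is None:
                matrix = methio.build_meth_matrix(calls_by_sample, min_coverage=4)
                candidates = matrix.index
            # per-individual methylation: mean over that individual's samples
            matrix = methio.build_meth_matrix(calls_by_sample, min_coverage=4)
            by_ind = matrix.T.groupby(pd.Series(sample_map)).mean().T
            pos_of = truth.cpgs.set_index(["chrom", "pos"])["cpg_id"]
            results = []
            for chrom, pos in candidates:
                cpg_id = pos_of.get((chrom, pos), f"{chrom}:{pos}")
                meth = by_ind.loc[(chrom, pos)]
                res = genotype_correlation.scan_window(
                    cpg_id, int(pos), truth.snps, truth.dosages, meth.dropna(),
                    window_bp=int(cp.get("window_bp", 10_000)), chrom=chrom,
                )
                for r in res[:1]:  # best SNP per CpG
                    r.direct_overlap = catalog.overlaps_dyad(chrom, int(pos))
                results.extend(res[:1])
            classes = genotype_correlation.classify_candidates(
                results,
                r_min=float(cp.get("r_min", 0.5)),
                p_max=float(cp.get("p_max", 0.05)),
                accuracy_min=float(cp.get("accuracy_min", 0.98)),
            )
            classes.to_csv(outdir / "correlation.tsv", sep="\t", index=False)
            _finish(
                "correlate",
                {
                    "n_tested": int(len(classes)),
                    "n_correlated": int(classes["correlated"].sum()),
                    "n_highly_predictive": int(classes["highly_predictive"].sum()),
                },
            )

        # ---- callgeno -------------------------------------------------
        variant_calls_by_sample: dict[str, pd.DataFrame] = {}
        if _stage_enabled(cfg, "callgeno"):
            gp = cfg["stages"]["callgeno"]
            calls_dir = outdir / "calls"
            calls_dir.mkdir(exist_ok=True)
            kw = dict(
                prior_mode=gp.get("prior_mode", "rare"),
                theta=float(gp.get("theta", 0.001)),
                error_rate=float(gp.get("error_rate", design.sequencing_error_rate)),
                non_conversion_rate=float(gp.get("non_conversion_rate", design.non_conversion_rate)),
                cph_methylation_rate=float(gp.get("cph_methylation_rate", design.cph_methylation_rate)),
                min_depth=int(gp.get("min_depth", 10)),
            )
            if kw["prior_mode"] == "catalog":
                kw["catalog"] = catalog
            n_variant = 0
            for sid, ev in cohort.evidence.items():
                calls = strand_audit.call_genotypes_for_sample(ev, sample_id=sid, **kw)
                variant_calls_by_sample[sid] = calls
                methio.write_vcf_calls(
                    calls[(calls["genotype"] != "CC") | (calls["filter"] != "PASS")],
                    calls_dir / f"{sid}.calls.vcf",
                    sample_id=sid,
                )
                n_variant += int(((calls["genotype"] != "CC") & (calls["filter"] == "PASS")).sum())
            _finish("callgeno", {"n_samples": len(variant_calls_by_sample), "n_variant_calls_pass": n_variant})

        # ---- diffaudit ------------------------------------------------
        if _stage_enabled(cfg, "diffaudit") and variant_calls_by_sample:
            dp = cfg["stages"]["diffaudit"]
            rng = np.random.default_rng(seed)
            sids = list(calls_by_sample)
            pairs = [(a, b) for i, a in enumerate(sids) for b in sids[i + 1 :]]
            max_pairs = int(dp.get("max_pairs", 40))
            if len(pairs) > max_pairs:
                idx = rng.choice(len(pairs), size=max_pairs, replace=False)
                pairs = [pairs[i] for i in sorted(idx)]
            audit = diffmeth_audit.audit_cohort(
                calls_by_sample,
                variant_calls_by_sample,
                cohort.samples,
                pairs=pairs,
                min_cov=int(dp.get("min_cov", 15)),
                min_diff=float(dp.get("min_diff", 0.30)),
            )
            audit.to_csv(outdir / "diffmeth_audit.tsv", sep="\t", index=False)
            med = audit.groupby("pair_type")["fraction_overlap"].median().to_dict()
            _finish("diffaudit", {"n_pairs": int(len(audit)), "median_fraction_overlap": med})

        # ---- sanitize -------------------------------------------------
        if _stage_enabled(cfg, "sanitize") and variant_calls_by_sample:
            zp = cfg["stages"]["sanitize"]
            policy = zp.get("policy", "detected")
            clean_dir = outdir / "sanitized"
            clean_dir.mkdir(exist_ok=True)
            retentions, reports = [], {}
            for sid, calls in calls_by_sample.items():
                clean, report, _log = sanitizer.sanitize_track(
                    calls,
                    variant_calls=variant_calls_by_sample.get(sid),
                    catalog=catalog if policy in ("catalog", "both") else None,
                    policy=policy,
                )
                track = methio.pooled_rates(clean).reset_index()
                methio.write_bedgraph(
                    track[track["coverage"] > 0], clean_dir / f"{sid}.bedGraph", overwrite=True
                )
                reports[sid] = report.to_dict()
                retentions.append(report.retention_fraction)
            with open(outdir / "sanitization_reports.json", "w") as fh:
                json.dump(reports, fh, indent=2)
            _finish(
                "sanitize",
                {
                    "policy": policy,
                    "n_samples": len(reports),
                    "median_retention": float(np.median(retentions)),
                },
            )

        summary["elapsed_s"] = round(time.time() - t0, 2)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        return summary
    except Exception as exc:
        manifest["failed"] = repr(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
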