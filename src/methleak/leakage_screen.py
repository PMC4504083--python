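"""Screen for CpGs whose methylation is static within individuals but
variable between them — the signature of genotype leaking into a
methylation track rather than of tissue-driven epigenetic variation.

The screen takes a dyad x sample matrix of pooled-strand methylation rates
and a sample -> individual map.  A dyad is a candidate when

* strictly more than half of the assessable individuals (those with at least
  ``min_samples_per_individual`` measured samples at the dyad) have a
  within-individual standard deviation below ``sd_threshold``, and
* the range of methylation across all measured samples is at least
  ``min_range``.

Defaults (SD < 0.07, range >= 0.15, >= 3 samples per individual, >= 4 reads
pooled across strands) reproduce the multi-tissue reference-epigenome
screen.  The SD is the population SD (divisor n).  A permutation null
(shuffling the sample -> individual assignment) calibrates the expected
candidate yield in the absence of individual-specific signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["ScreenParams", "screen_static_cpgs", "permutation_null_yield", "calibrate_thresholds"]


@dataclass(frozen=True)
class ScreenParams:
    min_samples_per_individual: int = 3
    sd_threshold: float = 0.07
    min_range: float = 0.15
    min_coverage: int = 4

    def validate(self) -> None:
        if self.min_samples_per_individual < 1:
            raise ConfigurationError("min_samples_per_individual must be >= 1")
        if not 0.0 < self.sd_threshold < 1.0:
            raise ConfigurationError("sd_threshold must lie in (0, 1)")
        if not 0.0 < self.min_range < 1.0:
            raise ConfigurationError("min_range must lie in (0, 1)")
        if self.min_coverage < 1:
            raise ConfigurationError("min_coverage must be >= 1")


def _individual_columns(meth_matrix: pd.DataFrame, sample_map: Mapping[str, str]) -> dict[str, list[str]]:
    by_ind: dict[str, list[str]] = {}
    for s in meth_matrix.columns:
        ind = sample_map.get(s)
        if ind is None:
            raise ConfigurationError(f"sample {s!r} missing from the sample -> individual map")
        by_ind.setdefault(ind, []).append(s)
    return by_ind


def screen_static_cpgs(
    meth_matrix: pd.DataFrame,
    sample_map: Mapping[str, str],
    params: ScreenParams = ScreenParams(),
) -> pd.DataFrame:
    """Run the static-within / variable-between screen.

    ``meth_matrix`` holds pooled-strand rates in [0, 1] with NaN for samples
    below coverage (see :func:`methleak.methio.build_meth_matrix`, which
    applies ``params.min_coverage``).

    Returns a frame indexed like ``meth_matrix`` with per-site statistics
    (``n_assessable``, ``n_static``, ``range``, per-individual SDs as a
    dict), an ``assessable`` flag and the ``is_candidate`` verdict.  Sites
    with no assessable individual are flagged unassessable and can never be
    candidates.
    """
    params.validate()
    by_ind = _individual_columns(meth_matrix, sample_map)
    vals = meth_matrix.to_numpy(dtype=float)
    n_sites = vals.shape[0]

    n_assessable = np.zeros(n_sites, dtype=int)
    n_static = np.zeros(n_sites, dtype=int)
    sd_records: list[dict[str, float]] = [dict() for _ in range(n_sites)]
    for ind, cols in by_ind.items():
        idx = [meth_matrix.columns.get_loc(c) for c in cols]
        sub = vals[:, idx]
        n_meas = np.sum(~np.isnan(sub), axis=1)
        ok = n_meas >= params.min_samples_per_individual
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(sub, axis=1, ddof=0)
        n_assessable += ok
        n_static += ok & (sd < params.sd_threshold)
        for i in np.nonzero(ok)[0]:
            sd_records[i][ind] = float(sd[i])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rng_all = np.nanmax(vals, axis=1) - np.nanmin(vals, axis=1)
    rng_all = np.where(np.all(np.isnan(vals), axis=1), np.nan, rng_all)

    assessable = n_assessable > 0
    majority = n_static > n_assessable / 2.0
    is_candidate = assessable & majority & (rng_all >= params.min_range)
    return pd.DataFrame(
        {
            "n_assessable": n_assessable,
            "n_static": n_static,
            "range": rng_all,
            "individual_sds": sd_records,
            "assessable": assessable,
            "is_candidate": is_candidate,
        },
        index=meth_matrix.index,
    )


def permutation_null_yield(
    meth_matrix: pd.DataFrame,
    sample_map: Mapping[str, str],
    params: ScreenParams = ScreenParams(),
    n_perm: int = 20,
    seed: int | None = None,
) -> dict:
    """Expected candidate yield when the sample -> individual assignment is
    random — the screen's false-positive calibration.

    Individual labels are permuted across samples (group sizes preserved).
    Returns mean yield, a normal-approximation 95 % CI and the per-
    permutation counts.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    samples = list(meth_matrix.columns)
    labels = [sample_map[s] for s in samples]
    if len(set(labels)) > len(samples):
        raise ConfigurationError("more individuals than samples; cannot permute assignments")
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_perm):
        perm = rng.permutation(len(samples))
        permuted = {samples[i]: labels[perm[i]] for i in range(len(samples))}
        res = screen_static_cpgs(meth_matrix, permuted, params)
        counts.append(int(res["is_candidate"].sum()))
    counts = np.asarray(counts)
    mean = float(counts.mean())
    half = 1.96 * counts.std(ddof=0) / np.sqrt(n_perm)
    return {"mean_yield": mean, "ci95": (mean - half, mean + half), "yields": counts.tolist()}


def calibrate_thresholds(
    meth_matrix: pd.DataFrame,
    sample_map: Mapping[str, str],
    sd_percentile: float = 70.0,
    range_percentile: float = 65.0,
    params: ScreenParams = ScreenParams(),
) -> ScreenParams:
    """Derive thresholds from empirical percentiles of a reference matrix.

    ``sd_threshold`` becomes the ``sd_percentile`` of all per-individual SDs
    (the "bottom 70 %" convention) and ``min_range`` the ``range_percentile``
    of per-site ranges (the "top 35 %").
    """
    stats = screen_static_cpgs(meth_matrix, sample_map, params)
    all_sds = [v for d in stats["individual_sds"] for v in d.values()]
    if not all_sds:
        raise ConfigurationError("no assessable individual SDs to calibrate from")
    sd_thr = float(np.percentile(all_sds, sd_percentile))
    rng_thr = float(np.nanpercentile(stats["range"].to_numpy(dtype=float), range_percentile))
    return replace(params, sd_threshold=sd_thr, min_range=rng_thr)
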