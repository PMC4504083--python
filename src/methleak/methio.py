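"""Readers and writers for the formats the pipeline touches.

Dialects
--------
* Bismark-style cytosine report: TSV of ``chrom, pos (1-based), strand
  (+/-), meth_count, unmeth_count, context, trinucleotide``.
* per-strand / pooled bedGraph: 0-based half-open, one dyad per line, value
  is the methylation percentage (0-100) as in public track hubs.
* VCF v4.2 (via pysam) for genotypes and genotype calls.
* BED3(+frequency) SNP catalog, 0-based half-open point intervals.
* sample sheet TSV: ``sample_id, individual_id, tissue, relationship_group``.

Coordinates are 0-based half-open everywhere inside the package; conversion
happens only at file boundaries.  Reverse-strand cytosine-report records are
re-keyed at ingest to their dyad's forward-C position, so every module
addresses a CpG dyad ``[pos, pos+2)`` by the single coordinate ``pos``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import ParseError

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "meth_count", "unmeth_count"]


# ---------------------------------------------------------------------------
# cytosine report


def write_cytosine_report(calls: pd.DataFrame, path: str | Path, sample_id: str | None = None) -> None:
    """Write long-format per-strand calls as a Bismark-style cytosine report.

    Forward records go out at 1-based ``pos + 1``, reverse records at the
    reverse C's own coordinate ``pos + 2``.
    """
    df = calls.copy()
    pos1 = np.where(df["strand"] == "+", df["pos"] + 1, df["pos"] + 2)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": pos1,
            "strand": df["strand"],
            "meth_count": df["meth_count"].astype(int),
            "unmeth_count": df["unmeth_count"].astype(int),
            "context": "CpG",
            "trinucleotide": "CGN",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cytosine_report(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into long per-strand calls.

    Positions are converted to 0-based and reverse-strand records are
    re-keyed to their dyad's forward-C position (1-based reverse coordinate
    minus 2).  Malformed lines raise :class:`ParseError` with line numbers.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}: line {lineno}: expected >=5 tab-separated columns, got {len(parts)}")
            chrom, pos_s, strand, meth_s, unmeth_s = parts[:5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: unknown strand symbol {strand!r}")
            try:
                pos1, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field ({exc})") from None
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}: line {lineno}: negative read count")
            if pos1 < 1:
                raise ParseError(f"{path}: line {lineno}: 1-based position must be >= 1")
            pos0 = pos1 - 1 if strand == "+" else pos1 - 2
            rows.append((chrom, pos0, strand, meth, unmeth))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if sample_id is not None:
        df["sample_id"] = sample_id
    return df


# ---------------------------------------------------------------------------
# pooled-strand rates and matrices


def pooled_rates(calls: pd.DataFrame, min_coverage: int = 1) -> pd.DataFrame:
    """Pool both strands of each dyad into one methylation rate.

    Returns a frame indexed by (chrom, pos) with ``meth``, ``coverage`` and
    ``rate``; dyads below ``min_coverage`` total reads get rate NaN.
    """
    g = calls.groupby(["chrom", "pos"], sort=True)[["meth_count", "unmeth_count"]].sum()
    cov = g["meth_count"] + g["unmeth_count"]
    rate = np.where(cov >= max(min_coverage, 1), g["meth_count"] / cov.replace(0, np.nan), np.nan)
    return pd.DataFrame({"meth": g["meth_count"], "coverage": cov, "rate": rate}, index=g.index)


def build_meth_matrix(calls_by_sample: dict[str, pd.DataFrame], min_coverage: int = 4) -> pd.DataFrame:
    """Assemble a dyad x sample matrix of pooled-strand rates.

    Samples whose pooled coverage at a dyad is below ``min_coverage`` are
    missing (NaN) at that dyad.
    """
    cols = {sid: pooled_rates(calls, min_coverage)["rate"] for sid, calls in calls_by_sample.items()}
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: pd.DataFrame, path: str | Path, overwrite: bool = False) -> None:
    """Write a pooled dyad track as bedGraph (percent methylation per dyad).

    ``track`` needs columns chrom, pos and rate (proportion).  Records are
    sorted before writing; an existing path is refused unless ``overwrite``.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    df = track.sort_values(["chrom", "pos"], kind="mergesort")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"].astype(int),
            "end": df["pos"].astype(int) + 2,
            "value": (df["rate"] * 100.0).round(6),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a dyad bedGraph back into chrom/pos/rate (proportion)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    if df.empty:
        return pd.DataFrame(columns=["chrom", "pos", "rate"])
    return pd.DataFrame({"chrom": df["chrom"], "pos": df["start"], "rate": df["value"] / 100.0})


# ---------------------------------------------------------------------------
# VCF genotypes


@dataclass
class GenotypeTable:
    """Biallelic SNVs with per-individual alt-allele dosages."""

    sites: pd.DataFrame  # snp_id, chrom, pos (0-based), ref, alt
    dosages: pd.DataFrame  # snp_id x individual, values {0,1,2} or -1 missing
    n_skipped: dict = field(default_factory=dict)


def read_genotypes_vcf(path: str | Path) -> GenotypeTable:
    """Read diploid genotypes from a VCF v4.2.

    Only biallelic SNVs are kept; multi-allelic records, indels and records
    without GT are skipped and counted in ``n_skipped``.  Dosage is the count
    of alt alleles; missing genotypes are coded -1.
    """
    skipped = {"multiallelic": 0, "indel": 0, "no_gt": 0}
    sites, rows = [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for i, rec in enumerate(vf):
            if rec.alts is None or len(rec.alts) != 1:
                skipped["multiallelic"] += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                skipped["indel"] += 1
                continue
            dosage = []
            ok = True
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    ok = False
                    break
                dosage.append(sum(gt))
            if not ok:
                skipped["no_gt"] += 1
                continue
            sites.append((rec.id or f"snp{i:06d}", rec.chrom, rec.start, ref, alt))
            rows.append(dosage)
    sites = pd.DataFrame(sites, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosages = pd.DataFrame(rows, columns=samples, index=sites["snp_id"] if len(sites) else None)
    if any(skipped.values()):
        logger.info("read_genotypes_vcf(%s): skipped %s", path, skipped)
    return GenotypeTable(sites=sites, dosages=dosages, n_skipped=skipped)


def write_genotypes_vcf(sites: pd.DataFrame, dosages: pd.DataFrame, path: str | Path) -> None:
    """Write biallelic genotypes (dosage-coded) as an uncompressed VCF v4.2."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in pd.unique(sites["chrom"]):
        header.add_line(f"##contig=<ID={chrom}>")
    for s in dosages.columns:
        header.add_sample(str(s))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, row in sites.sort_values(["chrom", "pos"], kind="mergesort").iterrows():
            rec = out.new_record(
                contig=row["chrom"], start=int(row["pos"]), stop=int(row["pos"]) + 1,
                alleles=(row["ref"], row["alt"]), id=row["snp_id"],
            )
            for s in dosages.columns:
                d = int(dosages.at[row["snp_id"], s])
                rec.samples[str(s)]["GT"] = (0, 0) if d == 0 else ((0, 1) if d == 1 else (1, 1))
                rec.samples[str(s)].phased = False
            out.write(rec)


def write_vcf_calls(calls: pd.DataFrame, path: str | Path, sample_id: str = "sample") -> None:
    """Write per-site genotype calls (one sample) as VCF with FILTER status.

    ``calls`` needs columns chrom, pos, genotype (two-base string, reference
    base C), posterior and filter ({PASS, LOW_COV, AMBIGUOUS}).
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FILTER=<ID=LOW_COV,Description="Total depth below threshold">')
    header.add_line('##FILTER=<ID=AMBIGUOUS,Description="No genotype reaches the posterior threshold">')
    header.add_line('##INFO=<ID=PP,Number=1,Type=Float,Description="Posterior probability of the call">')
    for chrom in pd.unique(calls["chrom"]):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, row in calls.sort_values(["chrom", "pos"], kind="mergesort").iterrows():
            gt = str(row["genotype"])
            alts = sorted(set(a for a in gt if a != "C"))
            alleles = ("C",) + (tuple(alts) if alts else ("<NON_REF>",))
            rec = out.new_record(
                contig=row["chrom"], start=int(row["pos"]), stop=int(row["pos"]) + 1, alleles=alleles
            )
            idx = {a: i for i, a in enumerate(alleles)}
            code = tuple(sorted(idx.get(a, 0) for a in gt))
            rec.samples[sample_id]["GT"] = code
            rec.samples[sample_id].phased = False
            rec.info["PP"] = float(row["posterior"])
            rec.filter.add(str(row["filter"]))
            out.write(rec)


def read_vcf_calls(path: str | Path) -> pd.DataFrame:
    """Read single-sample genotype calls written by :func:`write_vcf_calls`."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            gt_idx = rec.samples[sample]["GT"]
            alleles = rec.alleles
            gt = "".join(sorted("C" if alleles[i] == "<NON_REF>" else alleles[i] for i in gt_idx))
            rows.append(
                (rec.chrom, rec.start, gt, float(rec.info.get("PP", 0.0)), ";".join(rec.filter.keys()) or "PASS")
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "genotype", "posterior", "filter"])


# ---------------------------------------------------------------------------
# SNP catalog


class SnpCatalog:
    """A point catalog of known SNP positions, queryable by point and dyad.

    Backed by per-chromosome sorted position arrays; duplicate records are
    collapsed with a warning.  Allele frequency is optional per site and
    defaults to unknown (NaN).
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None or df.empty:
            df = pd.DataFrame(columns=["chrom", "pos", "freq"])
        df = df.copy()
        if "freq" not in df.columns:
            df["freq"] = np.nan
        n_dup = df.duplicated(subset=["chrom", "pos"]).sum()
        if n_dup:
            warnings.warn(f"SNP catalog: collapsed {n_dup} duplicate record(s)", stacklevel=2)
            df = df.drop_duplicates(subset=["chrom", "pos"], keep="first")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self._df = df
        self._pos = {c: g["pos"].to_numpy(dtype=np.int64) for c, g in df.groupby("chrom", sort=False)}
        self._freq = {c: g["freq"].to_numpy(dtype=float) for c, g in df.groupby("chrom", sort=False)}

    def __len__(self) -> int:
        return len(self._df)

    def contains(self, chrom: str, pos: int) -> bool:
        p = self._pos.get(chrom)
        if p is None:
            return False
        i = np.searchsorted(p, pos)
        return bool(i < len(p) and p[i] == pos)

    def overlaps_dyad(self, chrom: str, pos: int) -> bool:
        """True iff any catalog SNP falls in the dyad [pos, pos+2)."""
        return self.count_in_interval(chrom, pos, pos + 2) > 0

    def count_in_interval(self, chrom: str, start: int, end: int) -> int:
        p = self._pos.get(chrom)
        if p is None:
            return 0
        return int(np.searchsorted(p, end) - np.searchsorted(p, start))

    def overlaps_dyads(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`overlaps_dyad` over an array of dyad starts."""
        p = self._pos.get(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        if p is None:
            return np.zeros(len(positions), dtype=bool)
        return np.searchsorted(p, positions + 2) > np.searchsorted(p, positions)

    def frequency(self, chrom: str, pos: int) -> float:
        """Allele frequency at an exact position; NaN when unknown/absent."""
        p = self._pos.get(chrom)
        if p is None:
            return float("nan")
        i = np.searchsorted(p, pos)
        if i < len(p) and p[i] == pos:
            return float(self._freq[chrom][i])
        return float("nan")

    @classmethod
    def from_bed(cls, path: str | Path) -> "SnpCatalog":
        """BED3 with an optional 4th column carrying allele frequency."""
        try:
            raw = pd.read_csv(path, sep="\t", header=None, comment="#")
        except pd.errors.EmptyDataError:
            return cls()
        if raw.shape[1] < 3:
            raise ParseError(f"{path}: BED needs >=3 columns")
        df = pd.DataFrame({"chrom": raw[0], "pos": raw[1].astype(int)})
        if raw.shape[1] >= 4:
            df["freq"] = pd.to_numeric(raw[3], errors="coerce")
        return cls(df)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "SnpCatalog":
        rows = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                freq = rec.info.get("AF", (np.nan,))
                freq = freq[0] if isinstance(freq, tuple) else freq
                rows.append((rec.chrom, rec.start, float(freq) if freq is not None else np.nan))
        return cls(pd.DataFrame(rows, columns=["chrom", "pos", "freq"]))

    def to_bed(self, path: str | Path) -> None:
        df = self._df
        out = pd.DataFrame(
            {"chrom": df["chrom"], "start": df["pos"], "end": df["pos"] + 1, "freq": df["freq"].fillna(-1)}
        )
        out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# sample sheet

SAMPLE_SHEET_COLUMNS = ["sample_id", "individual_id", "tissue", "relationship_group"]


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet is missing columns {missing}")
    return df
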