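"""Input/output for SNP tables, genome bins, depth tracks and CNA calls.

All BED-style tables (bins, calls, truth intervals) use 0-based half-open
coordinates; SNP positions are 1-based, matching VCF convention.

The central in-memory containers are plain :class:`pandas.DataFrame` objects
with documented column sets:

``snps``
    chrom, pos, ref, alt, gt, depth_a, depth_b, bulk_vaf
``bins``
    chrom, start, end, gc, mappable_bp
``profile`` (per cell)
    bin columns plus observed, expected, rdr, count_a, count_b, pbaf
``calls``
    chrom, start, end, cell_id, cn_a, cn_b, total_cn, rdr, baf, loh_flag
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "chrom", "start", "end", "cell_id",
    "cn_a", "cn_b", "total_cn", "rdr", "baf", "loh_flag",
]

SNP_COLUMNS = ["chrom", "pos", "ref", "alt", "gt", "depth_a", "depth_b", "bulk_vaf"]


class ParseError(ValueError):
    """A malformed row in an input table."""


@dataclass(frozen=True)
class SNPRecord:
    """One phased germline heterozygous SNP with allele-specific depths.

    ``depth_a``/``depth_b`` count reads supporting the haplotype-A and
    haplotype-B allele in a single cell; ``bulk_vaf`` is the variant allele
    fraction observed in matched bulk sequencing.
    """

    chrom: str
    pos: int
    hap_allele_a: str
    hap_allele_b: str
    depth_a: int
    depth_b: int
    bulk_vaf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        if self.depth_a < 0 or self.depth_b < 0:
            raise ValueError("allele depths must be non-negative")
        if not 0.0 <= self.bulk_vaf <= 1.0:
            raise ValueError("bulk VAF must lie in [0, 1]")


def _is_het(gt: str) -> bool:
    alleles = gt.replace("|", "/").split("/")
    return len(alleles) == 2 and alleles[0] != alleles[1]


def _is_phased(gt: str) -> bool:
    return "|" in gt


def load_ghets(
    path: str | Path,
    vaf_bounds: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Load a germline-heterozygous SNP table, applying standard filters.

    Retained records are heterozygous, pass-filtered, phased, biallelic and
    have ``vaf_bounds[0] < bulk_vaf < vaf_bounds[1]`` (bounds exclusive).
    Unphased or multi-allelic records are dropped and counted in the log.

    Parameters
    ----------
    path
        TSV with columns chrom, pos, ref, alt, gt, depth_a, depth_b,
        bulk_vaf and optionally filter (defaults to PASS when absent).
    vaf_bounds
        Exclusive lower/upper bulk-VAF bounds.
    """
    lo, hi = vaf_bounds
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gt": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse SNP table {path}: {exc}") from exc
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"SNP table {path} missing columns {missing}")
    for col in ("pos", "depth_a", "depth_b"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(f"malformed value in column {col!r} at line {line}")

    if "filter" not in df.columns:
        df = df.assign(filter="PASS")
    gt = df["gt"].astype(str)
    het = gt.map(_is_het)
    phased = gt.map(_is_phased)
    biallelic = ~df["alt"].astype(str).str.contains(",")
    passing = df["filter"].astype(str) == "PASS"
    in_vaf = (df["bulk_vaf"] > lo) & (df["bulk_vaf"] < hi)

    n_unphased = int((het & ~phased).sum())
    if n_unphased:
        logger.info("dropped %d unphased heterozygous records", n_unphased)
    n_multi = int((~biallelic).sum())
    if n_multi:
        logger.info("dropped %d multi-allelic records", n_multi)

    keep = het & phased & biallelic & passing & in_vaf
    out = df.loc[keep, SNP_COLUMNS].reset_index(drop=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def load_ghets_vcf(
    path: str | Path,
    sample: str,
    vaf_bounds: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Load phased heterozygous SNPs from a VCF (standard GT/AD fields only).

    The first ALT allele's depth becomes the haplotype-B depth when the
    phased genotype is 0|1 and the haplotype-A depth when it is 1|0.
    Bulk VAF is taken from the site-level AF INFO field when present, else
    from the sample's allele depths.
    """
    from cyvcf2 import VCF  # deferred: optional input path

    lo, hi = vaf_bounds
    vcf = VCF(str(path))
    if sample not in vcf.samples:
        raise ParseError(f"sample {sample!r} not in VCF {path}")
    si = vcf.samples.index(sample)
    rows = []
    for var in vcf:
        if var.FILTER is not None:  # None == PASS in cyvcf2
            continue
        if len(var.ALT) != 1:
            continue
        gt = var.genotypes[si]
        if len(gt) != 3 or not gt[2]:  # unphased
            continue
        if {gt[0], gt[1]} != {0, 1}:  # not heterozygous
            continue
        ad = var.format("AD")[si]
        ref_depth, alt_depth = int(ad[0]), int(ad[1])
        if gt[0] == 0:  # 0|1: haplotype A carries REF
            depth_a, depth_b = ref_depth, alt_depth
        else:  # 1|0
            depth_a, depth_b = alt_depth, ref_depth
        af = var.INFO.get("AF")
        if af is None:
            total = ref_depth + alt_depth
            af = alt_depth / total if total else 0.0
        if not lo < float(af) < hi:
            continue
        rows.append(
            {
                "chrom": var.CHROM, "pos": var.POS, "ref": var.REF, "alt": var.ALT[0],
                "gt": "0|1" if gt[0] == 0 else "1|0",
                "depth_a": depth_a, "depth_b": depth_b, "bulk_vaf": float(af),
            }
        )
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def make_fixed_bins(
    chrom: str, length: int, bin_size: int, gc: np.ndarray | None = None
) -> pd.DataFrame:
    """Fixed-span bins covering ``[0, length)``; trailing partial bin dropped."""
    starts = np.arange(0, length - bin_size + 1, bin_size, dtype=np.int64)
    ends = starts + bin_size
    if gc is None:
        gc = np.full(len(starts), np.nan)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "gc": np.asarray(gc, dtype=float),
            "mappable_bp": ends - starts,
        }
    )


def make_mappable_bins(
    chrom: str,
    mappable_positions: np.ndarray,
    bin_size: int,
) -> pd.DataFrame:
    """Variable-span bins each containing ``bin_size`` uniquely mappable bases.

    ``mappable_positions`` is a sorted array of mappable genomic coordinates;
    consecutive runs of ``bin_size`` positions define one bin, so genomic
    spans vary while information content per bin is constant.
    """
    pos = np.asarray(mappable_positions)
    n_full = len(pos) // bin_size
    if n_full == 0:
        raise ValueError("fewer mappable positions than one bin")
    starts = pos[: n_full * bin_size : bin_size]
    ends = pos[bin_size - 1 : n_full * bin_size : bin_size] + 1
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "gc": np.nan,
            "mappable_bp": bin_size,
        }
    )


def aggregate_bin_counts(snps: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Aggregate haplotype-specific SNP depths into per-bin counts and pBAF.

    ``count_a`` (``count_b``) is the sum of ``depth_a`` (``depth_b``) over
    gHETs falling in the bin; pBAF = count_b / (count_a + count_b), left
    missing for bins with no informative gHET. SNPs outside every bin are
    ignored (count logged).
    """
    out = bins[["chrom", "start", "end"]].copy()
    count_a = np.zeros(len(bins), dtype=np.int64)
    count_b = np.zeros(len(bins), dtype=np.int64)
    n_outside = 0
    for chrom, sub in snps.groupby("chrom", sort=False):
        mask = bins["chrom"].to_numpy() == chrom
        if not mask.any():
            n_outside += len(sub)
            continue
        b = bins.loc[mask]
        # SNP pos is 1-based; bin [start, end) is 0-based half-open.
        pos0 = sub["pos"].to_numpy() - 1
        idx = np.searchsorted(b["start"].to_numpy(), pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < b["end"].to_numpy()[np.clip(idx, 0, len(b) - 1)])
        n_outside += int((~inside).sum())
        rows = b.index.to_numpy()[idx[inside]]
        np.add.at(count_a, rows, sub["depth_a"].to_numpy()[inside])
        np.add.at(count_b, rows, sub["depth_b"].to_numpy()[inside])
    if n_outside:
        logger.info("%d SNPs fell outside every bin", n_outside)
    total = count_a + count_b
    with np.errstate(invalid="ignore"):
        pbaf = np.where(total > 0, count_b / np.maximum(total, 1), np.nan)
    out["count_a"] = count_a
    out["count_b"] = count_b
    out["pbaf"] = pbaf
    return out


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Write allelic copy-number calls as BED-style TSV.

    Calls must arrive sorted by (cell_id, chrom, start); the file round-trips
    losslessly through :func:`read_calls`.
    """
    calls = calls.reset_index(drop=True)
    key = calls[["cell_id", "chrom", "start"]]
    if not key.equals(key.sort_values(["cell_id", "chrom", "start"], kind="mergesort").reset_index(drop=True)):
        raise ValueError("calls must be sorted by (cell_id, chrom, start)")
    out = calls[CALL_COLUMNS].copy()
    out["loh_flag"] = out["loh_flag"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a call table written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "cell_id": str})
    df["loh_flag"] = df["loh_flag"].astype(bool)
    for col in ("start", "end", "cn_a", "cn_b", "total_cn"):
        df[col] = df[col].astype(np.int64)
    return df[CALL_COLUMNS]


def write_bed(intervals: pd.DataFrame, path: str | Path, extra: Sequence[str] = ()) -> None:
    """Write chrom/start/end (+extra columns) as headered BED-style TSV."""
    cols = ["chrom", "start", "end", *extra]
    intervals[cols].to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_bedgraph(path: str | Path, value_name: str = "value") -> pd.DataFrame:
    """Read a headerless 4-column bedGraph track (chrom, start, end, value)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", value_name], dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df
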