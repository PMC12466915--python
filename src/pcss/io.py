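"""Readers and writers for pooled count tables, bin manifests, annotation
tables, interval tracks and result tables.

Conventions: the canonical counts input is a long-form TSV with one row per
variant x sample; a VCF with per-sample allele depths (AD) is accepted as a
convenience dialect and mapped to the same frame.  All positions are held
1-based internally; BED input (0-based, half-open) is converted on read so
that an interval [s, e) covers 1-based positions s+1..e.  Only biallelic
SNVs are retained — multi-allelic or indel records are rejected at read
time with a logged report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalTrack",
    "read_pooled_counts",
    "read_bin_manifest",
    "read_sites",
    "read_tracks",
    "read_track_map",
    "write_results",
    "read_results",
]

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "ref_reads", "alt_reads"]
_NUCLEOTIDES = {"A", "C", "G", "T"}
ANNOTATION_CLASSES = [
    "missense",
    "nonsense",
    "synonymous",
    "utr5",
    "utr3",
    "intron",
    "intergenic",
    "uorf_gain",
    "uorf_loss",
]


@dataclass
class IntervalTrack:
    """One factor/term track; intervals are 1-based inclusive, sorted."""

    factor: str
    term: str
    intervals: pd.DataFrame  # columns: chrom, start, end


def _is_snv(ref: str, alt: str) -> bool:
    return (
        len(ref) == 1
        and len(alt) == 1
        and ref in _NUCLEOTIDES
        and alt in _NUCLEOTIDES
        and ref != alt
    )


def read_pooled_counts(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read per-variant, per-sample allele counts.

    ``dialect="tsv"`` expects the header chrom, pos, ref, alt, sample,
    ref_reads, alt_reads; ``dialect="vcf_ad"`` reads a VCF 4.x with an AD
    (ref,alt depth) field per sample.  Rows that are not biallelic SNVs
    are dropped and reported; the number dropped is stored in
    ``df.attrs["n_rejected"]``.
    """
    if dialect == "tsv":
        return _read_counts_tsv(path)
    if dialect == "vcf_ad":
        return _read_counts_vcf(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("pos", "ref_reads", "alt_reads"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header, one for 0-based index
            raise ValueError(f"{path}: malformed {col!r} at line {bad[0] + 2}")
    neg = df.index[(df["ref_reads"] < 0) | (df["alt_reads"] < 0)]
    if len(neg):
        raise ValueError(f"{path}: negative read count at line {neg[0] + 2}")
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    ok = df.apply(lambda r: _is_snv(str(r["ref"]), str(r["alt"])), axis=1)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning(
            "%s: rejected %d non-biallelic-SNV row(s)", path, n_rejected
        )
    out = df.loc[ok, COUNT_COLUMNS].reset_index(drop=True)
    out.attrs["n_rejected"] = n_rejected
    return out


def _read_counts_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    records = []
    n_rejected = 0
    for v in vcf:
        if len(v.ALT) != 1 or not _is_snv(v.REF, v.ALT[0]):
            n_rejected += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record at {v.CHROM}:{v.POS} lacks AD")
        for i, sample in enumerate(samples):
            ref_reads, alt_reads = int(ad[i][0]), int(ad[i][1])
            if ref_reads < 0 or alt_reads < 0:  # cyvcf2 encodes missing as -1
                continue
            records.append(
                {
                    "chrom": v.CHROM,
                    "pos": v.POS,
                    "ref": v.REF,
                    "alt": v.ALT[0],
                    "sample": sample,
                    "ref_reads": ref_reads,
                    "alt_reads": alt_reads,
                }
            )
    if n_rejected:
        logger.warning("%s: rejected %d non-biallelic-SNV record(s)", path, n_rejected)
    out = pd.DataFrame(records, columns=COUNT_COLUMNS)
    out.attrs["n_rejected"] = n_rejected
    return out


def read_bin_manifest(path) -> pd.DataFrame:
    """Read the phenotypic-bin manifest and enforce its invariants.

    Columns: replicate, bin_index, mean_survival_h, n_individuals.  Within
    a replicate bin indices must be unique and mean survival times
    strictly increasing with bin index.  Adds a ``sample`` column
    (replicate label + bin index) naming the pooled sample.
    """
    df = pd.read_csv(path, sep="\t", dtype={"replicate": str})
    required = ["replicate", "bin_index", "mean_survival_h", "n_individuals"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if (df["mean_survival_h"] <= 0).any() or (df["n_individuals"] <= 0).any():
        raise ValueError(f"{path}: mean_survival_h and n_individuals must be positive")
    for rep, sub in df.groupby("replicate"):
        if sub["bin_index"].duplicated().any():
            raise ValueError(f"{path}: duplicate bin_index in replicate {rep}")
        ordered = sub.sort_values("bin_index")
        if not ordered["mean_survival_h"].is_monotonic_increasing or (
            ordered["mean_survival_h"].diff().dropna() <= 0
        ).any():
            raise ValueError(
                f"{path}: mean_survival_h not strictly increasing in replicate {rep}"
            )
        if len(sub) < 2:
            logger.warning(
                "%s: replicate %s has a single bin; association is undefined",
                path,
                rep,
            )
    df["sample"] = df["replicate"].astype(str) + df["bin_index"].astype(str)
    return df


def read_sites(path) -> pd.DataFrame:
    """Read a variant annotation table (chrom, pos, ref, alt, qual,
    annotation_class, gene_id, near_indel).

    ``annotation_class`` may hold several comma-separated labels; priority
    resolution happens downstream.  ``gene_id`` and ``near_indel`` are
    optional (defaults: missing / False).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "qual" not in df.columns:
        df["qual"] = np.nan
    if "gene_id" not in df.columns:
        df["gene_id"] = pd.NA
    if "near_indel" not in df.columns:
        df["near_indel"] = False
    df["near_indel"] = df["near_indel"].astype(bool)
    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"])
    if dup.any():
        raise ValueError(f"{path}: duplicate variant key at line {dup.idxmax() + 2}")
    return df


def read_track_map(path) -> list[tuple[str, str, str]]:
    """Read a factor/term/path map (TSV with those three columns)."""
    df = pd.read_csv(path, sep="\t")
    required = ["factor", "term", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return list(df[required].itertuples(index=False, name=None))


def read_tracks(entries) -> list[IntervalTrack]:
    """Read BED files into 1-based inclusive interval tracks.

    ``entries`` is an iterable of (factor, term, bed_path).  BED is 0-based
    half-open, so a line ``2L 100 200`` becomes the 1-based inclusive
    interval 101..200.  Intervals are sorted per chromosome.
    """
    tracks = []
    for factor, term, path in entries:
        bed = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
            comment="#",
        )
        bad = bed[bed["start"] >= bed["end"]]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(
                f"{path}: start >= end at {r['chrom']}:{r['start']}-{r['end']}"
            )
        bed = bed.sort_values(["chrom", "start"], ignore_index=True)
        bed["start"] = bed["start"] + 1  # to 1-based inclusive
        tracks.append(IntervalTrack(factor=str(factor), term=str(term), intervals=bed))
    return tracks


def write_results(records: pd.DataFrame, path) -> None:
    """Write a result table as TSV with a deterministic column order.

    Floats are serialised with enough digits that p/q values round-trip to
    within 1e-12 relative; an empty frame yields a header-only file.
    """
    records.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def read_results(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
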