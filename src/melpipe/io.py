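"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is tab-separated text: SNP site tables, truth segments (BED plus
a copy-number column), variant tables, count matrices, cohort tables, GMT
gene sets, and gene-interval BED. Internal coordinates are 1-based
inclusive; BED files are converted from 0-based half-open at this boundary
and back on write. Uncompressed single-sample VCFs are read via pysam.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CnSegmentTruth

_BOOL_COLS = {"in_population_db", "in_blacklist_db", "in_db", "pfs_event", "os_event", "kept"}


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if col in _BOOL_COLS:
            df[col] = df[col].astype(bool)
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


read_sites_tsv = _read_tsv
read_variants_tsv = _read_tsv
read_cohort_tsv = _read_tsv


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_segments_bed(segments: list[CnSegmentTruth], path: str | Path) -> None:
    """Truth segments as BED (0-based half-open) with a copy_number column."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.copy_number}\n")


def read_segments_bed(path: str | Path) -> list[CnSegmentTruth]:
    segments = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, c = line.split("\t")[:4]
            segments.append(CnSegmentTruth(chrom, int(start) + 1, int(end), int(c)))
    return segments


def read_bed(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED; returns 1-based inclusive start/end."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            rows.append({"gene": name, "chrom": chrom, "start": start + 1, "end": end})
    return pd.DataFrame(rows)


def read_db_positions(path: str | Path) -> set[tuple[str, int]]:
    """Population-SNP positions from a two-column (chrom, pos) TSV."""
    df = pd.read_csv(path, sep="\t")
    return set(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))


def read_blacklist(path: str | Path) -> set[tuple[str, int, str, str]]:
    """In-house blacklist of (chrom, pos, ref, alt) keys."""
    df = pd.read_csv(path, sep="\t")
    return set(
        zip(
            df.iloc[:, 0].astype(str),
            df.iloc[:, 1].astype(int),
            df.iloc[:, 2].astype(str),
            df.iloc[:, 3].astype(str),
        )
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name, description, then member genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def read_variant_vcf(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Variant evidence from an uncompressed single-sample VCF.

    Pulls total depth from FORMAT/DP (falling back to the sum of AD), alt
    reads from FORMAT/AD, and the strand split from ADF/ADR when present
    (otherwise from INFO/SB; otherwise the split is unknown and alt reads
    are reported on both strands as NA-free equal halves is NOT assumed —
    the forward count defaults to the full alt count, which the strand rule
    treats as single-strand only when the reverse count is zero and alt > 0,
    so supply strand fields for strand filtering to be meaningful).
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        if sample is None:
            sample = list(vcf.header.samples)[0]
        for rec in vcf:
            s = rec.samples[sample]
            ad = s.get("AD")
            for i, alt in enumerate(rec.alts or ()):
                t_alt = int(ad[i + 1]) if ad is not None else 0
                dp = s.get("DP")
                t_depth = int(dp) if dp is not None else int(sum(x or 0 for x in (ad or ())))
                adf, adr = s.get("ADF"), s.get("ADR")
                if adf is not None and adr is not None:
                    fwd, rev = int(adf[i + 1]), int(adr[i + 1])
                else:
                    sb = rec.info.get("SB")
                    if sb is not None and len(sb) >= 4:
                        fwd, rev = int(sb[2]), int(sb[3])
                    else:
                        fwd, rev = t_alt, 0
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "t_depth": t_depth,
                        "t_alt": t_alt,
                        "t_alt_fwd": fwd,
                        "t_alt_rev": rev,
                    }
                )
    return pd.DataFrame(rows)


def loss_calls_to_json(calls) -> list[dict]:
    """Serializable records for gene status output."""
    return [
        {
            "gene": c.gene,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "mean_rep_lrr": None if np.isnan(c.mean_rep_lrr) else round(c.mean_rep_lrr, 4),
            "n_sites": c.n_sites,
            "status": c.status,
        }
        for c in calls
    ]
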