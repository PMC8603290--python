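"""GC-adjusted log-R-ratio (LRR) copy-number calling from paired depths.

The pipeline has four steps: (1) select informative SNP positions — sites
catalogued in a population SNP database whose normal-sample VAF marks them
homozygous (<= 0.05 or >= 0.95) or heterozygous (0.4-0.6); (2) adjust
normal and tumor depths for the GC fraction of the 100 bp flanking window
by binned median-ratio normalization; (3) per-site LRR = log2(adjusted
tumor / adjusted normal), optionally median-centered genome-wide; (4) a
representative LRR per site as the median of a 1 Mb moving window centered
at the site. Gene-level loss/gain calls threshold the mean representative
LRR over a gene interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LossThresholds",
    "LossCall",
    "select_informative_snps",
    "gc_adjust_depths",
    "compute_lrr",
    "smooth_lrr",
    "call_gene_status",
    "call_genes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LossThresholds:
    """Mean representative-LRR cutoffs for gene status calls.

    Conventional defaults: <= -1.0 homozygous loss, <= -0.3 single-copy
    loss, >= +0.3 gain, otherwise neutral.
    """

    homozygous_loss: float = -1.0
    loss: float = -0.3
    gain: float = 0.3


@dataclass(frozen=True)
class LossCall:
    gene: str
    chrom: str
    start: int
    end: int
    mean_rep_lrr: float
    n_sites: int
    status: str | None


def select_informative_snps(
    sites: pd.DataFrame, db_positions: set[tuple[str, int]] | None = None
) -> pd.DataFrame:
    """Step 1: keep database SNPs that are cleanly hom or het in the normal.

    ``db_positions`` is a set of (chrom, pos) pairs; if ``None``, a boolean
    ``in_db`` column on the table is used instead. Normal VAF is computed
    as ``n_alt / n_depth`` (zero-depth sites are excluded). Retained sites
    gain a ``zygosity`` column ("hom" or "het").
    """
    s = sites.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        n_vaf = np.where(s["n_depth"] > 0, s["n_alt"] / np.maximum(s["n_depth"], 1), np.nan)
    s["n_vaf"] = n_vaf

    if db_positions is not None:
        in_db = np.array(
            [(c, int(p)) in db_positions for c, p in zip(s["chrom"], s["pos"])]
        )
    elif "in_db" in s.columns:
        in_db = s["in_db"].astype(bool).to_numpy()
    else:
        raise ValueError("provide db_positions or an in_db column")

    hom = (n_vaf <= 0.05) | (n_vaf >= 0.95)
    het = (n_vaf >= 0.4) & (n_vaf <= 0.6)
    keep = in_db & (hom | het) & (s["n_depth"].to_numpy() > 0)
    out = s.loc[keep].copy()
    out["zygosity"] = np.where(hom[keep], "hom", "het")
    if out.empty:
        warnings.warn("no informative SNPs selected", stacklevel=2)
    return out.reset_index(drop=True)


def _merge_small_bins(bin_ids: np.ndarray, centers_of: dict[int, float], min_sites: int) -> np.ndarray:
    """Group contiguous GC bins until each group has >= min_sites members.

    Small groups are absorbed into the nearest neighbor by count-weighted
    GC-center distance (ties toward the lower-GC side). Returns a group id
    per site.
    """
    uniq, counts = np.unique(bin_ids, return_counts=True)
    groups: list[list[int]] = [[b] for b in uniq]
    gcounts = list(counts)

    def center(g: list[int]) -> float:
        w = np.array([counts[np.searchsorted(uniq, b)] for b in g], dtype=float)
        c = np.array([centers_of[b] for b in g])
        return float(np.average(c, weights=w))

    while len(groups) > 1 and min(gcounts) < min_sites:
        i = int(np.argmin(gcounts))
        cands = [j for j in (i - 1, i + 1) if 0 <= j < len(groups)]
        j = min(cands, key=lambda j: (abs(center(groups[j]) - center(groups[i])), j))
        lo, hi = sorted((i, j))
        groups[lo] = groups[lo] + groups[hi]
        gcounts[lo] = gcounts[lo] + gcounts[hi]
        del groups[hi], gcounts[hi]

    bin_to_group = {b: gi for gi, g in enumerate(groups) for b in g}
    return np.array([bin_to_group[b] for b in bin_ids])


def gc_adjust_depths(
    sites: pd.DataFrame,
    bin_width: float = 0.01,
    min_bin_sites: int = 20,
) -> pd.DataFrame:
    """Step 2: remove GC depth bias sample-by-sample.

    Sites are binned by ``gc100`` into bins of ``bin_width``; within each
    (merged) bin the adjusted depth is raw depth times global median depth
    over bin median depth, independently for normal and tumor. Bins with
    fewer than ``min_bin_sites`` sites are merged with their nearest
    neighbor so medians stay stable. Adds ``n_adj`` and ``t_adj`` columns.
    """
    s = sites.copy()
    if s.empty:
        raise ValueError("no sites to adjust")
    if (s["n_depth"].sum() == 0) or (s["t_depth"].sum() == 0):
        raise ValueError("all depths are zero in one sample; cannot adjust")

    gc = np.clip(s["gc100"].to_numpy(dtype=float), 0.0, 1.0 - 1e-9)
    bin_ids = np.floor(gc / bin_width).astype(int)
    centers = {b: (b + 0.5) * bin_width for b in np.unique(bin_ids)}
    group = _merge_small_bins(bin_ids, centers, min_bin_sites)

    for raw, adj in (("n_depth", "n_adj"), ("t_depth", "t_adj")):
        depth = s[raw].to_numpy(dtype=float)
        global_med = float(np.median(depth))
        out = np.empty_like(depth)
        for g in np.unique(group):
            mask = group == g
            med = float(np.median(depth[mask]))
            if med <= 0:  # degenerate bin: leave depths unscaled
                logger.warning("zero median depth in GC bin group %d for %s", g, raw)
                factor = 1.0
            else:
                factor = global_med / med
            out[mask] = depth[mask] * factor
        s[adj] = out
    return s


def compute_lrr(sites: pd.DataFrame, center_median: bool = True) -> pd.DataFrame:
    """Step 3: per-site LRR = log2(t_adj / n_adj), optionally centered.

    Sites with a zero adjusted depth in either sample are dropped (their
    count is logged) so the track never contains infinities. With
    ``center_median`` the genome-wide median LRR is subtracted, absorbing
    tumor/normal throughput differences.
    """
    ok = (sites["n_adj"] > 0) & (sites["t_adj"] > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropping %d sites with zero adjusted depth", n_dropped)
    track = sites.loc[ok].copy()
    if track.empty:
        raise ValueError("no sites with positive adjusted depths")
    lrr = np.log2(track["t_adj"].to_numpy() / track["n_adj"].to_numpy())
    if center_median:
        lrr = lrr - np.median(lrr)
    track["lrr_raw"] = lrr
    track = track.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return track


def smooth_lrr(track: pd.DataFrame, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Step 4: representative LRR = median over a centered bp window.

    The window covers sites with ``|pos - pos_i| <= window_bp / 2`` on the
    same chromosome; it truncates at chromosome ends and never crosses a
    chromosome boundary. Every site has at least itself in its window.
    """
    t = track.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    half = window_bp / 2.0
    rep = np.empty(len(t))
    for _, idx in t.groupby("chrom", sort=False).indices.items():
        pos = t["pos"].to_numpy()[idx].astype(float)
        lrr = t["lrr_raw"].to_numpy()[idx]
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        rep[idx] = [np.median(lrr[a:b]) for a, b in zip(lo, hi)]
    t["lrr_rep"] = rep
    return t


def call_gene_status(
    track: pd.DataFrame,
    gene: str,
    chrom: str,
    start: int,
    end: int,
    thresholds: LossThresholds = LossThresholds(),
    min_sites: int = 5,
) -> LossCall:
    """Mean representative LRR over a gene interval, thresholded to a call.

    Interval is 1-based inclusive. With fewer than ``min_sites``
    overlapping sites the status is ``None`` (reported missing).
    """
    mask = (track["chrom"] == chrom) & (track["pos"] >= start) & (track["pos"] <= end)
    sub = track.loc[mask, "lrr_rep"]
    n = int(mask.sum())
    if n == 0:
        warnings.warn(f"no LRR sites overlap {gene} ({chrom}:{start}-{end})", stacklevel=2)
        return LossCall(gene, chrom, start, end, float("nan"), 0, None)
    mean = float(sub.mean())
    if n < min_sites:
        return LossCall(gene, chrom, start, end, mean, n, None)
    if mean <= thresholds.homozygous_loss:
        status = "homozygous_loss"
    elif mean <= thresholds.loss:
        status = "loss"
    elif mean >= thresholds.gain:
        status = "gain"
    else:
        status = "neutral"
    return LossCall(gene, chrom, start, end, mean, n, status)


def call_genes(
    track: pd.DataFrame,
    genes: pd.DataFrame,
    thresholds: LossThresholds = LossThresholds(),
    min_sites: int = 5,
) -> list[LossCall]:
    """Vector form of :func:`call_gene_status` over a gene-interval table.

    ``genes`` needs columns ``gene, chrom, start, end`` with 1-based
    inclusive coordinates (BED input is converted on read).
    """
    return [
        call_gene_status(track, r.gene, r.chrom, int(r.start), int(r.end), thresholds, min_sites)
        for r in genes.itertuples(index=False)
    ]
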