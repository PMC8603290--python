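"""Multi-caller consensus merging, somatic discard rules, and TMB.

A candidate mutation survives filtering only if none of the discard rules
fire: tumor depth < 20 reads, tumor VAF < 0.05, more than 2 alt reads in
the germline control, alt reads confined to a single strand, presence in a
population database or in-house blacklist, or support from fewer than
``min_callers`` of the callers. All inequalities are strict exactly as
stated (depth 20, VAF 0.05 and germline alt 2 are kept). Tumor mutation
burden (TMB) is the count of kept non-synonymous mutations; synonymous kept
variants stay in the output tables but not in the count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FilterThresholds",
    "REASONS",
    "compute_vaf",
    "consensus_merge",
    "apply_discard_rules",
    "compute_tmb",
]

#: Canonical order in which reasons are reported.
REASONS = (
    "low_total_reads",
    "low_vaf",
    "germline_support",
    "single_strand",
    "population_db",
    "insufficient_caller_support",
)

_KEY = ["chrom", "pos", "ref", "alt"]
_EVIDENCE = ["t_depth", "t_alt", "t_alt_fwd", "t_alt_rev", "n_alt",
             "in_population_db", "in_blacklist_db", "consequence"]


@dataclass(frozen=True)
class FilterThresholds:
    """Discard-rule thresholds; defaults are the pipeline's published values."""

    min_total_reads: int = 20
    min_vaf: float = 0.05
    max_germline_alt: int = 2
    min_callers: int = 2

    def __post_init__(self) -> None:
        if self.min_total_reads <= 0 or self.min_vaf <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_germline_alt < 0 or self.min_callers < 1:
            raise ValueError("max_germline_alt >= 0 and min_callers >= 1 required")


def compute_vaf(t_alt: int, t_depth: int) -> float:
    """Tumor variant allele frequency ``t_alt / t_depth``.

    Raises ``ValueError`` on zero depth or inconsistent counts; a
    zero-depth site must be pre-filtered (it would be discarded for low
    total reads anyway).
    """
    if t_depth <= 0:
        raise ValueError("VAF undefined at zero tumor depth")
    if not 0 <= t_alt <= t_depth:
        raise ValueError(f"require 0 <= t_alt <= t_depth, got {t_alt}/{t_depth}")
    return t_alt / t_depth


def consensus_merge(
    per_caller: Mapping[str, pd.DataFrame],
    precedence: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Merge per-caller variant tables into one row per distinct variant.

    Parameters
    ----------
    per_caller
        Mapping of caller name to a table keyed by (chrom, pos, ref, alt)
        carrying the read-count evidence columns.
    precedence
        Order in which callers are consulted for evidence when they
        disagree; defaults to the sorted caller names. The source is
        recorded in an ``evidence_caller`` provenance column.

    Raises
    ------
    ValueError
        If two callers report different reference alleles at the same
        position.
    """
    if precedence is None:
        precedence = sorted(per_caller)
    else:
        missing = set(per_caller) - set(precedence)
        if missing:
            raise ValueError(f"precedence omits callers: {sorted(missing)}")

    frames = []
    for caller in precedence:
        t = per_caller[caller]
        if t.empty:
            continue
        t = t.copy()
        t["__caller"] = caller
        frames.append(t)
    if not frames:
        return pd.DataFrame(columns=_KEY + ["callers", "evidence_caller"] + _EVIDENCE)
    pooled = pd.concat(frames, ignore_index=True)

    refs = pooled.groupby(["chrom", "pos"])["ref"].nunique()
    if (refs > 1).any():
        bad = refs[refs > 1].index.tolist()
        raise ValueError(f"conflicting ref alleles at positions: {bad}")

    rows = []
    for key, grp in pooled.groupby(_KEY, sort=True):
        callers = sorted(grp["__caller"].unique())
        # evidence from the highest-precedence caller reporting the variant
        first = grp.iloc[np.argmin([precedence.index(c) for c in grp["__caller"]])]
        row = dict(zip(_KEY, key))
        row["callers"] = ",".join(callers)
        row["evidence_caller"] = first["__caller"]
        for col in _EVIDENCE:
            if col in grp.columns:
                row[col] = first[col]
        rows.append(row)
    merged = pd.DataFrame(rows)
    return merged.sort_values(_KEY, kind="mergesort").reset_index(drop=True)


def _caller_count(callers: Iterable) -> np.ndarray:
    return np.array([len([c for c in str(s).split(",") if c]) for s in callers])


def apply_discard_rules(
    variants: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Evaluate every discard rule on every variant.

    Returns a copy of the input with ``vaf``, boolean per-reason columns,
    a comma-joined ``reasons`` column (in :data:`REASONS` order) and a
    ``kept`` flag that is true iff no reason fired. The decision for each
    row depends only on that row, so output order follows input order.
    """
    v = variants.reset_index(drop=True).copy()
    t_depth = v["t_depth"].to_numpy(dtype=float)
    t_alt = v["t_alt"].to_numpy(dtype=float)
    if (t_alt > t_depth).any() or (t_alt < 0).any() or (t_depth < 0).any():
        raise ValueError("require 0 <= t_alt <= t_depth for all variants")
    fwd = v["t_alt_fwd"].to_numpy(dtype=float)
    rev = v["t_alt_rev"].to_numpy(dtype=float)
    if not np.array_equal(fwd + rev, t_alt):
        raise ValueError("strand counts must sum to t_alt")

    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(t_depth > 0, t_alt / np.maximum(t_depth, 1), np.nan)

    flags = {
        "low_total_reads": t_depth < thresholds.min_total_reads,
        # zero-depth sites have undefined VAF; they already fail the depth rule
        "low_vaf": np.where(t_depth > 0, vaf < thresholds.min_vaf, False),
        "germline_support": v["n_alt"].to_numpy(dtype=float) > thresholds.max_germline_alt,
        "single_strand": ((fwd == 0) ^ (rev == 0)) & (t_alt > 0),
        "population_db": v["in_population_db"].astype(bool).to_numpy()
        | v["in_blacklist_db"].astype(bool).to_numpy(),
        "insufficient_caller_support": _caller_count(v["callers"]) < thresholds.min_callers,
    }

    v["vaf"] = vaf
    any_reason = np.zeros(len(v), dtype=bool)
    for name in REASONS:
        v[f"reason_{name}"] = flags[name]
        any_reason |= flags[name]
    v["reasons"] = [
        ",".join(name for name in REASONS if flags[name][i]) for i in range(len(v))
    ]
    v["kept"] = ~any_reason
    return v


def compute_tmb(decisions: pd.DataFrame) -> int:
    """Tumor mutation burden: kept variants annotated non-synonymous."""
    kept = decisions["kept"].astype(bool)
    return int((kept & (decisions["consequence"] == "non_synonymous")).sum())
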