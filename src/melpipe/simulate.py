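"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators mirror the four data streams a paired tumor/normal study
produces: per-SNP depth profiles (copy-number input), candidate somatic
variant calls (filtering input), gene-by-sample count matrices (expression
input), and a patient cohort with immunohistochemistry markers and survival
outcomes (biostatistics input). Each generator is deterministic given the
global seed: the seed fans out to independent per-generator child streams,
so re-running one generator never perturbs another.

Depths follow a negative-binomial model — overdispersion is universal in
hybrid-capture sequencing — with a smooth multiplicative GC bias
``g(gc) = 1 + amplitude * sin(2*pi*gc)`` acting identically on tumor and
normal. Tumor means scale with the local copy number ``c`` through
``purity * c/2 + (1 - purity)``, floored at ``residual_depth_floor`` so
homozygous deletions retain the residual mapped coverage observed in real
capture data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CnSegmentTruth",
    "SimulationConfig",
    "GROUPS",
    "default_segments",
    "simulate_depth_profile",
    "simulate_variant_calls",
    "simulate_expression",
    "simulate_cohort",
]

#: Four-way immune stratification labels used throughout the cohort stage.
GROUPS = ("CD8lo/CD155lo", "CD8lo/CD155hi", "CD8hi/CD155lo", "CD8hi/CD155hi")

#: Discard rules the variant generator can violate, one at a time.
ARTIFACT_RULES = (
    "low_total_reads",
    "low_vaf",
    "germline_support",
    "single_strand",
    "population_db",
)

_STREAMS = {"depths": 0, "variants": 1, "expression": 2, "cohort": 3}
_BASES = np.array(list("ACGT"))


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent child stream for one generator under a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class CnSegmentTruth:
    """One piecewise-constant copy-number segment (1-based, inclusive).

    ``expected_lrr`` is the asymptotic log2 tumor/normal depth ratio at
    purity 1; the residual-coverage floor of the depth generator makes a
    zero-copy segment behave like copy ``eps = 0.1`` rather than true zero.
    """

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("positions are 1-based; start must be >= 1")
        if self.copy_number < 0:
            raise ValueError("copy number must be a non-negative integer")

    @property
    def expected_lrr(self) -> float:
        return math.log2(max(self.copy_number, 0.1) / 2.0)


def default_segments() -> list[CnSegmentTruth]:
    """A small genome, mostly diploid, with one segment per copy state 0-4.

    Diploid territory dominates (70 of 100 Mb) so that median-centering of
    the LRR track leaves diploid segments at zero, as on a largely euploid
    exome.
    """
    return [
        CnSegmentTruth("chr1", 1, 60_000_000, 2),
        CnSegmentTruth("chr2", 1, 10_000_000, 1),
        CnSegmentTruth("chr2", 10_000_001, 20_000_000, 2),
        CnSegmentTruth("chr3", 1, 5_000_000, 0),
        CnSegmentTruth("chr3", 5_000_001, 15_000_000, 3),
        CnSegmentTruth("chr3", 15_000_001, 20_000_000, 4),
    ]


@dataclass
class SimulationConfig:
    """Shared knobs for all four generators.

    Defaults describe a clonal cell-line study: purity 1, mean on-target
    depth 100x with negative-binomial dispersion 10, GC-bias amplitude 0.3,
    a cohort of 144 patients stratified by CD8 infiltration (cutoff 82.8
    cells per 0.25 mm^2 field) and CD155 immunohistochemistry score (high =
    2-3), and 25 paired baseline/resistance CD155 scorings.
    """

    seed: int = 0
    # depth model
    mean_depth: float = 100.0
    nb_dispersion: float = 10.0
    gc_bias_amplitude: float = 0.3
    purity: float = 1.0
    n_snps: int = 10_000
    segments: list[CnSegmentTruth] = field(default_factory=default_segments)
    het_fraction: float = 0.5
    residual_depth_floor: float = 0.05
    db_fraction: float = 1.0
    # variant calls
    n_true_somatic: int = 50
    n_artifacts_per_rule: int = 5
    n_low_support: int = 0
    nonsyn_fraction: float = 0.6
    # expression
    n_genes: int = 2000
    n_samples_per_group: int = 5
    n_shifted_genes: int = 200
    expr_shift_log2: float = 1.0
    expr_dispersion: float = 8.0
    # cohort
    cohort_n: int = 144
    hazard_ratios: dict[str, float] = field(
        default_factory=lambda: {
            "CD8lo/CD155lo": 1.0,
            "CD8lo/CD155hi": 1.3,
            "CD8hi/CD155lo": 0.4,
            "CD8hi/CD155hi": 1.2,
        }
    )
    censoring_rate: float = 0.25
    cd8_cutoff_truth: float = 82.8
    n_paired: int = 25
    cd155_post_shift: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.nb_dispersion <= 0:
            raise ValueError("mean_depth and nb_dispersion must be positive")
        if not 0 <= self.gc_bias_amplitude < 1:
            raise ValueError("gc_bias_amplitude must lie in [0, 1)")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must lie in (0, 1]")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not 0 <= self.het_fraction <= 1:
            raise ValueError("het_fraction must lie in [0, 1]")
        if not 0 <= self.db_fraction <= 1:
            raise ValueError("db_fraction must lie in [0, 1]")
        if not 0 <= self.nonsyn_fraction <= 1:
            raise ValueError("nonsyn_fraction must lie in [0, 1]")
        if self.n_true_somatic < 0 or self.n_artifacts_per_rule < 0:
            raise ValueError("variant counts must be non-negative")
        for name, hr in self.hazard_ratios.items():
            if hr <= 0:
                raise ValueError(f"hazard ratio for {name} must be positive")
        _validate_segments(self.segments)


def _validate_segments(segments: list[CnSegmentTruth]) -> None:
    by_chrom: dict[str, list[CnSegmentTruth]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial with given mean and size (dispersion) parameter."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + np.maximum(mean, 1e-12))
    return rng.negative_binomial(size_param, p)


def gc_bias_factor(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth multiplicative depth bias as a function of window GC fraction."""
    return 1.0 + amplitude * np.sin(2.0 * np.pi * np.asarray(gc, dtype=float))


def simulate_depth_profile(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[CnSegmentTruth]]:
    """Paired tumor/normal depths at SNP positions over a segmented genome.

    Returns a site table (columns ``chrom, pos, ref, alt, n_depth, n_alt,
    t_depth, t_alt, gc100, in_db, true_c``) sorted by (chrom, pos), plus the
    truth segment list unchanged. Sites are allocated to segments in
    proportion to segment length; flanking-window GC is drawn uniformly on
    [0.3, 0.7] independently of position, so copy state and GC are
    unconfounded by construction.
    """
    if config.n_snps <= 0:
        raise ValueError("n_snps must be positive")
    _validate_segments(config.segments)
    rng = _child_rng(config.seed, "depths")

    lengths = np.array([s.end - s.start + 1 for s in config.segments], dtype=float)
    alloc = np.floor(config.n_snps * lengths / lengths.sum()).astype(int)
    # distribute the remainder deterministically to the longest segments
    for i in np.argsort(-lengths)[: config.n_snps - alloc.sum()]:
        alloc[i] += 1

    frames = []
    for seg, k in zip(config.segments, alloc):
        if k == 0:
            continue
        pos = np.sort(
            rng.choice(np.arange(seg.start, seg.end + 1), size=k, replace=False)
            if seg.end - seg.start + 1 >= k
            else rng.integers(seg.start, seg.end + 1, size=k)
        )
        frames.append(
            pd.DataFrame({"chrom": seg.chrom, "pos": pos, "true_c": seg.copy_number})
        )
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    n = len(sites)

    gc = rng.uniform(0.3, 0.7, size=n)
    g = gc_bias_factor(gc, config.gc_bias_amplitude)
    normal_mean = config.mean_depth * g
    copy_mult = np.maximum(
        config.purity * sites["true_c"].to_numpy() / 2.0 + (1.0 - config.purity),
        config.residual_depth_floor,
    )
    tumor_mean = config.mean_depth * g * copy_mult

    n_depth = _nb_draw(rng, normal_mean, config.nb_dispersion)
    t_depth = _nb_draw(rng, tumor_mean, config.nb_dispersion)

    het = rng.random(n) < config.het_fraction
    vaf = np.where(
        het,
        rng.beta(100.0, 100.0, size=n),
        np.where(rng.random(n) < 0.5, rng.beta(1.0, 100.0, size=n), rng.beta(100.0, 1.0, size=n)),
    )
    n_alt = rng.binomial(n_depth, vaf)
    t_alt = rng.binomial(t_depth, vaf)

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    sites["ref"] = _BASES[ref_idx]
    sites["alt"] = _BASES[alt_idx]
    sites["n_depth"] = n_depth
    sites["n_alt"] = n_alt
    sites["t_depth"] = t_depth
    sites["t_alt"] = t_alt
    sites["gc100"] = gc
    sites["in_db"] = rng.random(n) < config.db_fraction
    cols = ["chrom", "pos", "ref", "alt", "n_depth", "n_alt", "t_depth", "t_alt", "gc100", "in_db", "true_c"]
    return sites[cols], list(config.segments)


def _strand_split(rng: np.random.Generator, t_alt: int) -> tuple[int, int]:
    """Both-strand split: at least one alt read per strand when t_alt >= 2."""
    if t_alt < 2:
        fwd = int(rng.integers(0, 2)) * t_alt
        return fwd, t_alt - fwd
    fwd = int(rng.integers(1, t_alt))
    return fwd, t_alt - fwd


def simulate_variant_calls(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Candidate somatic calls: true somatics plus single-rule artifacts.

    True somatic variants satisfy every keep-condition (tumor depth >= 20,
    VAF >= 0.05, germline alt reads <= 2, both strands represented, absent
    from the population and blacklist databases) and carry support from at
    least two of the three callers. For each of the five discard rules,
    ``n_artifacts_per_rule`` variants violate exactly that rule and no
    other; ``n_low_support`` optional extras are clean but single-caller.

    Returns ``(variants, truth)`` where ``truth`` holds ``"somatic"`` or the
    violated rule name, index-aligned with the variant table.
    """
    rng = _child_rng(config.seed, "variants")
    rows: list[dict] = []
    labels: list[str] = []

    total = (
        config.n_true_somatic
        + len(ARTIFACT_RULES) * config.n_artifacts_per_rule
        + config.n_low_support
    )
    if total == 0:
        empty = pd.DataFrame(
            columns=[
                "chrom", "pos", "ref", "alt", "callers", "t_depth", "t_alt",
                "t_alt_fwd", "t_alt_rev", "n_alt", "in_population_db",
                "in_blacklist_db", "consequence",
            ]
        )
        return empty, pd.Series([], dtype=object, name="truth_class")
    positions = rng.choice(np.arange(1, 200_000_000), size=total, replace=False)

    def base_variant(pos: int) -> dict:
        ref_i = int(rng.integers(0, 4))
        alt_i = (ref_i + int(rng.integers(1, 4))) % 4
        depth = int(rng.integers(50, 200))
        t_alt = max(4, int(round(depth * rng.uniform(0.10, 0.60))))
        t_alt = min(t_alt, depth)
        fwd, rev = _strand_split(rng, t_alt)
        n_callers = int(rng.integers(2, 4))
        callers = sorted(rng.choice(["caller_A", "caller_B", "caller_C"], size=n_callers, replace=False))
        return {
            "chrom": "chr1",
            "pos": int(pos),
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
            "callers": ",".join(callers),
            "t_depth": depth,
            "t_alt": t_alt,
            "t_alt_fwd": fwd,
            "t_alt_rev": rev,
            "n_alt": int(rng.choice([0, 1, 2], p=[0.8, 0.15, 0.05])),
            "in_population_db": False,
            "in_blacklist_db": False,
        }

    cursor = 0
    for _ in range(config.n_true_somatic):
        rows.append(base_variant(positions[cursor])); cursor += 1
        labels.append("somatic")

    for rule in ARTIFACT_RULES:
        for _ in range(config.n_artifacts_per_rule):
            v = base_variant(positions[cursor]); cursor += 1
            if rule == "low_total_reads":
                depth = int(rng.integers(10, 20))
                t_alt = int(rng.integers(2, max(3, depth // 2 + 1)))
                fwd, rev = _strand_split(rng, t_alt)
                v.update(t_depth=depth, t_alt=t_alt, t_alt_fwd=fwd, t_alt_rev=rev)
            elif rule == "low_vaf":
                depth = int(rng.integers(150, 400))
                t_alt = max(2, int(depth * rng.uniform(0.01, 0.045)))
                while t_alt / depth >= 0.05:
                    t_alt -= 1
                fwd, rev = _strand_split(rng, t_alt)
                v.update(t_depth=depth, t_alt=t_alt, t_alt_fwd=fwd, t_alt_rev=rev)
            elif rule == "germline_support":
                v["n_alt"] = int(rng.integers(3, 11))
            elif rule == "single_strand":
                if rng.random() < 0.5:
                    v.update(t_alt_fwd=v["t_alt"], t_alt_rev=0)
                else:
                    v.update(t_alt_fwd=0, t_alt_rev=v["t_alt"])
            elif rule == "population_db":
                if rng.random() < 0.5:
                    v["in_population_db"] = True
                else:
                    v["in_blacklist_db"] = True
            rows.append(v)
            labels.append(rule)

    for _ in range(config.n_low_support):
        v = base_variant(positions[cursor]); cursor += 1
        v["callers"] = str(rng.choice(["caller_A", "caller_B", "caller_C"]))
        rows.append(v)
        labels.append("insufficient_caller_support")

    variants = pd.DataFrame(rows)
    variants["consequence"] = np.where(
        rng.random(len(variants)) < config.nonsyn_fraction, "non_synonymous", "synonymous"
    )
    truth = pd.Series(labels, name="truth_class")
    return variants, truth


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Gene-by-sample negative-binomial counts with a two-group shift.

    The first ``n_shifted_genes`` (randomly chosen) genes gain
    ``expr_shift_log2`` log2-units of mean expression in group B. Returns
    the raw count matrix (genes x samples), per-sample group labels, and the
    list of shifted gene identifiers.
    """
    rng = _child_rng(config.seed, "expression")
    n_g, n_s = config.n_genes, 2 * config.n_samples_per_group
    genes = [f"gene{i:05d}" for i in range(n_g)]
    samples = [f"A{i}" for i in range(config.n_samples_per_group)] + [
        f"B{i}" for i in range(config.n_samples_per_group)
    ]
    labels = pd.Series(
        ["A"] * config.n_samples_per_group + ["B"] * config.n_samples_per_group,
        index=samples, name="group",
    )
    base_mean = np.exp(rng.normal(3.0, 1.2, size=n_g))
    shifted_idx = rng.choice(n_g, size=min(config.n_shifted_genes, n_g), replace=False)
    log2fc = np.zeros(n_g)
    log2fc[shifted_idx] = config.expr_shift_log2

    mean = np.tile(base_mean[:, None], (1, n_s)).astype(float)
    is_b = np.array([lab == "B" for lab in labels])
    mean[:, is_b] *= 2.0 ** log2fc[:, None]
    counts = _nb_draw(rng, mean, config.expr_dispersion)
    matrix = pd.DataFrame(counts, index=genes, columns=samples)
    shifted_genes = sorted(genes[i] for i in shifted_idx)
    return matrix, labels, shifted_genes


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Patient table with markers, stratified survival, and paired scores.

    CD8 counts are gamma-distributed (shape 2, scale 50: median near the
    82.8 cutoff); CD155 scores are ordinal 0-3 with roughly the marginal
    split of a melanoma cohort. PFS and OS event times are exponential with
    stratum hazards ``hazard_ratios[group] * log(2)/median``, medians 6 and
    18 months; censoring is independent exponential calibrated to
    ``censoring_rate``. The first ``n_paired`` patients carry a
    resistance-state CD155 score shifted upward (by ``cd155_post_shift`` on
    average) when their resistance-state CD8 count is high.
    """
    rng = _child_rng(config.seed, "cohort")
    n = config.cohort_n
    cd8 = rng.gamma(2.0, 50.0, size=n)
    cd155 = rng.choice([0, 1, 2, 3], size=n, p=[0.28, 0.28, 0.22, 0.22])
    cd8_hi = cd8 >= config.cd8_cutoff_truth
    cd155_hi = cd155 >= 2
    group = np.where(
        cd8_hi,
        np.where(cd155_hi, "CD8hi/CD155hi", "CD8hi/CD155lo"),
        np.where(cd155_hi, "CD8lo/CD155hi", "CD8lo/CD155lo"),
    )
    hr = np.array([config.hazard_ratios[g] for g in group])

    def survival(median_months: float) -> tuple[np.ndarray, np.ndarray]:
        lam = math.log(2.0) / median_months * hr
        t_event = rng.exponential(1.0 / lam)
        if config.censoring_rate == 0:
            return t_event, np.ones(n, dtype=bool)
        lam_c = lam * config.censoring_rate / (1.0 - config.censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c)
        return np.minimum(t_event, t_cens), t_event <= t_cens

    pfs, pfs_event = survival(6.0)
    os_, os_event = survival(18.0)
    os_ = np.maximum(os_, pfs)  # death never precedes progression follow-up

    treatment_line = rng.choice(["first", "second"], size=n, p=[0.91, 0.09])
    melanoma_type = rng.choice(
        ["cutaneous_or_unknown", "acral_or_mucosal"], size=n, p=[0.44, 0.56]
    )

    cd155_post = np.full(n, np.nan)
    cd8_post = np.full(n, np.nan)
    k = min(config.n_paired, n)
    cd8_post[:k] = rng.gamma(2.0, 50.0, size=k)
    post_hi = cd8_post[:k] >= config.cd8_cutoff_truth
    bump = np.where(
        post_hi, rng.poisson(config.cd155_post_shift, size=k), rng.integers(-1, 2, size=k)
    )
    cd155_post[:k] = np.clip(cd155[:k] + bump, 0, 3)

    return pd.DataFrame(
        {
            "id": [f"P{i:03d}" for i in range(n)],
            "cd8_count": cd8,
            "cd155_score": cd155,
            "treatment_line": treatment_line,
            "melanoma_type": melanoma_type,
            "pfs_months": pfs,
            "pfs_event": pfs_event,
            "os_months": os_,
            "os_event": os_event,
            "cd8_post": cd8_post,
            "cd155_post": cd155_post,
            "true_group": group,
        }
    )
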