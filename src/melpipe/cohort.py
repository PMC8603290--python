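"""ROC cut-off selection, immune stratification, and survival comparisons.

Implements the cohort-analysis stage of the study design: pick marker
cut-offs from ROC curves against a 6-month progression-free-survival
outcome (Youden's J), split patients into four CD8 x CD155 groups, compare
group composition with Fisher's exact test, estimate survival with
Kaplan-Meier curves, compare them with log-rank tests (Bonferroni option
for pairwise follow-up), and test paired baseline/resistance marker shifts
with a paired t-test.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "RocCutoff",
    "progression_free_at",
    "roc_cutoff",
    "stratify",
    "fisher_exact_2x2",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank",
    "paired_pre_post",
    "GROUPS",
]

logger = logging.getLogger(__name__)

GROUPS = ("CD8lo/CD155lo", "CD8lo/CD155hi", "CD8hi/CD155lo", "CD8hi/CD155hi")


@dataclass(frozen=True)
class RocCutoff:
    cutoff: float
    youden_j: float
    curve: pd.DataFrame  # columns: threshold, sensitivity, specificity


def progression_free_at(
    times: np.ndarray,
    events: np.ndarray,
    horizon: float = 6.0,
    censored_policy: str = "exclude",
) -> tuple[np.ndarray, np.ndarray]:
    """Dichotomize survival data at a landmark time.

    Returns ``(outcome, valid)`` where ``outcome`` is True for patients
    progression-free at the horizon. Patients censored before the horizon
    carry no information about it; they are excluded by default
    (``censored_policy="exclude"``) or counted as non-progressors with
    ``censored_policy="non_progressor"``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    progressed = events & (times < horizon)
    free = times >= horizon
    censored_early = ~events & (times < horizon)
    if censored_policy == "exclude":
        valid = ~censored_early
        outcome = free
    elif censored_policy == "non_progressor":
        valid = np.ones_like(events)
        outcome = free | censored_early
    else:
        raise ValueError(f"unknown censored_policy {censored_policy!r}")
    assert np.all(outcome[valid] == ~progressed[valid])
    return outcome, valid


def roc_cutoff(
    marker: np.ndarray, outcome: np.ndarray, direction: str = ">="
) -> RocCutoff:
    """Cut-off maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the observed marker values; with
    ``direction=">="`` a marker at or above the threshold predicts a
    positive outcome (use ``"<"`` for markers where low values predict the
    positive class). Ties in J break toward the smaller cutoff.
    """
    marker = np.asarray(marker, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if outcome.all() or not outcome.any():
        raise ValueError("outcome has a single class; ROC undefined")
    if direction not in (">=", "<"):
        raise ValueError("direction must be '>=' or '<'")

    thresholds = np.unique(marker)
    n_pos = outcome.sum()
    n_neg = (~outcome).sum()
    rows = []
    for thr in thresholds:
        pred = marker >= thr if direction == ">=" else marker < thr
        sens = (pred & outcome).sum() / n_pos
        spec = (~pred & ~outcome).sum() / n_neg
        rows.append((thr, sens, spec))
    curve = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])
    j = curve["sensitivity"] + curve["specificity"] - 1.0
    best = int(j.idxmax())  # idxmax returns the first (smallest threshold) maximum
    return RocCutoff(float(curve.loc[best, "threshold"]), float(j[best]), curve)


def stratify(
    cohort: pd.DataFrame,
    cd8_cutoff: float,
    cd155_high_levels: frozenset[int] = frozenset({2, 3}),
) -> pd.DataFrame:
    """Assign each patient to one of the four CD8 x CD155 groups.

    CD8-high means ``cd8_count >= cd8_cutoff`` (the cutoff itself is high);
    CD155-high means the ordinal score is in ``cd155_high_levels``.
    Patients with a missing marker are excluded with a logged count.
    """
    c = cohort.copy()
    missing = c["cd8_count"].isna() | c["cd155_score"].isna()
    if missing.any():
        logger.info("excluding %d patients with missing markers", int(missing.sum()))
        c = c.loc[~missing].copy()
    cd8_hi = c["cd8_count"].to_numpy(dtype=float) >= cd8_cutoff
    cd155_hi = np.isin(c["cd155_score"].to_numpy(dtype=int), list(cd155_high_levels))
    c["group"] = np.where(
        cd8_hi,
        np.where(cd155_hi, "CD8hi/CD155hi", "CD8hi/CD155lo"),
        np.where(cd155_hi, "CD8lo/CD155hi", "CD8lo/CD155lo"),
    )
    return c


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities of all tables with the
    same margins no more probable than the observed one (the
    minimum-likelihood convention). Returns the sample odds ratio
    ``(a*d)/(b*c)`` (inf/nan on zero cells) and the p-value; a zero margin
    yields p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        logger.info("zero margin in 2x2 table; p = 1 by convention")
        return float("nan"), 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step-function table with columns ``time`` and ``survival``,
    starting at (0, 1); censored subjects leave the risk set without a
    step.
    """
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    ).reset_index(drop=True)


def logrank_test(
    groups: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, int, float]:
    """Log-rank comparison of two or more survival curves.

    ``groups`` is a list of ``(times, events)`` pairs. Returns
    ``(chi_square, df, p)`` with ``df = n_groups - 1``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for times, events in groups:
        if len(times) == 0:
            raise ValueError("empty group in log-rank test")
    if not any(np.asarray(e, dtype=bool).any() for _, e in groups):
        raise ValueError("no events in any group")
    durations = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    observed = np.concatenate([np.asarray(e, dtype=bool) for _, e in groups])
    label = np.concatenate(
        [np.full(len(t), i) for i, (t, _) in enumerate(groups)]
    )
    res = multivariate_logrank_test(durations, label, observed)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def pairwise_logrank(
    groups: dict[str, tuple[np.ndarray, np.ndarray]],
    bonferroni: bool = True,
) -> pd.DataFrame:
    """All pairwise log-rank tests, optionally Bonferroni-adjusted.

    The adjusted p multiplies the raw p by the number of comparisons,
    capped at 1.
    """
    names = sorted(groups)
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for g1, g2 in pairs:
        chi2, _, p = logrank_test([groups[g1], groups[g2]])
        rows.append({"group1": g1, "group2": g2, "chi_square": chi2, "p_raw": p})
    out = pd.DataFrame(rows)
    if bonferroni:
        out["p_adjusted"] = np.minimum(out["p_raw"] * len(pairs), 1.0)
    return out


def paired_pre_post(
    pre: np.ndarray, post: np.ndarray
) -> tuple[float, float]:
    """Paired t-test of a pre/post marker shift.

    Returns ``(mean_change, p_two_sided)`` where the change is post minus
    pre. Degenerate input with zero variance of the differences gives p = 1
    for zero mean change and a limiting p = 0 (with a warning) otherwise.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    if len(pre) < 2:
        raise ValueError("need at least two pairs")
    diff = post - pre
    mean_change = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.isclose(mean_change, 0.0):
            return mean_change, 1.0
        warnings.warn(
            "zero variance of paired differences with nonzero mean; p -> 0",
            stacklevel=2,
        )
        return mean_change, 0.0
    t = stats.ttest_rel(post, pre)
    return mean_change, float(t.pvalue)
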