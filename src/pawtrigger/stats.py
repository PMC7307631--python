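"""Behavioral trial statistics: trigger counts, paired tests, ANOVA, bootstrap.

The learning analysis asks whether animals make more criterion movements on
training (rewarded) trials than on baseline trials and whether training
counts rise across days.  The inferential toolkit mirrors common practice
in conditioning studies:

* per-trial trigger counts tabulated by mouse × day × mode, with per-cell
  means (each mouse contributes one value per cell, so tests pair by mouse);
* paired t tests with Bonferroni correction over an explicitly declared
  comparison family;
* one-way ANOVA across digits for the per-digit movement-count analysis;
* estimation statistics: the mean paired difference with a bootstrapped
  95% confidence interval (BCa by default, percentile as fallback),
  resampling mice with replacement under a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import CriterionConfig
from .errors import ConfigurationError, InsufficientDataError, InputError
from .runner import TrialRecord
from .synthetic import PoseTrace

__all__ = [
    "count_triggers",
    "cell_means",
    "count_post_trigger_contralateral",
    "count_digit_movements",
    "paired_t_bonferroni",
    "ComparisonResult",
    "anova_digits",
    "AnovaResult",
    "EstimationResult",
    "bootstrap_mean_difference",
]


def count_triggers(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy table of per-trial trigger counts (QC-excluded trials omitted)."""
    rows = [
        {
            "mouse": t.mouse_id,
            "day": t.day,
            "mode": t.mode,
            "trial": t.trial,
            "count": t.trigger_count,
        }
        for t in trials
        if not t.excluded
    ]
    return pd.DataFrame(rows, columns=["mouse", "day", "mode", "trial", "count"])


def cell_means(table: pd.DataFrame, value: str = "count") -> pd.DataFrame:
    """Per-(mouse, day, mode) mean of a per-trial column."""
    return (
        table.groupby(["mouse", "day", "mode"], as_index=False)[value]
        .mean()
        .rename(columns={value: "mean"})
    )


def _pair_dys(trace: PoseTrace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pair second-frame row, |dy_left|, |dy_right|) over non-overlapping pairs."""
    my = trace.mean_paw_y()
    n_pairs = len(my) // 2
    i = 2 * np.arange(n_pairs)
    dy_l = np.abs(my[i + 1, 0] - my[i, 0])
    dy_r = np.abs(my[i + 1, 1] - my[i, 1])
    return i + 1, dy_l, dy_r


def count_post_trigger_contralateral(
    trace: PoseTrace,
    events: Sequence,
    threshold: float = 10.0,
) -> int:
    """Right-paw movements above threshold on the pair right after each trigger.

    For each logged trigger, the immediately following frame pair is
    inspected; the count is how many of those show ``|dy_right| >
    threshold``.  A trigger on the last pair of the trace has no following
    pair and is skipped.  This quantifies whether left-paw triggers are
    being trailed by right-paw movement, i.e. how selective the reinforced
    behavior really is.
    """
    rows, _, dy_r = _pair_dys(trace)
    pair_of_frame = {int(trace.frame_indices[r]): p for p, r in enumerate(rows)}
    count = 0
    for e in events:
        p = pair_of_frame.get(int(getattr(e, "frame_index", e)))
        if p is None or p + 1 >= len(dy_r):
            continue  # trigger at trace end: skipped, noted by caller
        if dy_r[p + 1] > threshold:
            count += 1
    return count


def count_digit_movements(
    trace: PoseTrace,
    paw: str,
    threshold: float | None = None,
) -> np.ndarray:
    """Per-digit counts of above-threshold vertical movements in one trial.

    Uses the same non-overlapping pairing and |Δy| convention as the
    trigger engine, per digit: the left paw counts ``|Δy| >= 5`` px
    (inclusive, like the trigger gate), the right ``|Δy| > 10`` px.
    Returns a length-4 array in digit order.
    """
    if paw not in ("left", "right"):
        raise InputError(f"paw must be 'left' or 'right', got {paw!r}")
    cols = slice(0, 4) if paw == "left" else slice(4, 8)
    y = trace.positions[:, cols, 1]
    n_pairs = len(y) // 2
    i = 2 * np.arange(n_pairs)
    dy = np.abs(y[i + 1] - y[i])  # (n_pairs, 4)
    if threshold is None:
        c = CriterionConfig()
        return (
            (dy >= c.min_left).sum(axis=0)
            if paw == "left"
            else (dy > c.max_right).sum(axis=0)
        )
    op = np.greater_equal if paw == "left" else np.greater
    return op(dy, threshold).sum(axis=0)


@dataclass
class ComparisonResult:
    label: str
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    significant: bool
    zero_variance: bool = False


def paired_t_bonferroni(
    cells: pd.DataFrame,
    comparisons: Sequence[tuple[dict, dict]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[ComparisonResult]:
    """Paired t tests over a declared family, Bonferroni-adjusted.

    ``cells`` is the output of :func:`cell_means`; each comparison is a
    pair of cell selectors (e.g. ``{"day": 3, "mode": "training"}`` vs
    ``{"day": 1, "mode": "training"}``), paired by mouse.  Adjusted
    p = min(1, raw p × family size); the family is exactly the comparisons
    passed in one call.
    """
    m = len(comparisons)
    results: list[ComparisonResult] = []
    for k, (sel_a, sel_b) in enumerate(comparisons):
        a = cells.loc[
            np.logical_and.reduce([cells[c] == v for c, v in sel_a.items()])
        ].set_index("mouse")["mean"]
        b = cells.loc[
            np.logical_and.reduce([cells[c] == v for c, v in sel_b.items()])
        ].set_index("mouse")["mean"]
        mice = a.index.intersection(b.index)
        missing = a.index.symmetric_difference(b.index)
        if len(missing):
            raise InputError(
                f"comparison {sel_a} vs {sel_b}: unpaired mouse/mice {list(missing)}"
            )
        if len(mice) < 2:
            raise InsufficientDataError(
                f"comparison {sel_a} vs {sel_b}: needs >= 2 paired mice"
            )
        diffs = (a.loc[mice] - b.loc[mice]).to_numpy(dtype=float)
        label = labels[k] if labels else f"{sel_a} vs {sel_b}"
        if np.allclose(np.std(diffs, ddof=1), 0.0):
            results.append(
                ComparisonResult(label, float("nan"), len(mice) - 1, 1.0, 1.0,
                                 False, zero_variance=True)
            )
            continue
        res = sps.ttest_rel(a.loc[mice], b.loc[mice])
        p_adj = min(1.0, float(res.pvalue) * m)
        results.append(
            ComparisonResult(
                label,
                float(res.statistic),
                len(mice) - 1,
                float(res.pvalue),
                p_adj,
                p_adj < alpha,
            )
        )
    return results


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def anova_digits(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA across per-digit movement counts.

    ``groups`` is one sequence of per-trial counts per digit; tests whether
    any digit moves above threshold more often than the others within a
    (day, mode) stratum.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError(
            "ANOVA needs >= 2 digits with >= 2 observations each"
        )
    arrays = [np.asarray(g, dtype=float) for g in groups]
    res = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    return AnovaResult(
        F=float(res.statistic), df_between=k - 1, df_within=n - k, p=float(res.pvalue)
    )


@dataclass
class EstimationResult:
    """Mean paired difference with a bootstrapped confidence interval."""

    mean_difference: float
    ci_low: float
    ci_high: float
    n_resamples: int
    ci_level: float
    seed: int
    method: str = "bca"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean_difference <= self.ci_high:
            raise InputError(
                "estimation CI must bracket the mean difference: "
                f"[{self.ci_low}, {self.ci_high}] vs {self.mean_difference}"
            )

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def bootstrap_mean_difference(
    pairs: Sequence[tuple[float, float]],
    n_resamples: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
    method: str = "bca",
) -> EstimationResult:
    """Bootstrap the mean of per-mouse paired differences A − B.

    Mice are resampled with replacement; the statistic is the mean paired
    difference, and the CI comes from the resample distribution (BCa by
    default, ``method="percentile"`` as fallback).  Deterministic under a
    fixed seed.  Degenerate data (all differences equal) collapse the CI
    to a point, which is reported, not an error.
    """
    if n_resamples < 100:
        raise ConfigurationError(
            f"n_resamples must be >= 100, got {n_resamples}"
        )
    if len(pairs) < 2:
        raise InsufficientDataError("bootstrap needs >= 2 paired observations")
    if method not in ("bca", "percentile"):
        raise ConfigurationError(f"method must be bca|percentile, got {method!r}")
    diffs = np.array([a - b for a, b in pairs], dtype=float)
    point = float(np.mean(diffs))
    if np.allclose(diffs, diffs[0]):
        return EstimationResult(point, point, point, n_resamples, ci_level, seed, method)
    rng = np.random.default_rng(seed)
    res = sps.bootstrap(
        (diffs,),
        np.mean,
        n_resamples=n_resamples,
        confidence_level=ci_level,
        method="BCa" if method == "bca" else "percentile",
        rng=rng,
        vectorized=True,
        axis=-1,
    )
    lo = float(res.confidence_interval.low)
    hi = float(res.confidence_interval.high)
    # BCa intervals can land on the point estimate with tiny samples
    lo, hi = min(lo, point), max(hi, point)
    return EstimationResult(point, lo, hi, n_resamples, ci_level, seed, method)
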