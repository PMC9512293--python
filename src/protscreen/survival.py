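"""Best-cutoff survival dichotomization: log-rank scan, Kaplan-Meier, permutation correction.

The two-group log-rank statistic uses the standard aggregated risk-set
formulation with hypergeometric variance at each distinct event time.
``best_cutpoint`` scans the midpoints between consecutive distinct
marker values (subject to a minimum group proportion) and returns the
argmax of the statistic; because that maximization makes the naive
p-value anti-conservative, ``corrected_cutpoint_p`` provides a
permutation null of the maximal statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .tables import SurvivalCohort

logger = logging.getLogger(__name__)


def _event_time_counts(
    time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """At-risk and event indicator matrices over distinct event times.

    Returns (times, atrisk[n, T], died[n, T]) where column t refers to the
    t-th distinct event time.
    """
    etimes = np.unique(time[event == 1])
    atrisk = time[:, None] >= etimes[None, :]
    died = (time[:, None] == etimes[None, :]) & (event[:, None] == 1)
    return etimes, atrisk, died


def _logrank_from_counts(
    n1: np.ndarray, d1: np.ndarray, n: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Chi-square statistic(s) from per-event-time group-1 counts.

    ``n1``/``d1`` may carry a leading candidate axis; ``n``/``d`` are the
    per-time totals.  Times with a single subject at risk contribute no
    variance.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = d * n1 / n
        var = d * (n1 / n) * (1.0 - n1 / n) * (n - d) / np.maximum(n - 1.0, 1.0)
        var = np.where(n > 1, var, 0.0)
    o_minus_e = (d1 - expected).sum(axis=-1)
    v = var.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(v > 0, o_minus_e**2 / v, 0.0)
    return stat


def logrank_statistic(
    cohort: SurvivalCohort, high_mask: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value."""
    high_mask = np.asarray(high_mask, dtype=bool)
    if len(high_mask) != len(cohort):
        raise ValidationError("mask length must match cohort size")
    if high_mask.all() or not high_mask.any():
        raise ValidationError("both groups must be non-empty")
    if cohort.event.sum() == 0:
        logger.warning("no events in cohort: log-rank p set to 1")
        return 0.0, 1.0
    _, atrisk, died = _event_time_counts(cohort.time, cohort.event)
    n = atrisk.sum(axis=0).astype(float)
    d = died.sum(axis=0).astype(float)
    n1 = atrisk[high_mask].sum(axis=0).astype(float)
    d1 = died[high_mask].sum(axis=0).astype(float)
    stat = float(_logrank_from_counts(n1, d1, n, d))
    return stat, float(stats.chi2.sf(stat, df=1))


def km_estimate(cohort: SurvivalCohort, mask: np.ndarray | None = None) -> pd.DataFrame:
    """Product-limit survival estimate for the masked subgroup.

    Returns one row per distinct observed time with columns
    ``time, n_risk, n_event, n_censored, survival``.  The curve starts at
    S(0) = 1, is non-increasing, and drops only at event times.
    """
    if mask is None:
        mask = np.ones(len(cohort), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    time = cohort.time[mask]
    event = cohort.event[mask]
    if len(time) == 0:
        raise ValidationError("empty group")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    utimes, first = np.unique(time, return_index=True)
    n = len(time)
    rows = []
    surv = 1.0
    for t in utimes:
        at = time == t
        n_risk = int((time >= t).sum())
        n_event = int(event[at].sum())
        n_cens = int((~event[at].astype(bool)).sum())
        if n_event:
            surv *= 1.0 - n_event / n_risk
        rows.append((t, n_risk, n_event, n_cens, surv))
    return pd.DataFrame(
        rows, columns=["time", "n_risk", "n_event", "n_censored", "survival"]
    )


@dataclass
class CutpointResult:
    cutoff: float
    logrank_stat: float
    p_value: float  # naive, selection-biased (see corrected_cutpoint_p)
    n_high: int
    n_low: int
    selection_trace: list[tuple[float, float]]  # (candidate cutoff, statistic)


def _candidate_splits(
    marker: np.ndarray, min_prop: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted subject order, candidate cutoffs, and low-group sizes.

    Candidates are midpoints between consecutive distinct marker values
    whose induced split keeps both arms at proportion >= ``min_prop``.
    """
    order = np.argsort(marker, kind="stable")
    sorted_m = marker[order]
    distinct = np.unique(sorted_m)
    if len(distinct) < 2:
        raise ValidationError("no candidate cutpoints: marker is constant")
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    # low-group size for each midpoint = #subjects with marker <= distinct[k]
    m_low = np.searchsorted(sorted_m, distinct[:-1], side="right")
    n = len(marker)
    lo = min_prop * n
    ok = (m_low >= lo) & ((n - m_low) >= lo)
    if not ok.any():
        raise ValidationError("no candidate cutpoints satisfy min_prop")
    return order, mids[ok], m_low[ok]


def _scan_statistics(
    time: np.ndarray, event: np.ndarray, order: np.ndarray, m_low: np.ndarray
) -> np.ndarray:
    """Log-rank statistic for every candidate split in one vectorized pass.

    ``order`` sorts subjects by marker; split ``m`` puts sorted positions
    >= m in the high group.  Suffix cumulative sums over sorted subjects
    give every split's per-time at-risk/event counts at once.
    """
    _, atrisk, died = _event_time_counts(time, event)
    atrisk_sorted = atrisk[order].astype(float)
    died_sorted = died[order].astype(float)
    # suffix[m, t] = count over sorted positions >= m
    suffix_risk = np.cumsum(atrisk_sorted[::-1], axis=0)[::-1]
    suffix_died = np.cumsum(died_sorted[::-1], axis=0)[::-1]
    n = suffix_risk[0]
    d = suffix_died[0]
    n1 = suffix_risk[m_low]  # (C, T): high-group at-risk per candidate
    d1 = suffix_died[m_low]
    return _logrank_from_counts(n1, d1, n[None, :], d[None, :])


def best_cutpoint(cohort: SurvivalCohort, min_prop: float = 0.1) -> CutpointResult:
    """Marker cutoff maximizing the two-group log-rank statistic.

    Ties are broken toward the candidate nearest the marker median.  The
    reported p-value is the naive chi-square tail at the optimum and is
    anti-conservative by construction.
    """
    if not 0.0 <= min_prop < 0.5:
        raise ValidationError("min_prop must lie in [0, 0.5)")
    order, candidates, m_low = _candidate_splits(cohort.marker, min_prop)
    if cohort.event.sum() == 0:
        logger.warning("no events: every candidate statistic is 0")
    stats_arr = _scan_statistics(cohort.time, cohort.event, order, m_low)
    best = stats_arr.max()
    tied = np.flatnonzero(np.isclose(stats_arr, best))
    median = float(np.median(cohort.marker))
    pick = tied[np.argmin(np.abs(candidates[tied] - median))]
    cutoff = float(candidates[pick])
    stat = float(stats_arr[pick])
    n = len(cohort)
    n_low = int(m_low[pick])
    p = float(stats.chi2.sf(stat, df=1)) if cohort.event.sum() > 0 else 1.0
    return CutpointResult(
        cutoff=cutoff,
        logrank_stat=stat,
        p_value=p,
        n_high=n - n_low,
        n_low=n_low,
        selection_trace=list(zip(candidates.tolist(), stats_arr.tolist())),
    )


def corrected_cutpoint_p(
    cohort: SurvivalCohort,
    n_permutations: int = 1000,
    seed: int = 0,
    min_prop: float = 0.1,
) -> float:
    """Selection-bias-corrected p for the best cutoff via a permutation null.

    Shuffles the marker against (time, event), re-runs the full scan, and
    reports the rank of the observed maximal statistic among the permuted
    maxima: ``(1 + #{perm >= obs}) / (n_permutations + 1)``.
    """
    if n_permutations < 100:
        logger.warning("n_permutations < 100 gives a coarse adjusted p")
    order, _, m_low = _candidate_splits(cohort.marker, min_prop=min_prop)
    observed = best_cutpoint(cohort, min_prop=min_prop).logrank_stat
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(cohort))
        stats_arr = _scan_statistics(
            cohort.time[perm], cohort.event[perm], order, m_low
        )
        if stats_arr.max() >= observed:
            n_ge += 1
    return (1 + n_ge) / (n_permutations + 1)
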