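"""Differential screening: group fold change, significance test, up/down call.

Fold change is the ratio of group means of protein relative values,
treated over control.  Significance defaults to a two-sided Welch t-test
on log2 values; a rank-sum alternative is available.  A protein is
called up when fc strictly exceeds the threshold and p <= alpha, down
when fc falls strictly below the reciprocal threshold and p <= alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .tables import ProteinTable

logger = logging.getLogger(__name__)

UP, DOWN, NS = "up", "down", "ns"

TEST_WELCH = "welch_t_log2"
TEST_WILCOXON = "wilcoxon"


@dataclass(frozen=True)
class ScreenConfig:
    fc_threshold: float = 1.3
    alpha: float = 0.05
    test: str = TEST_WELCH
    adjust_bh: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1.0:
            raise ConfigError("fc_threshold must be > 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.test not in (TEST_WELCH, TEST_WILCOXON):
            raise ConfigError(f"unknown test '{self.test}'")


def _group_arrays(
    table: ProteinTable, numerator: str, denominator: str
) -> tuple[np.ndarray, np.ndarray]:
    num_cols = table.samples_in_group(numerator)
    den_cols = table.samples_in_group(denominator)
    if not num_cols or not den_cols:
        raise ValidationError(
            f"groups '{numerator}' / '{denominator}' not found among samples"
        )
    return (
        table.values[num_cols].to_numpy(float),
        table.values[den_cols].to_numpy(float),
    )


def compute_fold_change(
    table: ProteinTable, numerator: str, denominator: str
) -> pd.Series:
    """mean(numerator group) / mean(denominator group), over observed values.

    Proteins with zero observed values in either group come back NaN and
    are logged as incalculable.
    """
    a, b = _group_arrays(table, numerator, denominator)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        fc = np.nanmean(a, axis=1) / np.nanmean(b, axis=1)
    bad = ~np.isfinite(fc)
    if bad.any():
        logger.warning(
            "%d proteins incalculable (a group with no observed values)",
            int(bad.sum()),
        )
        fc = np.where(bad, np.nan, fc)
    return pd.Series(fc, index=table.values.index, name="fc")


def _welch_t_log2(a: np.ndarray, b: np.ndarray) -> float:
    # degenerate-variance conventions: equal constant groups -> 1,
    # different constants -> 0 (infinite evidence in the noise-free limit)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if np.isclose(a[0], b[0]):
            return 1.0
        logger.warning("zero variance with unequal means: p set to 0")
        return 0.0
    res = stats.ttest_ind(np.log2(a), np.log2(b), equal_var=False)
    return float(res.pvalue)


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue)


def test_significance(
    table: ProteinTable,
    numerator: str,
    denominator: str,
    config: ScreenConfig | None = None,
) -> pd.Series:
    """Two-sided per-protein p-value for a group difference.

    Proteins with fewer than 2 observations in either group get NaN and
    are flagged in the log.
    """
    config = config or ScreenConfig()
    a_mat, b_mat = _group_arrays(table, numerator, denominator)
    testfun = _welch_t_log2 if config.test == TEST_WELCH else _wilcoxon
    pvals = np.full(len(a_mat), np.nan)
    n_flagged = 0
    for i in range(len(a_mat)):
        a = a_mat[i][np.isfinite(a_mat[i])]
        b = b_mat[i][np.isfinite(b_mat[i])]
        if len(a) < 2 or len(b) < 2:
            n_flagged += 1
            continue
        pvals[i] = testfun(a, b)
    if n_flagged:
        logger.warning("%d proteins with < 2 observations per group: p undefined", n_flagged)
    return pd.Series(pvals, index=table.values.index, name="p_value")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    ps = p[ok]
    m = len(ps)
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    adj[ok] = out
    return adj


def classify_proteins(
    fc: pd.Series, p: pd.Series, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Joint fold-change/significance call per protein, plus volcano columns."""
    config = config or ScreenConfig()
    fc_arr = fc.to_numpy(float)
    p_arr = p.reindex(fc.index).to_numpy(float)
    if config.adjust_bh:
        p_arr = _bh_adjust(p_arr)
    sig = p_arr <= config.alpha
    call = np.where(
        sig & (fc_arr > config.fc_threshold),
        UP,
        np.where(sig & (fc_arr < 1.0 / config.fc_threshold), DOWN, NS),
    )
    call[~np.isfinite(fc_arr) | ~np.isfinite(p_arr)] = NS
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(fc_arr)
        neglog10p = -np.log10(p_arr)
    return pd.DataFrame(
        {
            "fc": fc_arr,
            "log2fc": log2fc,
            "p_value": p_arr,
            "neg_log10_p": neglog10p,
            "call": call,
        },
        index=fc.index,
    )


def summarize_calls(result: pd.DataFrame) -> dict[str, int]:
    counts = result["call"].value_counts()
    return {
        "n_up": int(counts.get(UP, 0)),
        "n_down": int(counts.get(DOWN, 0)),
        "n_ns": int(counts.get(NS, 0)),
    }


def screen(
    table: ProteinTable,
    numerator: str,
    denominator: str,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Full screening chain: fold change + significance + classification."""
    config = config or ScreenConfig()
    fc = compute_fold_change(table, numerator, denominator)
    p = test_significance(table, numerator, denominator, config)
    return classify_proteins(fc, p, config)
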