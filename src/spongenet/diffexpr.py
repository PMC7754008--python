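"""Normalization, differential screening, and the qPCR fold-change utility.

Normalization follows the median-of-ratios estimator: each sample's size
factor is the median, over features with all-positive counts, of the ratio
of that feature's count to its geometric mean across samples.  ``baseMean``
is the mean of the size-factor-normalized counts for a feature.

The per-feature test is a Welch t-test on log2(normalized + 1) — a
deterministic, dependency-free choice adequate for the screening rule it
feeds, which calls a feature up (down) when log2 fold change >= +1 (<= -1)
at raw p < 0.05.  The boundary is inclusive on the fold change and strict
on the p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, SampleSheet
from .sponge import bh_adjust

logger = logging.getLogger(__name__)

_ZERO_VAR_SENTINEL_P = 1e-300


class EstimationError(ValueError):
    """Raised when size factors cannot be estimated."""


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Only features with strictly positive counts in every sample enter the
    median (the geometric-mean reference is undefined otherwise).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    values = df.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise EstimationError(
            "no feature has all-positive counts; size factors are undefined "
            "(supply deeper libraries or pre-filter empty features)"
        )
    logs = np.log(values[positive])
    log_geo_mean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo_mean, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalized_counts(counts: CountMatrix | pd.DataFrame,
                      factors: pd.Series | None = None) -> pd.DataFrame:
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = size_factors(df)
    if len(factors) != df.shape[1]:
        raise ValueError("one size factor per sample required")
    return df / factors


def base_means(counts: CountMatrix | pd.DataFrame, factors: pd.Series) -> pd.Series:
    """baseMean: mean over samples of count / size factor."""
    norm = normalized_counts(counts, factors)
    return norm.mean(axis=1).rename("base_mean")


def log2_expression(counts: CountMatrix | pd.DataFrame,
                    factors: pd.Series | None = None,
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(normalized count + pseudocount), the expression scale used by
    every correlation downstream."""
    return np.log2(normalized_counts(counts, factors) + pseudocount)


def log2_fold_change(norm_case_mean: float, norm_ctrl_mean: float,
                     pseudocount: float = 1.0) -> float:
    if norm_case_mean < 0 or norm_ctrl_mean < 0:
        raise ValueError("normalized means must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((norm_case_mean + pseudocount) / (norm_ctrl_mean + pseudocount)))


def de_test(norm_counts_case: np.ndarray, norm_counts_ctrl: np.ndarray) -> float:
    """Two-sided Welch t-test on log2(normalized + 1) for one feature."""
    case = np.log2(np.asarray(norm_counts_case, dtype=float) + 1.0)
    ctrl = np.log2(np.asarray(norm_counts_ctrl, dtype=float) + 1.0)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("need at least 2 samples per group")
    if case.std() == 0 and ctrl.std() == 0:
        if case.mean() == ctrl.mean():
            return 1.0
        warnings.warn(
            "zero variance in both groups with unequal means; "
            "returning sentinel p", stacklevel=2,
        )
        return _ZERO_VAR_SENTINEL_P
    p = stats.ttest_ind(case, ctrl, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


def run_de(
    counts: CountMatrix,
    samples: SampleSheet,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full differential table for one RNA class (PP vs normal).

    Positive log2 fold changes mean higher expression in the PP group.
    Returns a DataFrame indexed by feature id with columns base_mean,
    log2fc, p_value, adj_p, call.
    """
    factors = size_factors(counts)
    norm = normalized_counts(counts, factors)
    case_ids = [s for s in counts.sample_ids if s in set(samples.case_ids)]
    ctrl_ids = [s for s in counts.sample_ids if s in set(samples.control_ids)]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need at least 2 samples per group for testing")

    case = norm[case_ids].to_numpy()
    ctrl = norm[ctrl_ids].to_numpy()
    bm = norm.mean(axis=1)
    lfc = np.log2((case.mean(axis=1) + pseudocount) / (ctrl.mean(axis=1) + pseudocount))

    log_case = np.log2(case + 1.0)
    log_ctrl = np.log2(ctrl + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(log_case, log_ctrl, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate features: both groups constant
    both_const = (log_case.std(axis=1) == 0) & (log_ctrl.std(axis=1) == 0)
    equal_means = np.isclose(log_case.mean(axis=1), log_ctrl.mean(axis=1))
    p = np.where(both_const & equal_means, 1.0, p)
    if (both_const & ~equal_means).any():
        warnings.warn("zero-variance features with unequal means; sentinel p used",
                      stacklevel=2)
        p = np.where(both_const & ~equal_means, _ZERO_VAR_SENTINEL_P, p)
    p = np.where(np.isfinite(p), p, 1.0)
    p = np.clip(p, _ZERO_VAR_SENTINEL_P, 1.0)

    table = pd.DataFrame(
        {"base_mean": bm, "log2fc": lfc, "p_value": p},
        index=counts.counts.index,
    )
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
    table["call"] = screen_de(table, lfc_threshold, p_threshold)
    n_up = int((table["call"] == "up").sum())
    n_down = int((table["call"] == "down").sum())
    logger.info("DE %s: %d features, %d up / %d down at |lfc|>=%g, p<%g",
                counts.rna_class, len(table), n_up, n_down, lfc_threshold, p_threshold)
    return table


def screen_de(table: pd.DataFrame, lfc_threshold: float = 1.0,
              p_threshold: float = 0.05) -> pd.Series:
    """Up/down/ns calls: |log2fc| >= threshold (inclusive) AND p < threshold
    (strict)."""
    sig = table["p_value"] < p_threshold
    call = np.where(sig & (table["log2fc"] >= lfc_threshold), "up",
                    np.where(sig & (table["log2fc"] <= -lfc_threshold), "down", "ns"))
    return pd.Series(call, index=table.index, name="call")


@dataclass(frozen=True)
class QPCRMeasurement:
    """Cycle-threshold quartet for one target/reference, case/control."""

    ct_target_case: float
    ct_ref_case: float
    ct_target_ctrl: float
    ct_ref_ctrl: float


def ddct_fold_change(m: QPCRMeasurement) -> float:
    """Relative expression by the 2^-ddCt method."""
    cts = (m.ct_target_case, m.ct_ref_case, m.ct_target_ctrl, m.ct_ref_ctrl)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    ddct = (m.ct_target_case - m.ct_ref_case) - (m.ct_target_ctrl - m.ct_ref_ctrl)
    return float(2.0 ** (-ddct))
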