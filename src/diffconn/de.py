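"""Differential expression: log2 fold change, Student's t-test, BH FDR,
and the joint DEG filter (P < 0.05, FDR < 0.05, |log2FC| > 1).

Fold changes are mean differences on log2-scale data (RMA-style input is
already log2), not ratios of antilogs.  The t-test is the pooled-variance
Student's test by default, with Welch behind a flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NOT_SIGNIFICANT = "not_significant"


def _condition_blocks(
    em: ExpressionMatrix, cond_a: str, cond_b: str
) -> tuple[np.ndarray, np.ndarray]:
    a = em.values[em.samples_of(cond_a)].to_numpy()
    b = em.values[em.samples_of(cond_b)].to_numpy()
    return a, b


def log2_fold_change(em: ExpressionMatrix, cond_a: str, cond_b: str) -> pd.Series:
    """Per-feature log2FC = mean(cond_b) − mean(cond_a) on log2 data."""
    a, b = _condition_blocks(em, cond_a, cond_b)
    return pd.Series(b.mean(axis=1) - a.mean(axis=1), index=em.values.index, name="log2fc")


def two_sample_ttest(
    em: ExpressionMatrix, cond_a: str, cond_b: str, equal_var: bool = True
) -> pd.Series:
    """Two-sided two-sample t-test p-value per feature.

    Zero pooled variance yields p = 1 when the group means are equal and
    p = 0 (with a logged warning) when they differ — the test statistic is
    degenerate either way.
    """
    a, b = _condition_blocks(em, cond_a, cond_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each condition needs at least 2 samples for a t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        mean_diff = b.mean(axis=1) - a.mean(axis=1)
        equal_means = np.isclose(mean_diff, 0.0)
        p[degenerate & equal_means] = 1.0
        n_sep = int((degenerate & ~equal_means).sum())
        p[degenerate & ~equal_means] = 0.0
        if n_sep:
            logger.warning(
                "%d feature(s) had zero within-group variance with unequal "
                "means; p set to 0",
                n_sep,
            )
    return pd.Series(p, index=em.values.index, name="p_value")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        bad = np.argwhere(~((p >= 0) & (p <= 1)))[0]
        raise ValueError(f"p-value out of [0, 1] at position {int(bad[0])}")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def deg_table(
    em: ExpressionMatrix, cond_a: str, cond_b: str, equal_var: bool = True
) -> pd.DataFrame:
    """Per-feature statistics: log2fc, abs_log2fc, p_value, fdr."""
    lfc = log2_fold_change(em, cond_a, cond_b)
    p = two_sample_ttest(em, cond_a, cond_b, equal_var=equal_var)
    return pd.DataFrame(
        {
            "feature_id": em.values.index,
            "feature_type": em.feature_type_of.to_numpy(),
            "log2fc": lfc.to_numpy(),
            "abs_log2fc": np.abs(lfc.to_numpy()),
            "p_value": p.to_numpy(),
            "fdr": benjamini_hochberg(p.to_numpy()),
        }
    )


def call_degs(
    records: pd.DataFrame,
    p_max: float = 0.05,
    fdr_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> tuple[list[str], list[str]]:
    """Partition features into (up, down) DEG lists with strict thresholds.

    A feature is up iff p < p_max AND fdr < fdr_max AND log2fc >
    min_abs_log2fc; down iff the same with log2fc < −min_abs_log2fc.
    """
    sig = (records["p_value"] < p_max) & (records["fdr"] < fdr_max)
    up = records.loc[sig & (records["log2fc"] > min_abs_log2fc), "feature_id"]
    down = records.loc[sig & (records["log2fc"] < -min_abs_log2fc), "feature_id"]
    return list(up), list(down)


def classify_degs(
    records: pd.DataFrame,
    p_max: float = 0.05,
    fdr_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Return ``records`` with a ``direction`` column (up/down/not_significant)."""
    up, down = call_degs(records, p_max, fdr_max, min_abs_log2fc)
    direction = np.where(
        records["feature_id"].isin(up),
        UP,
        np.where(records["feature_id"].isin(down), DOWN, NOT_SIGNIFICANT),
    )
    out = records.copy()
    out["direction"] = direction
    return out
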