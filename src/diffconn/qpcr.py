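"""Validation arithmetic: relative qPCR quantification (2^−ΔΔCt),
dual-luciferase normalization, and simple group comparisons.

ΔΔCt referencing uses the control group's *mean* ΔCt, so the control
group's mean log2 fold change is 0 (geometric-mean fold change 1) by
construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def ddct_fold_change(records: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-sample ΔCt, ΔΔCt and 2^−ΔΔCt fold change vs a control group.

    ``records`` needs columns sample_id, group, ct_target, ct_reference.
    ΔCt = ct_target − ct_reference; ΔΔCt = ΔCt − mean(ΔCt of control);
    fold_change = 2^−ΔΔCt.
    """
    required = {"sample_id", "group", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing column {sorted(missing)[0]!r}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        bad = records.loc[
            records[["ct_target", "ct_reference"]].isna().any(axis=1), "sample_id"
        ].iloc[0]
        raise ValueError(f"missing Ct value for sample {bad!r}")
    out = records.copy()
    out["delta_ct"] = out["ct_target"] - out["ct_reference"]
    control = out.loc[out["group"] == control_group, "delta_ct"]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no records")
    out["ddct"] = out["delta_ct"] - control.mean()
    out["fold_change"] = np.power(2.0, -out["ddct"])
    return out


def ddct_group_summary(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD fold change per group from a :func:`ddct_fold_change` table."""
    g = folds.groupby("group")["fold_change"]
    return g.agg(mean_fold_change="mean", sd_fold_change="std", n="size").reset_index()


def luciferase_relative_activity(
    records: pd.DataFrame, control_group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Firefly/Renilla ratios normalized to a control group's mean ratio.

    ``records`` needs columns well_id, group, firefly, renilla
    (renilla > 0).  Returns (per-well table, per-group mean ± SD summary);
    the control group's mean relative activity is 1 by construction.
    """
    required = {"well_id", "group", "firefly", "renilla"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing column {sorted(missing)[0]!r}")
    if (records["renilla"] <= 0).any():
        bad = records.loc[records["renilla"] <= 0, "well_id"].iloc[0]
        raise ValueError(f"non-positive Renilla signal in well {bad!r}")
    out = records.copy()
    out["ratio"] = out["firefly"] / out["renilla"]
    control = out.loc[out["group"] == control_group, "ratio"]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no records")
    out["relative_activity"] = out["ratio"] / control.mean()
    g = out.groupby("group")["relative_activity"]
    summary = g.agg(mean_activity="mean", sd_activity="std", n="size").reset_index()
    return out, summary


def group_compare(values_by_group: dict[str, "np.ndarray | list[float]"], test: str = "auto"):
    """Two groups → two-tailed pooled t-test; more → one-way ANOVA.

    Returns (statistic, p_value).  Identical constant groups give a
    degenerate statistic; the p-value is reported as 1.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 values per group")
    if test == "auto":
        test = "ttest" if len(groups) == 2 else "anova"
    if test == "ttest":
        if len(groups) != 2:
            raise ValueError("t-test needs exactly 2 groups")
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
    elif test == "anova":
        stat, p = stats.f_oneway(*groups)
    else:
        raise ValueError(f"unknown test {test!r}")
    stat = float(stat)
    p = float(p)
    if not np.isfinite(p):
        means = [g.mean() for g in groups]
        p = 1.0 if np.allclose(means, means[0]) else 0.0
        stat = 0.0 if p == 1.0 else np.inf
    return stat, p
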