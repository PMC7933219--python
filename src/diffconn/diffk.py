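"""The normalized differential-connectivity statistic |Diffk|.

For a feature with degree k_A in the condition-A network (maximum degree
kmax_A) and degree k_B in the condition-B network (maximum degree kmax_B),

    |Diffk| = | k_A / kmax_A  −  k_B / kmax_B |

Large values flag "rewired hubs": features that are highly connected in
one condition and lose (or gain) that connectivity in the other.  The
per-network max-degree normalization is the unique simple rule consistent
with the published 10-row EC / TC-EC reference table this module also
validates against (see :func:`infer_normalizers`), and both normalizing
constants are always carried in the output rather than hidden.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .coexpr import CoexpressionNetwork


def round3(x: float) -> float:
    """Round to 3 decimals, half-up (the convention of the printed tables)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def diffk(k_a: int, kmax_a: int, k_b: int, kmax_b: int) -> float:
    """|k_a/kmax_a − k_b/kmax_b| for one feature.

    Both kmax values must be >= 1 and bound their degrees.
    """
    for k, kmax, side in ((k_a, kmax_a, "a"), (k_b, kmax_b, "b")):
        if kmax < 1:
            raise ValueError(f"kmax_{side} must be >= 1")
        if not 0 <= k <= kmax:
            raise ValueError(f"k_{side}={k} outside [0, kmax_{side}={kmax}]")
    return abs(k_a / kmax_a - k_b / kmax_b)


def diffk_table(
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    feature_types: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """|Diffk| record for every feature in the union of the two node sets.

    A feature absent from one network has degree 0 there (absence means no
    retained edges).  kmax is taken per network over its own nodes; an
    edgeless network contributes normalized degrees of 0.
    """
    nodes_a = set(net_a.graph.nodes)
    nodes_b = set(net_b.graph.nodes)
    if not nodes_a and not nodes_b:
        raise ValueError("both networks are empty")
    kmax_a = net_a.max_degree
    kmax_b = net_b.max_degree
    rows = []
    for f in sorted(nodes_a | nodes_b):
        k_a = net_a.degree_of(f)
        k_b = net_b.degree_of(f)
        norm_a = k_a / kmax_a if kmax_a else 0.0
        norm_b = k_b / kmax_b if kmax_b else 0.0
        rows.append(
            {
                "feature_id": f,
                "feature_type": feature_types.get(f, "coding") if feature_types else "coding",
                "k_a": k_a,
                "k_b": k_b,
                "kmax_a": kmax_a,
                "kmax_b": kmax_b,
                "diffk": abs(norm_a - norm_b),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "feature_type", "k_a", "k_b", "kmax_a", "kmax_b", "diffk"],
    )


def rank_diffk(records: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Top features by |Diffk|, descending, with a deterministic tie rule.

    Ties are broken by larger raw degree difference |k_a − k_b|, then by
    feature id.  A ``rank`` column (1-based) is added.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    df = records.copy()
    df["_abs_dk"] = (df["k_a"] - df["k_b"]).abs()
    df = df.sort_values(
        ["diffk", "_abs_dk", "feature_id"], ascending=[False, False, True]
    ).drop(columns="_abs_dk")
    df = df.head(top_n).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


class NormalizerFit(NamedTuple):
    kmax_a: int
    kmax_b: int
    max_abs_error: float
    unique: bool


def infer_normalizers(
    rows: Sequence[tuple[int, int, float]], kmax_bound: int = 100
) -> NormalizerFit:
    """Recover the per-network max-degree normalizers from printed values.

    Exhaustively searches integer pairs (kmax_a, kmax_b) with
    kmax_a >= max(k_a), kmax_b >= max(k_b) up to ``kmax_bound``, minimizing
    the maximum |computed − printed| over the rows (printed values carry 3
    decimals).  Returns the arg-min pair (smallest pair on ties), its
    error, and whether the fit is unique at the printed precision
    (max error <= 0.0005); a single row is never unique.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("infer_normalizers needs at least one row")
    k_a = np.array([r[0] for r in rows], dtype=float)
    k_b = np.array([r[1] for r in rows], dtype=float)
    printed = np.array([r[2] for r in rows], dtype=float)
    lo_a = max(int(k_a.max()), 1)
    lo_b = max(int(k_b.max()), 1)
    if kmax_bound < max(lo_a, lo_b):
        raise ValueError("kmax_bound below the largest observed degree")
    ka_cand = np.arange(lo_a, kmax_bound + 1)
    kb_cand = np.arange(lo_b, kmax_bound + 1)
    # err[i, j] = max over rows of |k_a/Ka_i − k_b/Kb_j − printed|
    norm_a = k_a[None, :] / ka_cand[:, None]          # (A, rows)
    norm_b = k_b[None, :] / kb_cand[:, None]          # (B, rows)
    diff = np.abs(norm_a[:, None, :] - norm_b[None, :, :])
    err = np.abs(diff - printed[None, None, :]).max(axis=2)
    best = np.unravel_index(np.argmin(err), err.shape)  # row-major: smallest pair on ties
    max_abs_error = float(err[best])
    n_consistent = int((err <= 5e-4).sum())
    unique = len(rows) >= 2 and n_consistent == 1
    return NormalizerFit(int(ka_cand[best[0]]), int(kb_cand[best[1]]), max_abs_error, unique)
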