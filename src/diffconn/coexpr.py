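"""Per-condition co-expression networks.

An edge connects two features whose within-condition expression
correlation magnitude reaches the build threshold (default |r| >= 0.8,
Pearson).  Degrees are counts of distinct neighbors; normalized degrees
divide by the network's maximum degree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def correlation_matrix(
    em: ExpressionMatrix,
    condition: str,
    method: str = "pearson",
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Symmetric pairwise correlation of features within one condition.

    Zero-variance features get undefined (NaN) off-diagonal correlations
    and never form edges.  With fewer than 3 samples every correlation is
    degenerate (|r| = 1); the function warns loudly and proceeds.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    sub = em if features is None else em.subset_features(features)
    samples = sub.samples_of(condition)
    X = sub.values[samples].to_numpy(dtype=float)
    if X.shape[1] < 3:
        warnings.warn(
            f"condition {condition!r} has only {X.shape[1]} samples: all "
            "correlations are degenerate (|r| = 1); results are not meaningful",
            stacklevel=2,
        )
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
    sd = X.std(axis=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(X)
    C = np.clip(C, -1.0, 1.0)
    C[zero_var, :] = np.nan
    C[:, zero_var] = np.nan
    np.fill_diagonal(C, 1.0)
    ids = sub.values.index
    return pd.DataFrame(C, index=ids, columns=ids)


@dataclass
class CoexpressionNetwork:
    """Undirected correlation network for one condition.

    Nodes are all features the correlation matrix covered (including
    degree-0 ones); each edge carries its correlation ``r`` and satisfies
    |r| >= ``threshold``.
    """

    condition: str
    graph: nx.Graph
    threshold: float
    method: str = "pearson"

    @property
    def max_degree(self) -> int:
        degrees = [d for _, d in self.graph.degree]
        return max(degrees, default=0)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_of(self, feature_id: str) -> int:
        return self.graph.degree(feature_id) if feature_id in self.graph else 0


def build_network(
    corr: pd.DataFrame,
    threshold_abs_r: float,
    condition: str = "",
    method: str = "pearson",
) -> CoexpressionNetwork:
    """Threshold a correlation matrix into a network: edge iff |r| >= threshold.

    Undefined (NaN) correlations never create edges.
    """
    if not 0.0 < threshold_abs_r <= 1.0:
        raise ValueError("threshold_abs_r must be in (0, 1]")
    C = corr.to_numpy(dtype=float)
    ids = list(corr.index)
    G = nx.Graph()
    G.add_nodes_from(ids)
    with np.errstate(invalid="ignore"):
        mask = np.abs(C) >= threshold_abs_r
    mask &= np.isfinite(C)
    mask &= np.triu(np.ones_like(mask, dtype=bool), k=1)
    for i, j in np.argwhere(mask):
        G.add_edge(ids[i], ids[j], r=float(C[i, j]))
    return CoexpressionNetwork(condition, G, threshold_abs_r, method)


def condition_network(
    em: ExpressionMatrix,
    condition: str,
    threshold_abs_r: float = 0.8,
    method: str = "pearson",
    features: list[str] | None = None,
) -> CoexpressionNetwork:
    """Convenience: correlation_matrix + build_network for one condition."""
    corr = correlation_matrix(em, condition, method=method, features=features)
    return build_network(corr, threshold_abs_r, condition=condition, method=method)


def node_degrees(network: CoexpressionNetwork) -> pd.DataFrame:
    """Degree and max-degree-normalized degree per node.

    Normalized degree is k / max_degree, 0 for every node of an edgeless
    network.
    """
    kmax = network.max_degree
    rows = [
        {
            "feature_id": n,
            "degree": d,
            "normalized_degree": (d / kmax) if kmax else 0.0,
        }
        for n, d in network.graph.degree
    ]
    return pd.DataFrame(rows, columns=["feature_id", "degree", "normalized_degree"])
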