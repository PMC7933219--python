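"""Independent brute-force / closed-form oracles used by the test suite.

Every function here deliberately avoids the code path it checks: the BH
oracle applies the step-up rule directly, betweenness enumerates all
simple shortest paths, the seed-site oracle matches explicit regex
patterns, the t-test oracle evaluates the closed-form statistic through
the incomplete beta function, and the hypergeometric oracle sums
binomial-coefficient terms.
"""

from __future__ import annotations

import math
import re
from itertools import combinations

import numpy as np
from scipy import special


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini–Hochberg q-values by the literal step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):  # from largest p down
        idx = order[rank - 1]
        running_min = min(running_min, m * p[idx] / rank)
        q_sorted[rank - 1] = running_min
    q = np.empty(m)
    q[order] = q_sorted
    return q


def brute_force_betweenness(nodes, edges, normalized: bool = True) -> dict:
    """Betweenness by enumerating every simple path between every pair."""
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_simple_paths(s, t):
        paths = []

        def dfs(path):
            cur = path[-1]
            if cur == t:
                paths.append(list(path))
                return
            for nxt in adj[cur]:
                if nxt not in path:
                    path.append(nxt)
                    dfs(path)
                    path.pop()

        dfs([s])
        return paths

    bc = {n: 0.0 for n in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_simple_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sps = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in sps if v in p)
            bc[v] += through / len(sps)
    n = len(nodes)
    if normalized and n > 2:
        scale = (n - 1) * (n - 2) / 2
        bc = {v: x / scale for v, x in bc.items()}
    return bc


_RC = {"A": "U", "C": "G", "G": "C", "U": "A"}


def _rc_rna(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq.upper().replace("T", "U")))


def naive_seed_scan(mirna_seq: str, utr_seq: str):
    """Seed sites by explicit regex pattern matching per site type.

    Returns (start, end, type) tuples, 1-based inclusive, one site per
    seed-hexamer locus with longer types suppressing shorter ones.
    """
    mir = mirna_seq.upper().replace("T", "U")
    utr = utr_seq.upper().replace("T", "U")
    site7 = _rc_rna(mir[1:8])
    hex6 = _rc_rna(mir[1:7])
    assert site7[1:] == hex6

    def occurrences(pattern):
        return {m.start(1) for m in re.finditer(f"(?=({re.escape(pattern)}))", utr)}

    occ8 = occurrences(site7 + "A")
    occ7m8 = occurrences(site7)
    occ7a1 = occurrences(hex6 + "A")
    occ6 = occurrences(hex6)

    out = []
    for i in sorted(occ6):  # i = 0-based hexamer start = locus
        if i - 1 in occ8:
            out.append((i, i + 7, "8mer"))
        elif i - 1 in occ7m8:
            out.append((i, i + 6, "7mer-m8"))
        elif i in occ7a1:
            out.append((i + 1, i + 7, "7mer-A1"))
        else:
            out.append((i + 1, i + 6, "6mer"))
    return out


def student_t_pvalue(a, b) -> float:
    """Two-sided pooled-variance t-test p via the incomplete beta function."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return float(special.betainc(df / 2, 0.5, df / (df + t * t)))


def hypergeom_upper_tail(M: int, n: int, N: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe M, set n, draws N), by comb sums."""
    total = math.comb(M, N)
    acc = 0
    for x in range(k, min(n, N) + 1):
        if N - x <= M - n:
            acc += math.comb(n, x) * math.comb(M - n, N - x)
    return acc / total


def pearson_direct(x, y) -> float:
    """Pearson r straight from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def anova_f_direct(groups) -> float:
    """One-way ANOVA F from explicit between/within sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    return float((ss_between / df_between) / (ss_within / df_within))
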