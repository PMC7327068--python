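"""Pathway over-representation analysis of DEG sets.

A pathway is tested by the one-sided Fisher's exact test (upper tail of the
hypergeometric distribution): with ``N`` genes in the universe, ``K`` of them
in the pathway and ``n`` differential genes, the p-value is the probability
of observing ``k`` or more differential genes inside the pathway by chance.
A pathway is *reported* when p < 0.05 and it contains at least 3 differential
genes; BH-adjusted p-values are emitted alongside but do not enter the
reporting rule. The universe is the set of features actually quantified in
the layer under test, not the genome.
"""

from __future__ import annotations

from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import UniverseError, ValidationError
from .io import PathwaySets

__all__ = ["enrich", "overrepresentation_p", "hypergeom_tail"]

ALPHA = 0.05
MIN_OVERLAP = 3


def overrepresentation_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided Fisher's exact p: P(X >= k) for X ~ Hypergeom(N, K, n)."""
    _check_margins(k, K, n, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _check_margins(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent margins: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValidationError(f"k={k} outside [0, min(K={K}, n={n})]")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability by direct summation.

    Computes sum_{i>=k} C(K,i) C(N-K, n-i) / C(N,n) in log space. This is an
    independent check of :func:`overrepresentation_p`; the two share no code.
    """
    _check_margins(k, K, n, N)

    def log_c(a: int, b: int) -> float:
        return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)

    lo = max(k, n + K - N, 0)
    hi = min(K, n)
    if lo > hi:
        return 0.0
    terms = [
        log_c(K, i) + log_c(N - K, n - i) - log_c(N, n) for i in range(lo, hi + 1)
    ]
    return float(min(1.0, np.exp(logsumexp(terms))))


def enrich(
    deg_set: set[str],
    universe: set[str],
    pathways: PathwaySets,
    alpha: float = ALPHA,
    min_overlap: int = MIN_OVERLAP,
) -> pd.DataFrame:
    """Over-representation of ``deg_set`` in each pathway.

    Pathways are intersected with the universe before counting; pathways with
    no gene in the universe are dropped. A differential gene outside the
    universe is an error (it would silently inflate the background otherwise).

    Returns a DataFrame sorted by p-value with columns
    ``pathway, description, k, K, n, N, p_value, p_bh, reported``.
    """
    deg_set = set(deg_set)
    universe = set(universe)
    stray = deg_set - universe
    if stray:
        raise UniverseError(
            f"{len(stray)} differential gene(s) not in universe, e.g. {sorted(stray)[:5]}"
        )
    N = len(universe)
    n = len(deg_set)

    rows = []
    for name in pathways:
        members = pathways.genes(name) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & deg_set)
        rows.append(
            {
                "pathway": name,
                "description": pathways.descriptions.get(name, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": overrepresentation_p(k, K, n, N),
            }
        )
    out = pd.DataFrame(
        rows, columns=["pathway", "description", "k", "K", "n", "N", "p_value"]
    )
    if len(out):
        out["p_bh"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        out["reported"] = (out["p_value"] < alpha) & (out["k"] >= min_overlap)
        out = out.sort_values(["p_value", "pathway"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        out["p_bh"] = pd.Series(dtype=float)
        out["reported"] = pd.Series(dtype=bool)
    return out
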