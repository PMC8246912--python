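"""Cross-dataset projection scoring and gene-list overlap significance.

After projecting a query dataset (e.g. bone-marrow progenitors) into a
reference PCA space, each reference cell is scored by how frequently it
appears among the k nearest reference neighbors of the query cells — high
scores mark the reference cells most similar to the query population.
Gene-list overlaps are tested with an exact upper-tail hypergeometric test
computed by log-space summation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import gammaln, logsumexp


def knn_frequency_score(
    reference_scores: np.ndarray,
    query_scores: np.ndarray,
    k: int = 10,
    reference_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Frequency with which each reference cell is among the k nearest
    reference neighbors of the query cells (Euclidean in the shared
    component space; ties broken by reference cell id).

    Returns one row per reference cell with the raw neighbor ``count`` and
    the ``score`` normalized by the number of query cells.  Raw counts sum
    to k x n_query.
    """
    R = np.atleast_2d(np.asarray(reference_scores, dtype=float))
    Q = np.atleast_2d(np.asarray(query_scores, dtype=float))
    n_ref, n_query = R.shape[0], Q.shape[0]
    if not 1 <= k <= n_ref:
        raise ValueError(f"k must lie in [1, {n_ref}]")
    if reference_ids is None:
        reference_ids = [f"ref{str(i).zfill(4)}" for i in range(n_ref)]
    id_rank = np.argsort(np.argsort(np.asarray(reference_ids, dtype=object), kind="stable"))

    D = cdist(Q, R)
    counts = np.zeros(n_ref, dtype=int)
    for qi in range(n_query):
        order = np.lexsort((id_rank, D[qi]))
        counts[order[:k]] += 1
    return pd.DataFrame(
        {"reference_cell_id": reference_ids, "count": counts, "score": counts / n_query}
    )


@dataclass
class OverlapResult:
    n_universe: int
    n_list_a: int
    n_list_b: int
    n_overlap: int
    p: float


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_overlap(list_a, list_b, universe) -> OverlapResult:
    """Exact upper-tail hypergeometric test of the overlap of two gene sets.

    p = P(X >= n_overlap) for X hypergeometric with population
    ``n_universe``, ``n_list_b`` successes and ``n_list_a`` draws, summed
    exactly in log space.
    """
    uni = set(universe)
    a, b = set(list_a), set(list_b)
    bad = sorted((a | b) - uni)
    if bad:
        raise ValueError(f"list elements outside the universe: {bad[:10]}")
    M, na, nb = len(uni), len(a), len(b)
    k = len(a & b)

    lo = max(0, na + nb - M)
    hi = min(na, nb)
    if k <= lo:
        p = 1.0
    else:
        terms = [
            _log_comb(nb, i) + _log_comb(M - nb, na - i) - _log_comb(M, na)
            for i in range(k, hi + 1)
        ]
        p = float(min(np.exp(logsumexp(terms)), 1.0))
    return OverlapResult(n_universe=M, n_list_a=na, n_list_b=nb, n_overlap=k, p=p)


def expression_universe(values: np.ndarray, gene_ids: list[str]) -> set[str]:
    """Genes expressed (nonzero in at least one cell) in a matrix — the
    default universe for overlap tests."""
    expressed = np.asarray(values).sum(axis=1) > 0
    return {g for g, e in zip(gene_ids, expressed) if e}
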