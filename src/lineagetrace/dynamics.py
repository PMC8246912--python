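"""Pseudotime ordering and expression dynamics along a trajectory.

Cells are ordered either by their first principal component (oriented so
that declared progenitor markers decrease) or by diffusion pseudotime from
a root cell.  Expression and surface-marker profiles are smoothed with a
stride-1 sliding window (default size 20) over the pseudotime-sorted cells;
genes with reproducible trends are called by a permutation test on the
variance of the smoothed profile, BH-corrected, and the dynamic genes are
clustered by Louvain community detection on a kNN graph of their z-scored
smoothed profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from . import flow
from .io import ExpressionMatrix
from .scrna import bh_adjust

SCALINGS = ("zscore", "minmax01", "maxscale", "none")


@dataclass
class PseudotimeOrdering:
    """Per-cell scalar pseudotime plus how it was derived and oriented."""

    cell_ids: list[str]
    pseudotime: np.ndarray
    method: str  # "pc1" or "dpt"
    provenance: dict

    def __post_init__(self) -> None:
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if not np.all(np.isfinite(self.pseudotime)):
            raise ValueError("pseudotime must be finite")

    def argsort(self) -> np.ndarray:
        """Cells sorted by pseudotime, ties broken by cell_id."""
        ids = np.asarray(self.cell_ids)
        return np.lexsort((ids, self.pseudotime))


def highly_variable_genes(matrix: ExpressionMatrix, n_top: int = 2000) -> np.ndarray:
    """Row indices of the top genes by dispersion (variance/mean) rank."""
    means = matrix.values.mean(axis=1)
    var = matrix.values.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(means > 0, var / means, 0.0)
    n_top = min(n_top, matrix.n_genes)
    return np.sort(np.argsort(-disp, kind="stable")[:n_top])


def pc1_pseudotime(
    matrix: ExpressionMatrix,
    orientation_genes_down: list[str],
    n_top_genes: int = 2000,
) -> PseudotimeOrdering:
    """PC1 of the cells, oriented so the given progenitor markers decrease.

    PCA is fitted on the standardized cells x genes matrix restricted to
    highly variable genes; the sign of PC1 is chosen so the mean Pearson
    correlation of the orientation genes' expression with pseudotime is
    negative.
    """
    down_idx = matrix.gene_index(orientation_genes_down)
    hvg = highly_variable_genes(matrix, n_top_genes)
    X = matrix.values[hvg].T  # cells x genes
    keep = X.std(axis=0) > 0
    _, scores = flow.fit_pca(X[:, keep], n_components=1)
    pt = scores[:, 0]

    rs = []
    for gi in down_idx:
        g = matrix.values[gi]
        if g.std() > 0 and pt.std() > 0:
            rs.append(stats.pearsonr(g, pt)[0])
        else:
            rs.append(0.0)
    mean_r = float(np.mean(rs))
    if abs(mean_r) < 1e-6:
        raise ValueError("orientation genes uncorrelated with PC1; direction undefined")
    if mean_r > 0:
        pt = -pt
    return PseudotimeOrdering(
        cell_ids=list(matrix.cell_ids),
        pseudotime=pt,
        method="pc1",
        provenance={"orientation_genes_down": list(orientation_genes_down),
                    "n_top_genes": int(n_top_genes)},
    )


def diffusion_pseudotime(
    model: flow.DiffusionModel, root: int, cell_ids: list[str] | None = None
) -> PseudotimeOrdering:
    """Diffusion pseudotime: distance from the root cell in the rescaled
    eigencomponent space, dpt(x) = sqrt( sum_i (l_i/(1-l_i))^2 (psi_i(x)-psi_i(root))^2 )."""
    lam = model.eigenvalues
    if np.any(lam >= 1.0):
        raise ValueError("a retained eigenvalue equals 1 (non-decaying component)")
    n = model.psi.shape[0]
    if not 0 <= root < n:
        raise IndexError("root cell index out of range")
    scale = lam / (1.0 - lam)
    delta = (model.psi - model.psi[root]) * scale[None, :]
    dpt = np.sqrt((delta**2).sum(axis=1))
    ids = cell_ids if cell_ids is not None else [str(i) for i in range(n)]
    return PseudotimeOrdering(
        cell_ids=list(ids), pseudotime=dpt, method="dpt", provenance={"root_cell": ids[root]}
    )


def select_root(candidates: list[str], scores) -> str:
    """The candidate with the maximal score; ties broken by lexicographically
    smallest cell id.  The default score in the pipelines is the kNN
    projection frequency (most reference-progenitor-like cell)."""
    if len(candidates) == 0:
        raise ValueError("no root candidates")
    s = np.asarray(scores, dtype=float)
    if len(s) != len(candidates):
        raise ValueError("scores length must match candidates")
    m = s.max()
    tied = sorted(c for c, v in zip(candidates, s) if v == m)
    return tied[0]


@dataclass
class SmoothedProfile:
    values: np.ndarray
    window: int
    scaling: str


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Stride-1 moving average over the last axis, trailing partial windows
    excluded (output length n - window + 1)."""
    c = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    return (c[..., window:] - c[..., :-window]) / window


def _apply_scaling(v: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "none":
        return v
    if scaling == "zscore":
        sd = v.std(axis=-1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return (v - v.mean(axis=-1, keepdims=True)) / sd
    if scaling == "minmax01":
        lo = v.min(axis=-1, keepdims=True)
        rng = v.max(axis=-1, keepdims=True) - lo
        out = np.where(rng == 0, 0.0, (v - lo) / np.where(rng == 0, 1.0, rng))
        return out
    if scaling == "maxscale":
        mx = v.max(axis=-1, keepdims=True)
        if np.any(mx <= 0):
            raise ValueError("maxscale requires a positive maximum")
        return v / mx
    raise ValueError(f"unknown scaling {scaling!r}; choose from {SCALINGS}")


def sliding_window_smooth(
    values, ordering: PseudotimeOrdering, window: int = 20, scaling: str = "none"
) -> SmoothedProfile:
    """Sort by pseudotime (ties by cell id), average over stride-1 windows of
    the given size, then apply the requested scaling."""
    v = np.asarray(values, dtype=float)
    n = v.shape[-1]
    if len(ordering.pseudotime) != n:
        raise ValueError("values length must match ordering")
    if not 1 <= window <= n:
        raise ValueError(f"window must lie in [1, {n}]")
    sm = _moving_average(v[..., ordering.argsort()], window)
    return SmoothedProfile(values=_apply_scaling(sm, scaling), window=window, scaling=scaling)


def window_composition(labels, ordering: PseudotimeOrdering, window: int = 20) -> pd.DataFrame:
    """Per-window phenotype label proportions along the pseudotime ordering
    (same windowing as the smoothing; rows sum to 1)."""
    lab = np.asarray(labels)[ordering.argsort()]
    n = len(lab)
    if not 1 <= window <= n:
        raise ValueError(f"window must lie in [1, {n}]")
    uniq = sorted(set(lab.tolist()))
    onehot = np.stack([(lab == u).astype(float) for u in uniq])
    props = _moving_average(onehot, window)
    return pd.DataFrame(props.T, columns=uniq)


def marker_pseudotime_correlation(marker_values, ordering: PseudotimeOrdering) -> float:
    """Pearson correlation of *unsmoothed* marker values with pseudotime."""
    v = np.asarray(marker_values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 cells")
    if v.std() == 0:
        raise ValueError("marker has zero variance")
    return float(stats.pearsonr(v, ordering.pseudotime)[0])


def dynamic_gene_test(
    matrix: ExpressionMatrix,
    ordering: PseudotimeOrdering,
    window: int = 20,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test for genes dynamically expressed along pseudotime.

    The per-gene statistic is the variance of the window-smoothed expression
    profile; the null redraws it after permuting the cell ordering (the same
    permutations shared across genes).  p = (1 + #{null >= obs}) / (1 +
    n_perm), BH-adjusted across genes; a gene is dynamic at p_adj < alpha.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    n = matrix.n_cells
    if not 1 <= window <= n:
        raise ValueError(f"window must lie in [1, {n}]")
    X = matrix.values[:, ordering.argsort()]
    obs = _moving_average(X, window).var(axis=1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(matrix.n_genes, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        null = _moving_average(X[:, perm], window).var(axis=1)
        exceed += null >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "statistic": obs,
            "p_perm": p,
            "p_adj": p_adj,
            "is_dynamic": p_adj < alpha,
        }
    )


def cluster_dynamic_genes(
    profiles: np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Louvain communities on a kNN graph of z-scored smoothed gene profiles.

    ``profiles`` is genes x window positions (already z-scored).  Clusters
    are relabeled by descending size, so cluster 0 is the largest.  The
    default resolution is coarse so that the top-level trend groups (e.g.
    increasing vs decreasing) emerge rather than their sub-dynamics; raise
    it to split profile shapes more finely.
    """
    P = np.asarray(profiles, dtype=float)
    n_genes = P.shape[0]
    if n_genes < 2:
        warnings.warn("fewer than 2 genes; returning a single cluster")
        return np.zeros(n_genes, dtype=int)
    k = min(n_neighbors, n_genes - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(P)
    _, idx = nn.kneighbors(P)
    G = nx.Graph()
    G.add_nodes_from(range(n_genes))
    for i in range(n_genes):
        for j in idx[i, 1:]:
            G.add_edge(i, int(j))
    comms = nx.community.louvain_communities(G, resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(n_genes, dtype=int)
    for ci, members in enumerate(comms):
        for m in members:
            labels[m] = ci
    return labels


def max_scale_profiles(profiles: np.ndarray) -> np.ndarray:
    """Scale each gene's profile by its maximum (used for staging the onset
    order of, e.g., protease genes); every row's max becomes 1."""
    P = np.asarray(profiles, dtype=float)
    mx = P.max(axis=-1, keepdims=True)
    if np.any(mx <= 0):
        raise ValueError("every profile needs a positive maximum")
    return P / mx
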