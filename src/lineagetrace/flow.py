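"""Embeddings of flow-cytometry event tables.

The preprocessing chain follows the order: down-sample every population to
the size of the smallest one, remove exact duplicate rows, log-transform the
fluorescent parameters (scatter stays linear), z-score every retained
column.  PCA is computed on centered-and-scaled data and supports projecting
new events with the *model's* transform (means, sds and log rules learned at
fit time), so a query dataset lands in the reference coordinate system.  The
diffusion map uses a kNN-truncated adaptive Gaussian kernel with anisotropic
(alpha = 1) density normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.sparse import csgraph, csr_matrix
from sklearn.neighbors import NearestNeighbors

from .io import EventTable


class PreprocessedEvents(NamedTuple):
    matrix: pd.DataFrame        # z-scored events x parameters
    kept_index: np.ndarray      # positional row indices into the input table
    population: np.ndarray      # per retained event


def log_transform(table: EventTable) -> pd.DataFrame:
    """log10(x+1) on fluorescent parameters; scatter parameters linear."""
    out = table.data.astype(float).copy()
    for p in table.fluorescent_params:
        out[p] = np.log10(out[p] + 1.0)
    return out


def preprocess_events(table: EventTable, seed: int = 0) -> PreprocessedEvents:
    """Down-sample, deduplicate, log-transform and z-score an event table.

    Every population is down-sampled without replacement to the minimum
    population size; exact duplicate rows are then removed (first occurrence
    kept); fluorescent parameters are log10(x+1)-transformed; every column
    is z-scored to mean 0, sd 1.
    """
    pops, counts = np.unique(table.population, return_counts=True)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    if counts.min() == 0:
        raise ValueError("a population has 0 events")
    n_min = int(counts.min())

    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for pop in pops:
        idx = np.flatnonzero(table.population == pop)
        if len(idx) > n_min:
            idx = np.sort(rng.choice(idx, size=n_min, replace=False))
        keep.append(idx)
    kept = np.sort(np.concatenate(keep))

    sub = table.data.iloc[kept]
    dup = sub.duplicated(keep="first").to_numpy()
    kept = kept[~dup]

    logged = log_transform(table).iloc[kept]
    sds = logged.std(axis=0, ddof=0)
    zero_var = sds[sds == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance columns after deduplication: {zero_var}")
    z = (logged - logged.mean(axis=0)) / sds
    return PreprocessedEvents(
        matrix=z.reset_index(drop=True),
        kept_index=kept,
        population=table.population[kept],
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Centered-and-scaled PCA with enough state to project new data.

    ``loadings`` columns are orthonormal; the sign convention fixes each
    column's largest-magnitude entry positive so results are reproducible.
    ``log_params`` lists parameters the model log10(x+1)-transforms before
    standardizing (used when fitting on flow data).
    """

    parameter_names: list[str]
    parameter_means: np.ndarray
    parameter_sds: np.ndarray
    loadings: np.ndarray            # parameters x components
    explained_variance: np.ndarray  # non-increasing
    log_params: list[str]

    def validate(self) -> None:
        g = self.loadings.T @ self.loadings
        if not np.allclose(g, np.eye(self.loadings.shape[1]), atol=1e-8):
            raise ValueError("loadings are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained_variance must be non-increasing")


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip


def fit_pca(
    matrix: pd.DataFrame | np.ndarray,
    n_components: int | None = None,
    log_params: list[str] | None = None,
) -> tuple[PCAModel, np.ndarray]:
    """Fit centered-and-scaled PCA; returns the model and the training scores.

    ``matrix`` holds rows x parameters on the scale the model should
    standardize (apply :func:`log_transform` first for raw flow data, and
    pass the fluorescent names as ``log_params`` so projection replays it).
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = [f"p{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("need at least 2 rows and 1 column")
    max_rank = min(n - 1, p)
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        raise ValueError(f"n_components {n_components} exceeds max rank {max_rank}")

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / sds
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = _fix_signs(vt[:n_components].T)
    explained = (s[:n_components] ** 2) / (n - 1)
    model = PCAModel(
        parameter_names=names,
        parameter_means=means,
        parameter_sds=sds,
        loadings=loadings,
        explained_variance=explained,
        log_params=list(log_params or []),
    )
    return model, Z @ loadings


def project_pca(model: PCAModel, query: EventTable | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Project query rows into a fitted PCA space.

    The query is transformed with the model's own log rules, means and sds;
    projecting the training data therefore reproduces the training scores.
    """
    if isinstance(query, EventTable):
        df = query.data
    elif isinstance(query, pd.DataFrame):
        df = query
    else:
        df = pd.DataFrame(np.asarray(query, dtype=float), columns=model.parameter_names)
    missing = [p for p in model.parameter_names if p not in df.columns]
    if missing:
        raise KeyError(f"query is missing parameter columns: {missing}")
    X = df[model.parameter_names].to_numpy(dtype=float).copy()
    for p in model.log_params:
        j = model.parameter_names.index(p)
        X[:, j] = np.log10(X[:, j] + 1.0)
    Z = (X - model.parameter_means) / model.parameter_sds
    return Z @ model.loadings


def fit_reference_pca(table: EventTable, n_components: int | None = None, seed: int = 0):
    """Down-sample/dedup/log a flow table, then fit PCA able to project raw
    index-sort rows (log rules recorded on the model).

    Returns ``(model, scores, kept_index, population)``.
    """
    pre = preprocess_events(table, seed=seed)
    logged = log_transform(table).iloc[pre.kept_index]
    model, scores = fit_pca(logged, n_components, log_params=table.fluorescent_params)
    return model, scores, pre.kept_index, pre.population


# ---------------------------------------------------------------------------
# diffusion map


@dataclass
class DiffusionModel:
    """Diffusion-map embedding of an event/cell matrix.

    ``eigenvalues`` exclude the trivial unit eigenvalue and are sorted by
    magnitude descending; ``components`` are the right eigenvectors of the
    Markov matrix scaled by their eigenvalues; ``psi`` are the unscaled
    eigenvectors (used by diffusion pseudotime); ``stationary`` is the
    stationary distribution under which the eigenvectors are orthogonal.
    """

    kernel_bandwidths: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray  # rows x n_dcs
    psi: np.ndarray         # rows x n_dcs
    stationary: np.ndarray


def fit_diffusion_map(
    matrix: pd.DataFrame | np.ndarray,
    n_dcs: int = 10,
    n_neighbors: int = 30,
) -> DiffusionModel:
    """Adaptive-bandwidth Gaussian-kernel diffusion map, alpha = 1.

    The kernel is truncated to the kNN graph with per-point bandwidth the
    distance to the ``n_neighbors``-th neighbor, symmetrized, normalized by
    the kernel density (removing sampling-density effects), row-normalized
    to a Markov matrix, and eigendecomposed; the trivial constant
    eigenvector is dropped.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    n = X.shape[0]
    if n <= n_neighbors:
        raise ValueError("need more rows than n_neighbors")

    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(X)
    dist, idx = nn.kneighbors(X)
    sigma = dist[:, -1].copy()
    sigma[sigma == 0] = np.finfo(float).eps

    rows = np.repeat(np.arange(n), n_neighbors)
    cols = idx.ravel()
    d2 = dist.ravel() ** 2
    w = np.exp(-d2 / (sigma[rows] * sigma[cols]))
    W = csr_matrix((w, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)  # symmetrize

    n_comp, _ = csgraph.connected_components(W, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"kNN graph has {n_comp} connected components; raise n_neighbors"
        )

    W = np.asarray(W.todense())
    np.fill_diagonal(W, 1.0)  # self-transition from the Gaussian at distance 0
    q = W.sum(axis=1)
    W = W / np.outer(q, q)  # alpha = 1 anisotropic normalization
    d = W.sum(axis=1)

    # symmetric conjugate of the Markov matrix for a stable eigendecomposition
    inv_sqrt_d = 1.0 / np.sqrt(d)
    S = W * np.outer(inv_sqrt_d, inv_sqrt_d)
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(-np.abs(evals))
    evals, evecs = evals[order], evecs[:, order]

    psi = evecs * inv_sqrt_d[:, None]  # right eigenvectors of the Markov matrix
    # normalize so that sum_i pi_i psi_k(i)^2 = 1, pi the stationary distribution
    pi = d / d.sum()
    psi /= np.sqrt((pi[:, None] * psi**2).sum(axis=0))

    n_keep = min(n_dcs, n - 1)
    lam = evals[1 : n_keep + 1]
    psi_k = _fix_signs(psi[:, 1 : n_keep + 1])
    return DiffusionModel(
        kernel_bandwidths=sigma,
        eigenvalues=lam,
        components=psi_k * lam[None, :],
        psi=psi_k,
        stationary=pi,
    )
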