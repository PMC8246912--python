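"""Expression preprocessing, differential expression, and cell-cycle scoring.

Differential expression is a per-gene Welch two-sample t-test on
log-normalized values with Benjamini-Hochberg correction across all tested
genes.  Cell-cycle phases are assigned from S and G2M scores computed with
expression-bin-matched control gene sets: a cell is G1 when both scores are
negative, otherwise the phase of the larger score (ties toward G2M).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SignatureList


def normalize_log(
    matrix: ExpressionMatrix, target_sum: float = 1e6, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then natural-log(x + pseudocount)."""
    if matrix.layer_tag != "counts":
        raise ValueError("normalize_log expects a counts layer")
    totals = matrix.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cells with zero total counts: {[matrix.cell_ids[i] for i in zero]}")
    scaled = matrix.values * (target_sum / totals)[None, :]
    return ExpressionMatrix(
        values=np.log(scaled + pseudocount),
        gene_ids=list(matrix.gene_ids),
        cell_ids=list(matrix.cell_ids),
        cell_labels=list(matrix.cell_labels),
        layer_tag="lognorm",
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving by input index."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def differential_expression(
    matrix: ExpressionMatrix, group_a: str, group_b: str, alpha: float = 0.01
) -> pd.DataFrame:
    """Welch t-test per gene between two phenotype labels, BH-corrected.

    ``direction`` is ``up`` when mean in ``group_b`` exceeds ``group_a``
    (and empty where p_adj >= alpha).  Genes with zero variance in both
    groups get p = 1 by convention.
    """
    labels = np.asarray(matrix.cell_labels)
    a = matrix.values[:, labels == group_a]
    b = matrix.values[:, labels == group_b]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 cells per group")

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p_adj = bh_adjust(p)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    direction = np.where(p_adj < alpha, np.where(mean_b > mean_a, "up", "down"), "")
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t_stat": t,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
        }
    )


def score_gene_set(
    matrix: ExpressionMatrix,
    signature: SignatureList,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell signature score against expression-bin-matched controls.

    Genes are cut into ``n_bins`` equal-frequency bins by mean expression;
    for each signature gene, ``ctrl_size`` control genes are sampled from
    its bin.  The score is the mean expression of the signature genes minus
    the mean expression of the pooled control set.
    """
    present = [g for g in signature.genes if g in set(matrix.gene_ids)]
    if not present:
        raise KeyError(f"no signature gene of {signature.name!r} found in matrix")
    sig_idx = matrix.gene_index(sorted(present))

    means = matrix.values.mean(axis=1)
    order = np.argsort(means, kind="stable")
    bins = np.empty(matrix.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(matrix.n_genes) * n_bins) // matrix.n_genes, n_bins - 1
    )

    rng = np.random.default_rng(seed)
    sig_set = set(sig_idx.tolist())
    ctrl: set[int] = set()
    for gi in sig_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~np.isin(np.arange(matrix.n_genes), list(sig_set)))
        if pool.size == 0:
            continue
        take = min(ctrl_size, pool.size)
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl:
        raise ValueError("no control genes could be sampled")
    ctrl_idx = np.array(sorted(ctrl), dtype=int)
    return matrix.values[sig_idx].mean(axis=0) - matrix.values[ctrl_idx].mean(axis=0)


@dataclass
class CellCycleResult:
    s_score: np.ndarray
    g2m_score: np.ndarray
    phase: np.ndarray  # per cell in {"G1","S","G2M"}

    def proportions(self, labels=None) -> pd.DataFrame:
        """Phase proportions, optionally per phenotype label."""
        df = pd.DataFrame({"phase": self.phase})
        df["label"] = "all" if labels is None else np.asarray(labels)
        out = df.groupby("label")["phase"].value_counts(normalize=True).unstack(fill_value=0.0)
        return out.reindex(columns=["G1", "S", "G2M"], fill_value=0.0)


def assign_cell_cycle(s_score, g2m_score) -> CellCycleResult:
    """G1 when both scores are negative; otherwise the larger score's phase,
    ties between positive scores broken toward G2M."""
    s = np.asarray(s_score, dtype=float)
    g = np.asarray(g2m_score, dtype=float)
    phase = np.where((s < 0) & (g < 0), "G1", np.where(s > g, "S", "G2M"))
    return CellCycleResult(s_score=s, g2m_score=g, phase=phase.astype(str))


def score_cell_cycle(
    matrix: ExpressionMatrix,
    s_genes: SignatureList | None = None,
    g2m_genes: SignatureList | None = None,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> CellCycleResult:
    """Score S and G2M gene sets and assign a phase per cell.

    Defaults to the bundled mouse orthologs of the canonical S/G2M phase
    gene lists; pass custom :class:`SignatureList` objects to override.
    """
    s_genes = s_genes or load_cycle_signature("S")
    g2m_genes = g2m_genes or load_cycle_signature("G2M")
    s = score_gene_set(matrix, s_genes, n_bins, ctrl_size, seed)
    g = score_gene_set(matrix, g2m_genes, n_bins, ctrl_size, seed)
    return assign_cell_cycle(s, g)


def load_cycle_signature(phase: str) -> SignatureList:
    """Bundled mouse S- or G2M-phase gene list."""
    fname = {"S": "mouse_s_genes.txt", "G2M": "mouse_g2m_genes.txt"}[phase]
    text = resources.files("lineagetrace.data").joinpath(fname).read_text()
    genes = {ln.split("#")[0].strip() for ln in text.splitlines()}
    genes.discard("")
    return SignatureList(name=f"cycle_{phase}", genes=genes)
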