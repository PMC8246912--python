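"""Order simulated basophil-progenitor cells in pseudotime and find the
genes that change along it.

Simulates a 300-cell, 2000-gene single-trajectory dataset, orders the cells
by PC1 (oriented so progenitor markers decrease), runs the sliding-window
permutation test for dynamic genes, and clusters their smoothed profiles.
"""

import numpy as np
from scipy import stats

from lineagetrace import dynamics, scrna
from lineagetrace.simulate import SimParams, simulate_bifurcating_expression

params = SimParams(n_cells=300, n_genes=2000, seed=11, p_branch_a=1.0)
matrix, truth = simulate_bifurcating_expression(params)
lognorm = scrna.normalize_log(matrix)

# planted decreasing genes stand in for progenitor markers like Cd34/Kit
orientation = [g for g, c in zip(truth.gene_ids, truth.gene_class) if c == "down"][:3]
pt = dynamics.pc1_pseudotime(lognorm, orientation)
rho = stats.spearmanr(pt.pseudotime, truth.latent_time)[0]
print(f"PC1 pseudotime vs latent time: Spearman rho = {abs(rho):.3f}")

table = dynamics.dynamic_gene_test(lognorm, pt, window=20, n_perm=1000, seed=0)
called = table["is_dynamic"].to_numpy()
recall = (called & truth.is_dynamic).sum() / truth.is_dynamic.sum()
print(f"dynamic genes called: {called.sum()} (recall of planted genes {recall:.2f})")

dyn = np.flatnonzero(called)
smoothed = dynamics.sliding_window_smooth(lognorm.values[dyn], pt, 20, "zscore")
clusters = dynamics.cluster_dynamic_genes(smoothed.values, seed=0)
sizes = np.bincount(clusters)
print(f"Louvain profile clusters (sizes): {sizes.tolist()}")
# rho near 1 means the ordering recovers maturation; the clusters separate
# rising from falling expression programs along differentiation
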