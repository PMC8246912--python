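# lineagetrace

Analysis toolkit for mapping the differentiation of bipotent basophil–mast
cell progenitors (BMCPs) into the basophil and mast-cell lineages, from
multicolor flow cytometry and Smart-Seq2-scale single-cell RNA-seq.

Basophils and mast cells arise from a shared bipotent progenitor, and the
bifurcation — as well as the maturation along each branch — can be read out
from two complementary single-cell modalities: index-sorted flow-cytometry
parameter tables (surface phenotype, colony founders) and per-cell
expression matrices (transcriptome).  `lineagetrace` implements the full
analysis chain for both, and ships a synthetic-data generator with known
ground truth (branch assignments, latent maturation times, dynamic-gene
identities) so that every stage can be validated by parameter recovery.

## What it computes

**Flow-cytometry embedding** (`lineagetrace.flow`).  Events are
down-sampled to the smallest population, deduplicated, fluorescent
parameters log10(x+1)-transformed (scatter left linear) and z-scored.  A
diffusion map is built from a kNN-truncated adaptive Gaussian kernel
k(x_i, x_j) = exp(−d²_ij / σ_i σ_j) with σ_i the distance to the
n-th neighbor, density-normalized (α = 1) and row-normalized to a Markov
matrix P; the embedding uses the leading nontrivial eigenpairs (λ_i, ψ_i)
of P.  PCA (centered and scaled, fixed sign convention) provides a
reference space into which new index-sorted events are projected with the
model's own transform.

**Pseudotime and expression dynamics** (`lineagetrace.dynamics`).  Cells
are ordered either by PC1 (sign chosen so that declared progenitor markers
such as *Cd34*/*Kit* decrease) or by diffusion pseudotime from a root cell,

    dpt(x) = sqrt( Σ_i [λ_i/(1−λ_i)]² (ψ_i(x) − ψ_i(root))² ).

Profiles are smoothed with a stride-1 sliding window (default 20 cells)
along the ordering.  A gene is *dynamic* when the variance of its smoothed
profile exceeds the permutation null (cell order permuted, permutations
shared across genes; p = (1 + #{null ≥ obs})/(1 + n_perm)) at
Benjamini–Hochberg adjusted p < .01.  Dynamic genes are grouped by Louvain
community detection on a kNN graph of their z-scored profiles, and staged
by max-scaling (each profile divided by its maximum).

**Differential expression and cell cycle** (`lineagetrace.scrna`).
Per-gene Welch t-tests with BH correction between sorting phenotypes;
S/G2M scoring against expression-bin-matched control gene sets (bundled
mouse phase lists), with phase G1 iff both scores are negative, otherwise
the larger score's phase.

**Cross-dataset projection score** (`lineagetrace.enrichment`).  Query
cells (e.g. bone-marrow BMCP profiles) are projected into the reference
PCA space; each reference cell is scored by how frequently it appears
among the k = 10 nearest reference neighbors of a query cell.  The
highest-scoring cell anchors the diffusion-pseudotime root.  Gene-list
overlaps are tested with an exact upper-tail hypergeometric p computed in
log space.

**Colony fate rules** (`lineagetrace.colony`).  A cultured colony is
classified only with ≥ 20 live flow events; a lineage (basophil gate:
c-Kit⁻ FcεRI⁺ CD49b⁺; mast gate: c-Kit⁺ FcεRI⁺) is called with ≥ 5 events
in its gate; both calls make the colony "mixed"; a well with no live cells
has size 1.  Colony outcomes join the index-sort projection with log10
colony size.

## Worked example

```sh
python examples/01_pseudotime_and_dynamic_genes.py
```

```
PC1 pseudotime vs latent time: Spearman rho = 0.976
dynamic genes called: 305 (recall of planted genes 1.00)
Louvain profile clusters (sizes): [125, 100, 40, 40]
```

The simulated trajectory (300 cells, 2000 genes, 10% planted dynamic genes
with ≥ 1 log-unit effects) is recovered almost perfectly: the PC1 ordering
tracks the latent maturation time (ρ = 0.976), every planted dynamic gene
is detected at BH-adjusted p < .01, and the profile clusters separate the
rising program from the falling program (the two largest clusters), with
the planted cell-cycle gene groups forming their own smaller clusters.
The remaining examples cover the flow-cytometry embedding
(`02_flow_embedding.py`), projection-anchored diffusion pseudotime and
staged gene induction (`03_projection_root_and_dpt.py`), and colony fate
classification (`04_colony_fate.py`).  A thin CLI wraps the same
functions: `lineagetrace {simulate|flow-embed|basophil|mastcell|colony}`.

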