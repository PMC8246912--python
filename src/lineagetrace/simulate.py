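"""Synthetic single-cell and flow-cytometry data with known ground truth.

The generators emulate the statistical structure the downstream analysis
assumes: Smart-Seq2-scale count matrices (hundreds of cells, thousands of
genes) sampled along a bifurcating latent trajectory with monotone dynamic
genes and cell-cycle-structured genes; index-sort marker intensities coupled
to the latent time; and multi-population flow event tables placed along a
branching one-dimensional manifold.  Every generator is a pure function of
its parameters and a seed, and returns ground truth sufficient to predict —
without re-simulation — the expected sign of every marker correlation and
the identity of every dynamic gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import EventTable, ExpressionMatrix

BRANCHES = ("trunk", "branchA", "branchB")
GENE_CLASSES = ("up", "down", "flat", "cycle_S", "cycle_G2M")


@dataclass
class SimParams:
    """Parameters of the bifurcating expression simulation.

    ``nb_dispersion`` is the negative-binomial shape theta, i.e. counts have
    variance mu + mu^2/theta.  ``frac_dynamic`` covers the monotone up/down
    classes only; ``frac_cycle`` is split evenly between S- and G2M-driven
    genes.  ``p_branch_a`` = 1 yields a single (trunk + branchA) trajectory.
    """

    n_cells: int = 300
    n_genes: int = 2000
    branch_point: float = 0.3
    frac_dynamic: float = 0.1
    frac_cycle: float = 0.04
    nb_dispersion: float = 10.0
    library_size_mean: float = 1e5
    library_size_sigma: float = 0.3
    effect_size_range: tuple[float, float] = (1.0, 2.0)
    cycle_effect: float = 2.0
    p_branch_a: float = 0.5
    marker_spec: list[tuple[str, str, int, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 2 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive (n_cells >= 2)")
        if not 0 < self.branch_point < 1:
            raise ValueError("branch_point must lie in (0,1)")
        if not 0 < self.frac_dynamic < 1:
            raise ValueError("frac_dynamic must lie in (0,1)")
        if not 0 <= self.frac_cycle < 1:
            raise ValueError("frac_cycle must lie in [0,1)")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("nb_dispersion and library_size_mean must be positive")
        if not 0 <= self.p_branch_a <= 1:
            raise ValueError("p_branch_a must lie in [0,1]")
        if int(round(self.frac_dynamic * self.n_genes)) < 2:
            raise ValueError("frac_dynamic * n_genes must be at least 2")


@dataclass
class TrajectoryTruth:
    """Ground truth of a simulated bifurcating trajectory."""

    cell_ids: list[str]
    branch: np.ndarray          # per cell, in BRANCHES
    latent_time: np.ndarray     # per cell, in [0,1]
    cell_phase: np.ndarray      # per cell, in {"none","S","G2M"}
    gene_ids: list[str]
    gene_class: np.ndarray      # per gene, in GENE_CLASSES
    gene_branch: np.ndarray     # per gene: branch a dynamic gene acts on ("" for others)
    effect_size: np.ndarray     # per gene, log-fold span of the dynamic profile

    @property
    def is_dynamic(self) -> np.ndarray:
        return np.isin(self.gene_class, ("up", "down"))

    @property
    def proliferative(self) -> np.ndarray:
        return self.cell_phase != "none"


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_bifurcating_expression(params: SimParams) -> tuple[ExpressionMatrix, TrajectoryTruth]:
    """Draw a negative-binomial count matrix along a bifurcating trajectory.

    Dynamic genes follow a scaled logistic (location and steepness drawn per
    gene) of latent time on the trunk plus their assigned branch and are
    flat — frozen at the branch-point value — on the other branch.  Cycle
    genes are elevated in proliferative cells, whose frequency decays with
    latent time.  Identical seed implies identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_cells, n_genes = params.n_cells, params.n_genes

    if n_cells < 40:  # window-20 smoothing downstream needs 2 windows' worth
        warnings.warn("n_cells is small relative to downstream window-20 smoothing")

    # --- cells
    t = rng.uniform(0.0, 1.0, n_cells)
    branch = np.where(t < params.branch_point, "trunk", "").astype(object)
    post = branch == ""
    to_a = rng.random(n_cells) < params.p_branch_a
    branch[post & to_a] = "branchA"
    branch[post & ~to_a] = "branchB"
    branch = branch.astype(str)

    p_prolif = (1.0 - t) ** 2  # progenitors cycle; mature cells mostly G1
    prolif = rng.random(n_cells) < p_prolif
    phase = np.where(prolif, np.where(rng.random(n_cells) < 0.5, "S", "G2M"), "none")

    # --- genes
    n_dyn = int(round(params.frac_dynamic * n_genes))
    n_cyc = int(round(params.frac_cycle * n_genes))
    n_cyc_s = n_cyc // 2
    n_cyc_g2m = n_cyc - n_cyc_s
    gene_class = np.array(
        ["up"] * (n_dyn // 2)
        + ["down"] * (n_dyn - n_dyn // 2)
        + ["cycle_S"] * n_cyc_s
        + ["cycle_G2M"] * n_cyc_g2m
        + ["flat"] * (n_genes - n_dyn - n_cyc),
        dtype=object,
    ).astype(str)

    gene_branch = np.full(n_genes, "", dtype=object)
    dyn_mask = np.isin(gene_class, ("up", "down"))
    branch_choices = np.array(["branchA", "branchB"])
    # dynamic genes act on a branch actually populated under p_branch_a
    probs = np.array([params.p_branch_a, 1.0 - params.p_branch_a])
    if probs[0] in (0.0, 1.0):
        gene_branch[dyn_mask] = branch_choices[0 if probs[0] == 1.0 else 1]
    else:
        gene_branch[dyn_mask] = rng.choice(branch_choices, size=dyn_mask.sum(), p=probs)
    gene_branch = gene_branch.astype(str)

    effect = np.zeros(n_genes)
    lo, hi = params.effect_size_range
    effect[dyn_mask] = rng.uniform(lo, hi, dyn_mask.sum())
    cyc_mask = np.isin(gene_class, ("cycle_S", "cycle_G2M"))
    effect[cyc_mask] = params.cycle_effect

    base = rng.normal(1.0, 1.0, n_genes)  # baseline log relative expression

    # --- log-mean profile per gene x cell
    loc = rng.uniform(0.25, 0.75, n_genes)   # logistic midpoint in latent time
    steep = rng.uniform(6.0, 12.0, n_genes)  # logistic steepness
    log_mu = np.tile(base[:, None], (1, n_cells))
    for gi in np.flatnonzero(dyn_mask):
        on_path = (branch == "trunk") | (branch == gene_branch[gi])
        s = _logistic(steep[gi] * (t - loc[gi]))
        s_frozen = _logistic(steep[gi] * (params.branch_point - loc[gi]))
        prof = np.where(on_path, s, s_frozen)
        if gene_class[gi] == "down":
            prof = 1.0 - prof
        log_mu[gi] += effect[gi] * prof
    s_cells = phase == "S"
    g2m_cells = phase == "G2M"
    log_mu[gene_class == "cycle_S"] += params.cycle_effect * s_cells[None, :]
    log_mu[gene_class == "cycle_G2M"] += params.cycle_effect * g2m_cells[None, :]

    # --- counts: relative expression -> library-size-scaled NB means
    rel = np.exp(log_mu)
    rel /= rel.sum(axis=0, keepdims=True)
    lib = params.library_size_mean * np.exp(
        rng.normal(0.0, params.library_size_sigma, n_cells)
        - 0.5 * params.library_size_sigma**2
    )
    mu = rel * lib[None, :]
    theta = params.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)

    cell_ids = [f"cell{str(i).zfill(4)}" for i in range(n_cells)]
    gene_ids = [f"gene{str(i).zfill(5)}" for i in range(n_genes)]
    labels = _phenotype_labels(branch, t, params.branch_point)
    matrix = ExpressionMatrix(counts, gene_ids, cell_ids, labels, layer_tag="counts")
    truth = TrajectoryTruth(
        cell_ids=cell_ids,
        branch=branch,
        latent_time=t,
        cell_phase=np.asarray(phase, dtype=str),
        gene_ids=gene_ids,
        gene_class=gene_class,
        gene_branch=gene_branch,
        effect_size=effect,
    )
    return matrix, truth


def _phenotype_labels(branch: np.ndarray, t: np.ndarray, branch_point: float) -> list[str]:
    """Sorting-gate-style phenotype labels: progenitor below the midpoint of
    the post-branch interval, mature above."""
    mid = (1.0 + branch_point) / 2.0
    out = []
    for b, ti in zip(branch, t):
        if b == "trunk":
            out.append("BMCP")
        elif b == "branchA":
            out.append("BaP" if ti < mid else "Ba")
        else:
            out.append("P1" if ti < mid else "MC")
    return out


def simulate_index_sort(
    truth: TrajectoryTruth,
    marker_spec: Sequence[tuple[str, str, int, float]],
    seed: int = 0,
    noise_sd: float = 0.15,
) -> EventTable:
    """Index-sort marker intensities coupled to latent time.

    Each marker is specified as (name, branch, sign, strength): its
    log10-intensity is ``sign * strength * latent_time`` on the trunk plus
    the named branch (frozen at the branch-point value elsewhere) plus
    Gaussian noise, then shifted and exponentiated to instrument scale.
    """
    rng = np.random.default_rng(seed)
    t = truth.latent_time
    trunk = truth.branch == "trunk"
    bp = float(t[trunk].max()) if trunk.any() else 0.0
    cols: dict[str, np.ndarray] = {}
    for name, br, sign, strength in marker_spec:
        if br not in BRANCHES:
            raise ValueError(f"unknown branch {br!r} for marker {name!r}")
        if sign not in (-1, 1):
            raise ValueError(f"marker sign must be +1 or -1, got {sign}")
        on_path = trunk | (truth.branch == br)
        # off-branch cells sit at the branch-point level of this marker
        drive = np.where(on_path, t, bp)
        logint = sign * strength * drive + rng.normal(0.0, noise_sd, len(t))
        cols[name] = 10.0 ** (2.0 + logint) - 1.0  # instrument scale, positive
    data = pd.DataFrame(cols)
    kinds = {name: "fluorescent" for name in data.columns}
    pops = np.asarray(_phenotype_labels(truth.branch, t, bp), dtype=object)
    return EventTable(data=data, kinds=kinds, population=pops, cell_ids=list(truth.cell_ids))


def simulate_flow_events(
    populations: Sequence[str],
    n_per_pop: Sequence[int],
    n_fluor: int = 9,
    n_scatter: int = 2,
    manifold_spec: dict | None = None,
    dup_rate: float = 0.0,
    noise_sd: float = 0.12,
    seed: int = 0,
) -> EventTable:
    """Gaussian population clusters along a 1-D branching curve in parameter
    space, mimicking a multi-population flow-cytometry acquisition.

    Populations are placed consecutively: the first along the trunk, the
    remainder alternating onto two branches, so adjacent populations overlap
    and the whole set traces a bifurcation.  ``dup_rate`` duplicates that
    fraction of rows verbatim (appended at the end) to exercise downstream
    deduplication.
    """
    if len(populations) < 2:
        raise ValueError("need at least 2 populations")
    if len(n_per_pop) != len(populations):
        raise ValueError("n_per_pop must match populations")
    if not 0 <= dup_rate < 1:
        raise ValueError("dup_rate must lie in [0,1)")
    rng = np.random.default_rng(seed)
    n_params = n_fluor + n_scatter

    # branching directions in parameter space: trunk u0, branches u1/u2
    u = rng.normal(size=(3, n_params))
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    if manifold_spec is None:
        manifold_spec = {}
        n_pop = len(populations)
        for i, pop in enumerate(populations):
            if i == 0:
                manifold_spec[pop] = ("trunk", (0.0, 0.45))
            else:
                seg = "branchA" if i % 2 == 1 else "branchB"
                depth = (i + 1) // 2
                n_side = (n_pop - 1 + (1 if i % 2 == 1 else 0)) // 2
                lo = 0.35 + 0.6 * (depth - 1) / max(n_side, 1)
                hi = 0.35 + 0.6 * depth / max(n_side, 1)
                manifold_spec[pop] = (seg, (lo, hi))

    seg_dir = {"trunk": u[0], "branchA": u[1], "branchB": u[2]}
    bp = 0.4  # branch point arc position
    rows, pops = [], []
    for pop, n in zip(populations, n_per_pop):
        seg, (lo, hi) = manifold_spec[pop]
        s = rng.uniform(lo, hi, n)
        if seg == "trunk":
            centers = np.outer(s, u[0])
        else:
            centers = bp * u[0] + np.outer(np.clip(s - bp, 0, None), seg_dir[seg])
        pts = centers + rng.normal(0.0, noise_sd, (n, n_params))
        rows.append(pts)
        pops.extend([pop] * n)
    X = np.vstack(rows)

    names = [f"FL{i + 1}" for i in range(n_fluor)] + [f"SC{i + 1}" for i in range(n_scatter)]
    kinds = {f"FL{i + 1}": "fluorescent" for i in range(n_fluor)}
    kinds |= {f"SC{i + 1}": "scatter" for i in range(n_scatter)}
    # fluorescent channels live on an exponentiated instrument scale
    vals = np.empty_like(X)
    vals[:, :n_fluor] = 10.0 ** (2.0 + X[:, :n_fluor]) - 1.0
    vals[:, n_fluor:] = 50_000.0 * (1.0 + 0.5 * X[:, n_fluor:])
    df = pd.DataFrame(vals, columns=names)
    population = np.asarray(pops, dtype=object)

    n_total = len(df)
    n_dup = int(round(dup_rate * n_total))
    if n_dup:
        pick = rng.choice(n_total, size=n_dup, replace=False)
        df = pd.concat([df, df.iloc[pick]], ignore_index=True)
        population = np.concatenate([population, population[pick]])
    return EventTable(data=df, kinds=kinds, population=population.astype(str))


def simulate_colony_events(
    n_cells: int,
    frac_ba_gate: float = 0.0,
    frac_mc_gate: float = 0.0,
    frac_dead: float = 0.0,
    seed: int = 0,
) -> EventTable:
    """One cultured colony's flow events with gate-consistent intensities.

    Events fall in the basophil gate (c-Kit low, FcepsilonRI+, CD49b+), the
    mast gate (c-Kit+, FcepsilonRI+) or neither, with the stated expected
    fractions; ``frac_dead`` events are dead (live flag 0, excluded from
    gating downstream).  Fractions must sum to at most 1.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if min(frac_ba_gate, frac_mc_gate, frac_dead) < 0 or (
        frac_ba_gate + frac_mc_gate + frac_dead
    ) > 1 + 1e-12:
        raise ValueError("fractions must be non-negative and sum to at most 1")
    rng = np.random.default_rng(seed)
    p_other = 1.0 - frac_ba_gate - frac_mc_gate - frac_dead
    cats = rng.choice(4, size=n_cells, p=[frac_ba_gate, frac_mc_gate, max(p_other, 0.0), frac_dead])

    # gate-consistent log10 intensity centers: [c-Kit, FceRI, CD49b]
    centers = np.array(
        [
            [1.0, 3.5, 3.5],  # basophil gate: c-Kit- FceRI+ CD49b+
            [3.5, 3.5, 1.0],  # mast gate: c-Kit+ FceRI+
            [2.0, 1.0, 1.0],  # neither: FceRI-
            [1.5, 1.5, 1.5],  # dead (values irrelevant, flagged)
        ]
    )
    logint = centers[cats] + rng.normal(0.0, 0.2, (n_cells, 3))
    df = pd.DataFrame(10.0**logint, columns=["cKit", "FceRI", "CD49b"])
    df["live"] = (cats != 3).astype(float)
    kinds = {"cKit": "fluorescent", "FceRI": "fluorescent", "CD49b": "fluorescent", "live": "scatter"}
    return EventTable(data=df, kinds=kinds, population=np.array(["colony"] * n_cells, dtype=object))
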