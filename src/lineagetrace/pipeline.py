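"""End-to-end orchestration of the three analyses.

``run_basophil_pipeline`` reproduces the bone-marrow basophil workflow
(PCA pseudotime, differential expression, cell cycle, marker correlations,
dynamic genes, profile clusters, signature overlaps); ``run_mastcell_pipeline``
the peritoneal mast-cell workflow (diffusion map, cross-dataset projection
score, root selection, diffusion pseudotime, dynamic genes, max-scaled
protease staging); ``run_flow_pipeline`` the flow-cytometry workflow
(preprocessing, diffusion map + reference PCA, index-sort projection,
colony fate classification).  Every run is deterministic given its seed and
can write all result tables as TSV with a JSON manifest of the resolved
configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import colony as colony_mod
from . import dynamics, enrichment, flow, scrna
from .io import EventTable, ExpressionMatrix, SignatureList

log = logging.getLogger("lineagetrace")


@dataclass
class PipelineConfig:
    """Stage parameters; the defaults are the study's stated constants where
    stated (window 20, alpha .01, k 10, >=20/>=5 colony rules)."""

    window: int = 20
    alpha: float = 0.01
    k_neighbors: int = 10
    n_perm: int = 1000
    n_dcs: int = 10
    n_neighbors: int = 30
    n_pcs: int = 20
    n_top_genes: int = 2000
    min_events: int = 20
    min_gate_events: int = 5
    target_sum: float = 1e6
    pseudocount: float = 1.0
    louvain_neighbors: int = 15
    louvain_resolution: float = 0.1
    orientation_genes: list[str] = field(default_factory=lambda: ["Cd34", "Kit"])
    seed: int = 0

    def resolved(self) -> dict:
        return asdict(self)


def _marker_dynamics(index_table: EventTable, ordering, cfg: PipelineConfig):
    """Per-marker Pearson correlation with pseudotime (on unsmoothed
    log-transformed values) and min-max-scaled smoothed profiles."""
    logged = flow.log_transform(index_table)
    corr, profiles = {}, {}
    for p in index_table.parameter_names:
        v = logged[p].to_numpy()
        corr[p] = dynamics.marker_pseudotime_correlation(v, ordering)
        profiles[p] = dynamics.sliding_window_smooth(
            v, ordering, cfg.window, scaling="minmax01"
        ).values
    corr_df = pd.DataFrame({"marker": list(corr), "pearson_r": list(corr.values())})
    prof_df = pd.DataFrame(profiles).T
    prof_df.index.name = "marker"
    return corr_df, prof_df


def _dynamic_gene_stage(lognorm: ExpressionMatrix, ordering, cfg: PipelineConfig):
    """Dynamic-gene permutation test, then Louvain clustering of the
    z-scored smoothed profiles of the dynamic genes."""
    table = dynamics.dynamic_gene_test(
        lognorm, ordering, cfg.window, cfg.n_perm, cfg.alpha, seed=cfg.seed
    )
    dyn_idx = np.flatnonzero(table["is_dynamic"].to_numpy())
    table["cluster_id"] = pd.array([pd.NA] * len(table), dtype="Int64")
    profiles = None
    if len(dyn_idx) >= 2:
        sm = dynamics.sliding_window_smooth(
            lognorm.values[dyn_idx], ordering, cfg.window, scaling="zscore"
        )
        labels = dynamics.cluster_dynamic_genes(
            sm.values, cfg.louvain_neighbors, cfg.louvain_resolution, seed=cfg.seed
        )
        table.loc[dyn_idx, "cluster_id"] = labels
        profiles = pd.DataFrame(
            sm.values, index=[lognorm.gene_ids[i] for i in dyn_idx]
        )
        profiles.insert(0, "cluster_id", labels)
        profiles.index.name = "gene_id"
    log.info("dynamic genes: %d of %d", len(dyn_idx), lognorm.n_genes)
    return table, profiles


def _overlap_stage(
    table: pd.DataFrame, lognorm: ExpressionMatrix, signatures: dict[str, SignatureList]
) -> pd.DataFrame:
    """Hypergeometric overlap of dynamic up/down gene lists with each
    signature, over the expressed-gene universe."""
    universe = enrichment.expression_universe(lognorm.values, lognorm.gene_ids)
    gid = table["gene_id"].to_numpy()
    dyn = table["is_dynamic"].to_numpy()
    rows = []
    for direction in ("up", "down"):
        if "direction" in table.columns:
            sel = dyn & (table["direction"].to_numpy() == direction)
        else:  # trend from the profile cluster is resolved by the caller
            sel = dyn
        genes = set(gid[sel]) & universe
        for name, sig in signatures.items():
            res = enrichment.hypergeometric_overlap(genes, sig.genes & universe, universe)
            rows.append(
                {
                    "dynamic_set": direction,
                    "signature": name,
                    "n_universe": res.n_universe,
                    "n_dynamic": res.n_list_a,
                    "n_signature": res.n_list_b,
                    "n_overlap": res.n_overlap,
                    "p": res.p,
                }
            )
        if "direction" not in table.columns:
            break
    return pd.DataFrame(rows)


def _annotate_trend(table: pd.DataFrame, lognorm: ExpressionMatrix, ordering) -> pd.DataFrame:
    """Tag each dynamic gene up/down by the sign of its Spearman trend with
    pseudotime, so overlap tests can split the lists."""
    from scipy import stats

    gid_index = {g: i for i, g in enumerate(lognorm.gene_ids)}
    directions = []
    pt = ordering.pseudotime
    for _, row in table.iterrows():
        if not row["is_dynamic"]:
            directions.append("")
            continue
        v = lognorm.values[gid_index[row["gene_id"]]]
        rho = stats.spearmanr(v, pt)[0]
        directions.append("up" if rho > 0 else "down")
    out = table.copy()
    out["direction"] = directions
    return out


def run_basophil_pipeline(
    counts: ExpressionMatrix,
    config: PipelineConfig | None = None,
    index_table: EventTable | None = None,
    signatures: dict[str, SignatureList] | None = None,
    cycle_signatures: tuple[SignatureList, SignatureList] | None = None,
    group_a: str = "BaP",
    group_b: str = "Ba",
    outdir=None,
) -> dict:
    """Bone-marrow basophil analysis: DE, cell cycle, PC1 pseudotime, marker
    correlations, dynamic genes + clusters, signature overlaps."""
    cfg = config or PipelineConfig()
    bundle: dict = {}

    lognorm = scrna.normalize_log(counts, cfg.target_sum, cfg.pseudocount)
    log.info("normalized %d genes x %d cells", lognorm.n_genes, lognorm.n_cells)

    bundle["de"] = scrna.differential_expression(lognorm, group_a, group_b, cfg.alpha)

    try:
        s_sig, g2m_sig = cycle_signatures or (None, None)
        cc = scrna.score_cell_cycle(lognorm, s_sig, g2m_sig, seed=cfg.seed)
        bundle["cell_cycle"] = pd.DataFrame(
            {
                "cell_id": lognorm.cell_ids,
                "s_score": cc.s_score,
                "g2m_score": cc.g2m_score,
                "phase": cc.phase,
            }
        )
        bundle["cell_cycle_proportions"] = cc.proportions(lognorm.cell_labels)
    except KeyError as e:
        log.warning("cell-cycle scoring skipped: %s", e)

    ordering = dynamics.pc1_pseudotime(lognorm, cfg.orientation_genes, cfg.n_top_genes)
    bundle["pseudotime"] = pd.DataFrame(
        {"cell_id": ordering.cell_ids, "pseudotime": ordering.pseudotime, "method": "pc1"}
    )
    bundle["window_composition"] = dynamics.window_composition(
        lognorm.cell_labels, ordering, cfg.window
    )

    if index_table is not None:
        corr, prof = _marker_dynamics(index_table, ordering, cfg)
        bundle["marker_correlations"] = corr
        bundle["marker_profiles"] = prof

    dyn_table, profiles = _dynamic_gene_stage(lognorm, ordering, cfg)
    dyn_table = _annotate_trend(dyn_table, lognorm, ordering)
    bundle["dynamic_genes"] = dyn_table
    if profiles is not None:
        bundle["dynamic_profiles"] = profiles

    if signatures:
        bundle["overlaps"] = _overlap_stage(dyn_table, lognorm, signatures)

    bundle["ordering"] = ordering
    if outdir is not None:
        write_bundle(bundle, outdir, cfg, stage="basophil")
    return bundle


def run_mastcell_pipeline(
    counts: ExpressionMatrix,
    config: PipelineConfig | None = None,
    query_counts: ExpressionMatrix | None = None,
    root_cell: str | None = None,
    index_table: EventTable | None = None,
    signatures: dict[str, SignatureList] | None = None,
    protease_genes: list[str] | None = None,
    outdir=None,
) -> dict:
    """Peritoneal mast-cell analysis: diffusion map, query projection score,
    root selection, DPT, dynamic genes, protease staging, overlaps.

    ``query_counts`` (e.g. bone-marrow progenitor profiles) selects the DPT
    root via the kNN projection frequency score; alternatively pass
    ``root_cell`` explicitly.
    """
    cfg = config or PipelineConfig()
    bundle: dict = {}

    lognorm = scrna.normalize_log(counts, cfg.target_sum, cfg.pseudocount)
    hvg = dynamics.highly_variable_genes(lognorm, cfg.n_top_genes)
    hvg = hvg[lognorm.values[hvg].std(axis=1) > 0]
    hvg_names = [lognorm.gene_ids[i] for i in hvg]
    expr_df = pd.DataFrame(lognorm.values[hvg].T, columns=hvg_names)

    n_pcs = min(cfg.n_pcs, len(hvg), lognorm.n_cells - 1)
    pca_model, pc_scores = flow.fit_pca(expr_df, n_pcs)
    dmodel = flow.fit_diffusion_map(
        pc_scores, cfg.n_dcs, min(cfg.n_neighbors, lognorm.n_cells - 1)
    )
    bundle["diffusion_components"] = pd.DataFrame(
        dmodel.components,
        index=lognorm.cell_ids,
        columns=[f"DC{i + 1}" for i in range(dmodel.components.shape[1])],
    )

    if query_counts is not None:
        query_log = scrna.normalize_log(query_counts, cfg.target_sum, cfg.pseudocount)
        qdf = pd.DataFrame(
            query_log.values[query_log.gene_index(hvg_names)].T, columns=hvg_names
        )
        q_scores = flow.project_pca(pca_model, qdf)
        nscore = enrichment.knn_frequency_score(
            pc_scores, q_scores, cfg.k_neighbors, reference_ids=lognorm.cell_ids
        )
        bundle["neighbor_scores"] = nscore
        root_cell = dynamics.select_root(lognorm.cell_ids, nscore["score"].to_numpy())
    if root_cell is None:
        raise ValueError("provide query_counts or an explicit root_cell")
    root_idx = lognorm.cell_ids.index(root_cell)

    ordering = dynamics.diffusion_pseudotime(dmodel, root_idx, lognorm.cell_ids)
    bundle["pseudotime"] = pd.DataFrame(
        {"cell_id": ordering.cell_ids, "pseudotime": ordering.pseudotime, "method": "dpt"}
    )
    bundle["window_composition"] = dynamics.window_composition(
        lognorm.cell_labels, ordering, cfg.window
    )

    if index_table is not None:
        corr, prof = _marker_dynamics(index_table, ordering, cfg)
        bundle["marker_correlations"] = corr
        bundle["marker_profiles"] = prof

    dyn_table, profiles = _dynamic_gene_stage(lognorm, ordering, cfg)
    dyn_table = _annotate_trend(dyn_table, lognorm, ordering)
    bundle["dynamic_genes"] = dyn_table
    if profiles is not None:
        bundle["dynamic_profiles"] = profiles

    if protease_genes:
        present = [g for g in protease_genes if g in set(lognorm.gene_ids)]
        if present:
            idx = lognorm.gene_index(present)
            sm = dynamics.sliding_window_smooth(
                lognorm.values[idx], ordering, cfg.window, scaling="none"
            )
            staged = dynamics.max_scale_profiles(sm.values)
            prot = pd.DataFrame(staged, index=present)
            prot.index.name = "gene_id"
            bundle["protease_profiles"] = prot

    if signatures:
        bundle["overlaps"] = _overlap_stage(dyn_table, lognorm, signatures)

    bundle["ordering"] = ordering
    if outdir is not None:
        write_bundle(bundle, outdir, cfg, stage="mastcell")
    return bundle


def run_flow_pipeline(
    events: EventTable,
    config: PipelineConfig | None = None,
    index_table: EventTable | None = None,
    colonies: dict[str, tuple[EventTable, str, int | None]] | None = None,
    gates: dict | None = None,
    outdir=None,
) -> dict:
    """Flow-cytometry analysis: preprocessing, diffusion map + reference
    PCA, index-sort projection, colony classification and overlay.

    ``colonies`` maps colony_id -> (colony EventTable, origin_cell_id,
    visual_size or None).
    """
    cfg = config or PipelineConfig()
    bundle: dict = {}

    pre = flow.preprocess_events(events, seed=cfg.seed)
    log.info("retained %d events after down-sampling/dedup", len(pre.matrix))
    dmodel = flow.fit_diffusion_map(pre.matrix, cfg.n_dcs, cfg.n_neighbors)
    bundle["diffusion_components"] = pd.DataFrame(
        dmodel.components, columns=[f"DC{i + 1}" for i in range(dmodel.components.shape[1])]
    ).assign(population=pre.population)

    model, scores, kept, pops = flow.fit_reference_pca(events, seed=cfg.seed)
    bundle["pca_scores"] = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    ).assign(population=pops)
    bundle["pca_model"] = model

    if index_table is not None:
        proj = flow.project_pca(model, index_table)
        bundle["index_projection"] = pd.DataFrame(
            proj,
            columns=[f"PC{i + 1}" for i in range(proj.shape[1])],
            index=index_table.cell_ids,
        )

    if colonies:
        records, origins = [], {}
        for cid, (ev, origin, vsize) in colonies.items():
            rec = colony_mod.classify_colony(
                ev,
                gates,
                colony_id=cid,
                origin_cell_id=origin,
                visual_size=vsize,
                min_events=cfg.min_events,
                min_gate_events=cfg.min_gate_events,
            )
            records.append(rec)
            origins[cid] = origin
        bundle["colony_records"] = records
        bundle["colony_table"] = pd.DataFrame(
            {
                "colony_id": [r.colony_id for r in records],
                "origin_cell_id": [r.origin_cell_id for r in records],
                "size": [r.size for r in records],
                "n_live_events": [r.n_live_events for r in records],
                "classified": [r.classified for r in records],
                "colony_type": [r.colony_type for r in records],
            }
        )
        if index_table is not None:
            bundle["colony_overlay"] = colony_mod.overlay_colonies(model, index_table, records)

    if outdir is not None:
        write_bundle(bundle, outdir, cfg, stage="flow")
    return bundle


def write_bundle(bundle: dict, outdir, config: PipelineConfig, stage: str) -> None:
    """Write every DataFrame in a result bundle as TSV, plus a manifest with
    the resolved configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            path = outdir / f"{stage}.{key}.tsv"
            obj.to_csv(path, sep="\t", float_format="%.10g")
            written.append(path.name)
    manifest = {
        "stage": stage,
        "config": config.resolved(),
        "outputs": sorted(written),
        "package": "lineagetrace 0.1.0",
    }
    (outdir / f"{stage}.manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
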