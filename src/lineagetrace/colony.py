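"""Colony fate classification from cultured-colony flow events.

A colony is classified only when it yields at least ``min_events`` live
flow events (default 20); a lineage (basophil or mast cell) is called when
at least ``min_gate_events`` live events (default 5) fall inside that
lineage's gate.  Colonies producing both lineages are "mixed".  Colony size
is the visual or event count, set to 1 when no live cells were observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import flow
from .io import EventTable


# axis-aligned gate regions over (instrument-scale) parameter intervals
Gate = dict[str, tuple[float, float]]


def standard_gates() -> dict[str, Gate]:
    """Default basophil / mast-cell gates on c-Kit, FceRI and CD49b.

    Basophil: c-Kit negative, FceRI positive, CD49b positive; mast cell:
    c-Kit positive, FceRI positive.  Bounds are log10-intensity-3 cutoffs
    (10^2.5) on an instrument scale spanning ~10^1-10^4.
    """
    hi = float("inf")
    cut = 10**2.5
    return {
        "Ba": {"cKit": (0.0, cut), "FceRI": (cut, hi), "CD49b": (cut, hi)},
        "MC": {"cKit": (cut, hi), "FceRI": (cut, hi)},
    }


@dataclass
class ColonyRecord:
    colony_id: str
    origin_cell_id: str
    size: int
    n_live_events: int
    lineage_calls: set[str] = field(default_factory=set)
    classified: bool = False

    @property
    def colony_type(self) -> str:
        if not self.classified:
            return "unclassified"
        if self.lineage_calls == {"Ba", "MC"}:
            return "mixed"
        if self.lineage_calls == {"Ba"}:
            return "Ba"
        if self.lineage_calls == {"MC"}:
            return "MC"
        return "none"


def _in_gate(data: pd.DataFrame, gate: Gate) -> np.ndarray:
    mask = np.ones(len(data), dtype=bool)
    for param, (lo, hi) in gate.items():
        if param not in data.columns:
            raise KeyError(f"gate references unknown parameter {param!r}")
        mask &= (data[param].to_numpy() >= lo) & (data[param].to_numpy() <= hi)
    return mask


def classify_colony(
    events: EventTable,
    gates: dict[str, Gate] | None = None,
    colony_id: str = "colony",
    origin_cell_id: str = "",
    visual_size: int | None = None,
    min_events: int = 20,
    min_gate_events: int = 5,
    live_column: str = "live",
) -> ColonyRecord:
    """Apply the >=``min_events`` / >=``min_gate_events`` lineage-call rules
    to one colony's flow events.

    Dead cells are excluded via the 0/1 ``live_column`` if present (all
    events counted live otherwise).  ``visual_size`` overrides the live
    event count as the recorded colony size; a colony with no live cells
    gets size 1.
    """
    gates = gates if gates is not None else standard_gates()
    if live_column in events.data.columns:
        live = events.data[live_column].to_numpy() > 0
    else:
        live = np.ones(events.n_events, dtype=bool)
    live_data = events.data.loc[live, [c for c in events.data.columns if c != live_column]]
    n_live = int(live.sum())

    size = visual_size if visual_size is not None else n_live
    if n_live == 0:
        size = max(int(size), 1) if visual_size is not None else 1
    size = max(int(size), 1)

    record = ColonyRecord(
        colony_id=colony_id, origin_cell_id=origin_cell_id, size=size, n_live_events=n_live
    )
    if n_live < min_events:
        return record
    record.classified = True
    for lineage, gate in gates.items():
        if int(_in_gate(live_data, gate).sum()) >= min_gate_events:
            record.lineage_calls.add(lineage)
    return record


def summarize_colony_output(
    records: list[ColonyRecord],
    origins: dict[str, str],
    experiments: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-origin-population proportions of colony types, mean +/- SEM
    across experiment replicates.

    ``origins`` maps colony_id -> origin population; ``experiments`` maps
    colony_id -> experiment replicate (one experiment assumed if absent, in
    which case SEM is reported as NaN).  Populations with zero classified
    colonies are absent from the output (missing, not zero).
    """
    rows = []
    for r in records:
        if not r.classified:
            continue
        rows.append(
            {
                "population": origins[r.colony_id],
                "experiment": (experiments or {}).get(r.colony_id, "exp1"),
                "colony_type": r.colony_type,
            }
        )
    if not rows:
        raise ValueError("no classified colonies")
    df = pd.DataFrame(rows)
    per_exp = (
        df.groupby(["population", "experiment"])["colony_type"]
        .value_counts(normalize=True)
        .rename("fraction")
        .reset_index()
    )
    wide = per_exp.pivot_table(
        index=["population", "experiment"], columns="colony_type", values="fraction", fill_value=0.0
    )
    out = wide.groupby("population").agg(["mean", "sem"])
    out.columns = [f"{ct}_{stat}" for ct, stat in out.columns]
    return out


def overlay_colonies(
    model: flow.PCAModel,
    index_table: EventTable,
    records: list[ColonyRecord],
) -> pd.DataFrame:
    """Join the PCA projection of index-sorted colony founders with their
    colony outcomes; one row per colony with PC coordinates, log10 colony
    size and colony type."""
    if index_table.cell_ids is None:
        raise ValueError("index table must carry cell_ids")
    scores = flow.project_pca(model, index_table)
    pos = {cid: i for i, cid in enumerate(index_table.cell_ids)}
    rows = []
    for r in records:
        if r.origin_cell_id not in pos:
            raise KeyError(f"colony {r.colony_id}: origin cell {r.origin_cell_id!r} not in index table")
        i = pos[r.origin_cell_id]
        row = {"colony_id": r.colony_id, "origin_cell_id": r.origin_cell_id}
        for j in range(scores.shape[1]):
            row[f"PC{j + 1}"] = scores[i, j]
        row["log10_size"] = float(np.log10(r.size))
        row["colony_type"] = r.colony_type
        rows.append(row)
    return pd.DataFrame(rows)
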