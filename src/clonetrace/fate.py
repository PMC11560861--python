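"""Clone-level fate statistics for barcoded stem/progenitor clones.

Each clone (barcode) observed in the stem/progenitor (HSPC) compartment
is scored against its progeny in the nine downstream lineages:

* output value: O1/O2, the clone's share of all downstream cells (O1)
  over its share of all HSPC cells (O2). Values above 2 mark
  differentiation-prone (high-output) clones, values below 0.4
  self-renewing (low-output) clones, and 0.8-1.2 balanced (med) clones;
  values in the gaps between classes are reported as unclassified.
* M value: the number of distinct downstream lineages carrying the
  clone's barcode; 1 is unipotent, 2 through L-1 multipotent, and all L
  lineages pluripotent.
* differentiation-bias score: D1/D2 per lineage, the clone's frequency
  within a lineage over its overall downstream frequency; scores above 1
  mark over-representation. Aggregating counts over a lymphoid/myeloid
  lineage grouping yields per-clone bias labels.

All denominators include non-barcoded cells by default (share-of-
compartment semantics); the downstream compartment means every
QC-passing non-HSPC cell. Both readings are toggleable and logged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import FATE_RESULT_COLUMNS

__all__ = [
    "OutputClass",
    "PotencyClass",
    "OutputThresholds",
    "CloneFateTable",
    "OutputResult",
    "PotencyResult",
    "BiasResult",
    "TransductionSummary",
    "build_fate_table",
    "output_value",
    "classify_output",
    "m_value",
    "bias_score",
    "bias_scores",
    "call_bias",
    "label_pl_hspcs",
    "transduction_summary",
    "subset_for_trajectory",
    "compute_fate_results",
]

HSPC = "HSPC"


class OutputClass(str, enum.Enum):
    LOW = "low"
    MED = "med"
    HIGH = "high"
    UNCLASSIFIED = "unclassified"


class PotencyClass(str, enum.Enum):
    NONE = "none"
    UNIPOTENT = "unipotent"
    MULTIPOTENT = "multipotent"
    PLURIPOTENT = "pluripotent"


@dataclass(frozen=True)
class OutputThresholds:
    """Output-class boundaries; all comparisons are strict, so values on a
    boundary or inside a gap fall into the unclassified class."""

    low_max: float = 0.4
    med_low: float = 0.8
    med_high: float = 1.2
    high_min: float = 2.0


@dataclass
class CloneFateTable:
    """Per-clone cell counts across the HSPC compartment and each
    downstream lineage, plus compartment totals over ALL QC-passed cells
    (barcoded or not)."""

    lineages: tuple[str, ...]
    counts: pd.DataFrame  # index clone_id; columns [HSPC] + lineages
    hspc_total: int
    lineage_totals: pd.Series  # indexed by lineage

    @property
    def downstream_total(self) -> int:
        return int(self.lineage_totals.sum())

    @property
    def clone_ids(self) -> list[str]:
        return list(self.counts.index)

    def clone_row(self, clone_id: str) -> pd.Series:
        if clone_id not in self.counts.index:
            raise KeyError(f"unknown clone {clone_id!r}")
        return self.counts.loc[clone_id]


def build_fate_table(
    cells: pd.DataFrame, lineages: Sequence[str], hspc_label: str = HSPC
) -> CloneFateTable:
    """Tally the clone fate table from a per-cell table.

    ``cells`` needs columns ``cell_id``, ``clone_id`` (NA/empty for
    unbarcoded cells), ``lineage``, ``is_hspc`` and ``qc_pass``. Only
    QC-passing cells enter. Compartment totals count every entering cell;
    clone counts only the cells carrying that clone id. Unknown lineage
    labels are a hard error.
    """
    lineages = tuple(lineages)
    df = cells.loc[cells["qc_pass"].astype(bool)].copy()
    known = set(lineages) | {hspc_label}
    unknown = ~df["lineage"].isin(known)
    if unknown.any():
        raise ValueError(f"unknown lineage label {df.loc[unknown, 'lineage'].iloc[0]!r}")
    is_hspc = df["is_hspc"].astype(bool)
    if (is_hspc != (df["lineage"] == hspc_label)).any():
        raise ValueError("is_hspc flag inconsistent with lineage label")

    hspc_total = int(is_hspc.sum())
    down = df.loc[~is_hspc]
    lineage_totals = (
        down["lineage"].value_counts().reindex(lineages, fill_value=0).astype(int)
    )

    barcoded = df.loc[df["clone_id"].notna() & (df["clone_id"] != "")]
    compartment = np.where(barcoded["is_hspc"].astype(bool), HSPC, barcoded["lineage"])
    tab = pd.crosstab(barcoded["clone_id"], compartment)
    counts = tab.reindex(columns=[HSPC, *lineages], fill_value=0).astype(int)
    counts.index.name = "clone_id"
    counts = counts.sort_index()
    return CloneFateTable(
        lineages=lineages,
        counts=counts,
        hspc_total=hspc_total,
        lineage_totals=lineage_totals,
    )


@dataclass(frozen=True)
class OutputResult:
    clone_id: str
    O1: float
    O2: float
    output_value: float
    output_class: OutputClass


@dataclass(frozen=True)
class PotencyResult:
    clone_id: str
    m_value: int
    potency_class: PotencyClass


@dataclass(frozen=True)
class BiasResult:
    clone_id: str
    lineage: str
    D1: float
    D2: float
    score: float


def classify_output(
    value: float, thresholds: OutputThresholds = OutputThresholds()
) -> OutputClass:
    """Map an output value to low/med/high with strict boundaries.

    low: value < low_max; med: med_low < value < med_high; high:
    value > high_min. Boundary values and gap values are unclassified.
    """
    if value < 0:
        raise ValueError("output value must be non-negative")
    t = thresholds
    if value < t.low_max:
        return OutputClass.LOW
    if t.med_low < value < t.med_high:
        return OutputClass.MED
    if value > t.high_min:
        return OutputClass.HIGH
    return OutputClass.UNCLASSIFIED


def _require_hspc_clone(row: pd.Series, clone_id: str) -> None:
    if int(row[HSPC]) < 1:
        raise ValueError(f"{clone_id!r} is not an HSPC clone (no HSPC cells)")


def output_value(
    clone_id: str,
    table: CloneFateTable,
    thresholds: OutputThresholds = OutputThresholds(),
) -> OutputResult:
    """O1 = clone downstream count / downstream total; O2 = clone HSPC
    count / HSPC total; output value = O1/O2. Defined for HSPC clones."""
    row = table.clone_row(clone_id)
    _require_hspc_clone(row, clone_id)
    clone_down = int(row[list(table.lineages)].sum())
    o1 = clone_down / table.downstream_total if table.downstream_total else 0.0
    o2 = int(row[HSPC]) / table.hspc_total
    value = o1 / o2
    return OutputResult(clone_id, o1, o2, value, classify_output(value, thresholds))


def m_value(clone_id: str, table: CloneFateTable) -> PotencyResult:
    """Number of downstream lineages where the clone is observed, with the
    potency class: 0 none, 1 unipotent, 2..L-1 multipotent, L pluripotent."""
    row = table.clone_row(clone_id)
    _require_hspc_clone(row, clone_id)
    m = int((row[list(table.lineages)] >= 1).sum())
    n_lin = len(table.lineages)
    if m == 0:
        cls = PotencyClass.NONE
    elif m == 1:
        cls = PotencyClass.UNIPOTENT
    elif m == n_lin:
        cls = PotencyClass.PLURIPOTENT
    else:
        cls = PotencyClass.MULTIPOTENT
    return PotencyResult(clone_id, m, cls)


def bias_score(clone_id: str, lineage: str, table: CloneFateTable) -> BiasResult:
    """D1 = clone count in ``lineage`` / lineage total; D2 = clone count in
    all downstream lineages / downstream total; score = D1/D2."""
    if lineage not in table.lineages:
        raise ValueError(f"unknown lineage {lineage!r}")
    row = table.clone_row(clone_id)
    clone_down = int(row[list(table.lineages)].sum())
    if clone_down == 0:
        raise ValueError(f"clone {clone_id!r} absent downstream (D2 == 0)")
    d2 = clone_down / table.downstream_total
    lin_total = int(table.lineage_totals[lineage])
    d1 = int(row[lineage]) / lin_total if lin_total else 0.0
    return BiasResult(clone_id, lineage, d1, d2, d1 / d2)


def bias_scores(clone_id: str, table: CloneFateTable) -> pd.DataFrame:
    """Bias score of one clone in every downstream lineage."""
    rows = [bias_score(clone_id, lin, table) for lin in table.lineages]
    return pd.DataFrame(
        {
            "clone_id": clone_id,
            "lineage": [r.lineage for r in rows],
            "D1": [r.D1 for r in rows],
            "D2": [r.D2 for r in rows],
            "score": [r.score for r in rows],
        }
    )


def call_bias(
    table: CloneFateTable,
    groups: Mapping[str, Sequence[str]],
    threshold: float = 2.0,
    min_clone_cells: int = 10,
) -> pd.Series:
    """Label clones as lymphoid- or myeloid-biased from group-level scores.

    ``groups`` partitions the downstream lineages into ``lymphoid`` and
    ``myeloid``. The group score substitutes group-aggregated counts into
    D1/D2 (clone-in-group / group total over clone-downstream / downstream
    total). A clone is labelled with a group when that group's score
    exceeds ``threshold`` while the opposite group's score is below 1;
    clones with fewer than ``min_clone_cells`` downstream cells are
    labelled ``none``.
    """
    if set(groups) != {"lymphoid", "myeloid"}:
        raise ValueError("groups must have exactly the keys 'lymphoid' and 'myeloid'")
    assigned = [lin for g in groups.values() for lin in g]
    if sorted(assigned) != sorted(table.lineages):
        missing = set(table.lineages) - set(assigned)
        extra = set(assigned) - set(table.lineages)
        raise ValueError(
            f"lineage grouping must partition the downstream lineages "
            f"(missing {sorted(missing)}, unknown {sorted(extra)})"
        )
    group_totals = {
        g: int(table.lineage_totals[list(lins)].sum()) for g, lins in groups.items()
    }
    total = table.downstream_total
    labels = {}
    lin_cols = list(table.lineages)
    for clone_id, row in table.counts.iterrows():
        clone_down = int(row[lin_cols].sum())
        if clone_down < min_clone_cells or clone_down == 0:
            labels[clone_id] = "none"
            continue
        d2 = clone_down / total
        score = {
            g: (int(row[list(lins)].sum()) / group_totals[g]) / d2
            for g, lins in groups.items()
        }
        if score["lymphoid"] > threshold and score["myeloid"] < 1:
            labels[clone_id] = "lymphoid"
        elif score["myeloid"] > threshold and score["lymphoid"] < 1:
            labels[clone_id] = "myeloid"
        else:
            labels[clone_id] = "none"
    return pd.Series(labels, name="bias_label").rename_axis("clone_id")


def label_pl_hspcs(
    output_results: Iterable[OutputResult], potency_results: Iterable[PotencyResult]
) -> set[str]:
    """Clones that are pluripotent AND low- or med-output — the
    high-stemness ("pluripotent-lineage") subset."""
    out_by_id = {r.clone_id: r for r in output_results}
    pot_by_id = {r.clone_id: r for r in potency_results}
    if set(out_by_id) != set(pot_by_id):
        raise ValueError("output and potency results cover different clones")
    return {
        cid
        for cid in out_by_id
        if pot_by_id[cid].potency_class is PotencyClass.PLURIPOTENT
        and out_by_id[cid].output_class in (OutputClass.LOW, OutputClass.MED)
    }


@dataclass
class TransductionSummary:
    n_cells: int
    n_barcoded: int
    barcoded_fraction: float
    subset_barcoded_fraction: dict
    subset_bias: dict
    empty_loading_rate: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_barcoded": self.n_barcoded,
            "barcoded_fraction": self.barcoded_fraction,
            "subset_barcoded_fraction": self.subset_barcoded_fraction,
            "subset_bias": self.subset_bias,
            "empty_loading_rate": self.empty_loading_rate,
        }


def transduction_summary(
    cells: pd.DataFrame, vector_positive: Optional[pd.Series] = None
) -> TransductionSummary:
    """Barcoded fractions overall and per lineage subset, with the per-
    subset bias (subset fraction / global fraction).

    ``cells`` needs ``lineage``, ``qc_pass`` and ``clone_id`` columns.
    The empty-loading rate — vector-positive cells with no recoverable
    tag, as a share of vector-positive cells — is only computable when a
    ``vector_positive`` boolean Series (aligned to ``cells``) is given;
    with zero vector-positive cells it is reported as missing.
    """
    df = cells.loc[cells["qc_pass"].astype(bool)].copy()
    barcoded = df["clone_id"].notna() & (df["clone_id"] != "")
    n_cells = len(df)
    n_barcoded = int(barcoded.sum())
    global_frac = n_barcoded / n_cells if n_cells else 0.0
    subset_frac = {}
    subset_bias = {}
    for lineage, sub in barcoded.groupby(df["lineage"]):
        frac = float(sub.mean())
        subset_frac[lineage] = frac
        subset_bias[lineage] = frac / global_frac if global_frac else float("nan")
    empty_rate = None
    if vector_positive is not None:
        vp = vector_positive.loc[df.index].astype(bool)
        n_vp = int(vp.sum())
        if n_vp > 0:
            empty_rate = float((vp & ~barcoded).sum() / n_vp)
    return TransductionSummary(
        n_cells=n_cells,
        n_barcoded=n_barcoded,
        barcoded_fraction=global_frac,
        subset_barcoded_fraction=dict(sorted(subset_frac.items())),
        subset_bias=dict(sorted(subset_bias.items())),
        empty_loading_rate=empty_rate,
    )


def subset_for_trajectory(
    cells: pd.DataFrame, bias_labels: pd.Series, label: str
) -> list[str]:
    """Cell ids (HSPC and downstream) of every cell whose clone carries
    ``label``, for export to external trajectory tools."""
    clones = set(bias_labels.index[bias_labels == label])
    mask = cells["clone_id"].isin(clones)
    return cells.loc[mask, "cell_id"].tolist()


def compute_fate_results(
    table: CloneFateTable,
    thresholds: OutputThresholds = OutputThresholds(),
) -> pd.DataFrame:
    """Per-clone fate results for every HSPC clone (clone with at least one
    HSPC cell), in the on-disk column layout.

    ``top_bias_lineage`` is the argmax of the per-lineage bias scores
    (ties broken by lineage order); clones absent downstream get an empty
    top lineage and score 0.
    """
    rows = []
    lin_cols = list(table.lineages)
    for clone_id in table.clone_ids:
        crow = table.clone_row(clone_id)
        if int(crow[HSPC]) < 1:
            continue
        out = output_value(clone_id, table, thresholds)
        pot = m_value(clone_id, table)
        clone_down = int(crow[lin_cols].sum())
        if clone_down > 0:
            sc = bias_scores(clone_id, table)
            top_idx = int(np.argmax(sc["score"].values))
            top_lin = sc["lineage"].iloc[top_idx]
            top_score = float(sc["score"].iloc[top_idx])
        else:
            top_lin, top_score = "", 0.0
        rows.append(
            {
                "clone_tag": clone_id,
                "n_hspc": int(crow[HSPC]),
                "n_downstream_total": clone_down,
                "O1": out.O1,
                "O2": out.O2,
                "output_value": out.output_value,
                "output_class": out.output_class.value,
                "m_value": pot.m_value,
                "potency_class": pot.potency_class.value,
                "top_bias_lineage": top_lin,
                "top_bias_score": top_score,
            }
        )
    return pd.DataFrame(rows, columns=FATE_RESULT_COLUMNS)
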