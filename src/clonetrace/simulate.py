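"""Synthetic barcoded-clone populations with known ground truth.

The generator emulates the counting universe the fate statistics run on:
founder clones carry unique random 20-base tags, seed a known number of
downstream lineages (potency), allocate their progeny with
Dirichlet-weighted lineage proportions (bias), and sit in an output
regime parameterized directly by the expected output value (downstream
share over HSPC share). Unbarcoded background cells dilute both
compartments, detection dropout hides a cell's barcode without removing
the cell, and an optional FASTQ emitter writes reads with the cassette
(anchors + tag) at a random offset plus configurable substitution
errors — the inverse of the capture stage, with per-read error
bookkeeping so capture decisions can be audited read by read.

Construction guarantees used by recovery tests:

* each clone's expected output value equals its regime target exactly,
  because the downstream compartment total is fixed at
  ``downstream_per_hspc`` x the HSPC total and background fills the gap;
* every seeded lineage receives at least one downstream cell, so with
  zero dropout the realized M value equals the seeded lineage count.

The default anchors are synthetic fixed 18-mers (stand-ins for a real
construct's flanks, which are experiment-specific inputs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .capture import ConstructSpec
from .io_formats import write_fastq

__all__ = [
    "DEFAULT_LINEAGES",
    "DEFAULT_CONSTRUCT",
    "SizeDist",
    "OutputRegime",
    "SimulationConfig",
    "SimTruth",
    "simulate_clones",
    "emit_reads",
    "evaluate_recovery",
]

DEFAULT_LINEAGES = ("Ery", "Mk", "GMP", "Mono", "DC1", "DC2", "pDC", "ProgB", "B")

# synthetic stand-in anchors (arbitrary fixed 18-mers, not from any real vector)
DEFAULT_CONSTRUCT = ConstructSpec(
    upstream_anchor="ACGTCTGAACTCCAGTCA",
    downstream_anchor="TGGAATTCTCGGGTGCCA",
)

_BASES = np.array(list("ACGT"))


class SizeDist(BaseModel):
    """Small count distribution. ``poisson`` draws are floored at 1 (a
    clone, cell or UMI that exists has at least one unit)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: Literal["fixed", "poisson", "uniform"]
    value: int = 1
    lam: float = 1.0
    low: int = 1
    high: int = 1

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "fixed":
            return np.full(size, self.value, dtype=np.int64)
        if self.name == "poisson":
            return np.maximum(1, rng.poisson(self.lam, size)).astype(np.int64)
        return rng.integers(self.low, self.high + 1, size, dtype=np.int64)


class OutputRegime(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    label: str
    output_value: float = Field(ge=0)
    share: float = Field(gt=0, le=1)


class SimulationConfig(BaseModel):
    """All knobs of the clone simulator; reproducible from ``seed`` alone.

    Defaults mirror a barcoding transplantation study: ~20% of cells
    barcoded (``unbarcoded_fraction`` 0.8), an HSPC compartment of ~10%
    of cells (``downstream_per_hspc`` 9), nine downstream lineages, a
    potency distribution tilted toward pluripotency, and low per-base
    substitution error rates.
    """

    model_config = ConfigDict(extra="forbid", frozen=True, populate_by_name=True)

    seed: int = 0
    n_clones: int = 300
    lineages: tuple[str, ...] = DEFAULT_LINEAGES
    hspc_label: str = "HSPC"
    clone_size: SizeDist = SizeDist(name="poisson", lam=3.0)
    output_regimes: tuple[OutputRegime, ...] = (
        OutputRegime(label="low", output_value=0.2, share=1 / 3),
        OutputRegime(label="med", output_value=1.0, share=1 / 3),
        OutputRegime(label="high", output_value=3.0, share=1 / 3),
    )
    potency_weights: Optional[tuple[float, ...]] = None  # weight for m = 1..L
    dirichlet_alpha: float = 5.0
    lineage_weight_multipliers: dict[str, float] = {}
    biased_lineage: Optional[str] = None
    bias_multiplier: float = 1.0
    biased_clone_fraction: float = 0.0
    unbarcoded_fraction: float = 0.8
    downstream_per_hspc: float = 9.0
    detection_dropout: float = 0.0
    anchor_error_rate: float = 0.001
    tag_error_rate: float = 0.001
    umi_error_rate: float = 0.001
    cell_barcode_error_rate: float = 0.001
    umis_per_cell: SizeDist = SizeDist(name="poisson", lam=3.0)
    reads_per_umi: SizeDist = SizeDist(name="poisson", lam=2.0)
    read2_length: int = 100
    construct_spec: ConstructSpec = Field(default=DEFAULT_CONSTRUCT, alias="construct")

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        shares = sum(r.share for r in self.output_regimes)
        if abs(shares - 1.0) > 1e-9:
            raise ValueError("output regime shares must sum to 1")
        for rate in (
            self.unbarcoded_fraction,
            self.detection_dropout,
            self.anchor_error_rate,
            self.tag_error_rate,
            self.umi_error_rate,
            self.cell_barcode_error_rate,
        ):
            if not 0 <= rate < 1:
                raise ValueError("all rates/fractions must lie in [0, 1)")
        if self.potency_weights is not None and len(self.potency_weights) != len(
            self.lineages
        ):
            raise ValueError("potency_weights must have one weight per lineage count 1..L")
        if self.biased_lineage is not None and self.biased_lineage not in self.lineages:
            raise ValueError(f"biased_lineage {self.biased_lineage!r} not in lineages")
        cassette = (
            len(self.construct_spec.upstream_anchor)
            + self.construct_spec.tag_length
            + len(self.construct_spec.downstream_anchor)
        )
        if cassette > self.read2_length:
            raise ValueError("anchors + tag longer than read2_length")
        if self.downstream_per_hspc <= 0:
            raise ValueError("downstream_per_hspc must be positive")
        return self

    @property
    def construct(self) -> ConstructSpec:
        return self.construct_spec


@dataclass
class SimTruth:
    """Ground truth: per-clone parameters and the full emitted cell table.

    ``clones`` columns: clone_id (= tag), regime, expected_output,
    hspc_cells, downstream_cells, m_seeded, seeded_lineages (tuple),
    biased (bool), one count column per lineage.
    ``cells`` columns: cell_id, lineage, compartment, clone_id (NA for
    unbarcoded), observed (False where dropout hid the barcode).
    """

    config: SimulationConfig
    clones: pd.DataFrame
    cells: pd.DataFrame

    def annotation_frame(self) -> pd.DataFrame:
        df = self.cells[["cell_id", "lineage", "compartment"]].copy()
        df["qc_pass"] = True
        df["doublet"] = False
        df["is_hspc"] = df["compartment"] == self.config.hspc_label
        return df

    def resolved_frame(self) -> pd.DataFrame:
        """Observed cell -> clone map, in the shape capture would produce."""
        mask = self.cells["clone_id"].notna() & self.cells["observed"]
        df = self.cells.loc[mask, ["cell_id", "clone_id"]].copy()
        df = df.rename(columns={"clone_id": "merged_clone_id"})
        df["resolution"] = "single"
        return df.reset_index(drop=True)

    def analysis_frame(self) -> pd.DataFrame:
        """Per-cell table ready for the fate statistics (observed barcodes only)."""
        df = self.annotation_frame()
        observed = self.cells["clone_id"].where(self.cells["observed"])
        df["clone_id"] = observed.values
        return df[["cell_id", "clone_id", "lineage", "is_hspc", "qc_pass"]]


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n unique random k-mers over ACGT (collisions redrawn)."""
    codes = rng.integers(0, 4, size=(n, k))
    kmers = _BASES[codes].view(f"<U{k}").ravel()
    seen = pd.Index(kmers)
    dup = seen.duplicated()
    while dup.any():
        idx = np.flatnonzero(dup)
        codes = rng.integers(0, 4, size=(len(idx), k))
        kmers[idx] = _BASES[codes].view(f"<U{k}").ravel()
        dup = pd.Index(kmers).duplicated()
    return kmers


def simulate_clones(config: SimulationConfig) -> SimTruth:
    """Draw the clone population and the full annotated cell table.

    Per clone: regime and HSPC cell count are drawn first; the downstream
    count is Poisson with mean ``regime_value x hspc_cells x
    downstream_per_hspc`` (floored at the seeded-lineage count so every
    seeded lineage is realized); progeny are spread as one cell per
    seeded lineage plus a Dirichlet-multinomial remainder. Background
    unbarcoded cells then top the HSPC compartment up to the configured
    unbarcoded fraction and the downstream compartment up to
    ``downstream_per_hspc`` x the HSPC total, making every clone's
    expected output value equal its regime target.
    """
    rng = np.random.default_rng(config.seed)
    L = len(config.lineages)
    n = config.n_clones

    # regime expectations are realizable only while the fixed downstream
    # compartment (downstream_per_hspc x HSPC total) can absorb the clones'
    # expected progeny: share-weighted mean output value < 1/(1-unbarcoded)
    mean_r = sum(r.share * r.output_value for r in config.output_regimes)
    if mean_r > 1 / (1 - config.unbarcoded_fraction):
        warnings.warn(
            "mean regime output value exceeds 1/(1-unbarcoded_fraction); "
            "the downstream compartment cannot absorb the expected progeny "
            "and realized output values will compress below their targets",
            stacklevel=2,
        )

    tags = _random_kmers(rng, n, config.construct_spec.tag_length)
    shares = np.array([r.share for r in config.output_regimes])
    regime_idx = rng.choice(len(config.output_regimes), size=n, p=shares / shares.sum())
    regime_vals = np.array([config.output_regimes[i].output_value for i in regime_idx])
    regime_labels = [config.output_regimes[i].label for i in regime_idx]
    h = config.clone_size.sample(rng, n)

    if config.potency_weights is None:
        pw = np.arange(1, L + 1, dtype=float)  # tilt toward pluripotency
    else:
        pw = np.asarray(config.potency_weights, dtype=float)
    pw = pw / pw.sum()
    m = rng.choice(np.arange(1, L + 1), size=n, p=pw)

    biased = rng.random(n) < config.biased_clone_fraction
    if config.biased_lineage is None:
        biased[:] = False
    base_alpha = np.array(
        [
            config.dirichlet_alpha * config.lineage_weight_multipliers.get(lin, 1.0)
            for lin in config.lineages
        ]
    )
    focal = (
        config.lineages.index(config.biased_lineage)
        if config.biased_lineage is not None
        else -1
    )

    lam = regime_vals * h * config.downstream_per_hspc
    d = rng.poisson(lam)

    seeded_sets: list[tuple[str, ...]] = []
    lin_counts = np.zeros((n, L), dtype=np.int64)
    for c in range(n):
        if regime_vals[c] == 0:
            seeded_sets.append(())
            d[c] = 0
            continue
        m_c = int(m[c])
        if biased[c]:
            others = [i for i in range(L) if i != focal]
            rest = rng.choice(others, size=m_c - 1, replace=False) if m_c > 1 else []
            seeded = np.sort(np.concatenate(([focal], np.asarray(rest, dtype=int))))
        else:
            seeded = np.sort(rng.choice(L, size=m_c, replace=False))
        seeded_sets.append(tuple(config.lineages[i] for i in seeded))
        d[c] = max(int(d[c]), m_c)
        alpha = base_alpha[seeded].copy()
        if biased[c]:
            alpha[np.searchsorted(seeded, focal)] *= config.bias_multiplier
        w = rng.dirichlet(alpha)
        extra = rng.multinomial(int(d[c]) - m_c, w)
        lin_counts[c, seeded] = 1 + extra

    m_seeded = np.array([len(s) for s in seeded_sets])

    # background cells
    u = config.unbarcoded_fraction
    sum_h = int(h.sum())
    bg_h = int(round(sum_h * u / (1 - u)))
    hspc_total = sum_h + bg_h
    d_target = int(round(config.downstream_per_hspc * hspc_total))
    bg_d = max(0, d_target - int(d.sum()))
    bg_lin = rng.multinomial(bg_d, np.full(L, 1.0 / L))

    # assemble the per-cell table (vectorized; stable clone-then-background order)
    cell_lineage: list[np.ndarray] = []
    cell_clone: list[np.ndarray] = []
    cell_comp: list[np.ndarray] = []

    hspc_arr = np.repeat(tags, h).astype(object)
    cell_clone.append(hspc_arr)
    cell_lineage.append(np.full(len(hspc_arr), config.hspc_label, dtype=object))
    cell_comp.append(np.full(len(hspc_arr), config.hspc_label, dtype=object))

    flat_counts = lin_counts.ravel()
    clone_rep = np.repeat(np.repeat(tags, L), flat_counts).astype(object)
    lin_rep = np.repeat(np.tile(np.array(config.lineages, dtype=object), n), flat_counts)
    cell_clone.append(clone_rep)
    cell_lineage.append(lin_rep)
    cell_comp.append(np.full(len(clone_rep), "downstream", dtype=object))

    cell_clone.append(np.full(bg_h, None, dtype=object))
    cell_lineage.append(np.full(bg_h, config.hspc_label, dtype=object))
    cell_comp.append(np.full(bg_h, config.hspc_label, dtype=object))

    bg_lin_rep = np.repeat(np.array(config.lineages, dtype=object), bg_lin)
    cell_clone.append(np.full(bg_d, None, dtype=object))
    cell_lineage.append(bg_lin_rep)
    cell_comp.append(np.full(bg_d, "downstream", dtype=object))

    clone_col = np.concatenate(cell_clone)
    n_cells = len(clone_col)
    cells = pd.DataFrame(
        {
            "cell_id": _random_kmers(rng, n_cells, 20),
            "lineage": np.concatenate(cell_lineage),
            "compartment": np.concatenate(cell_comp),
            "clone_id": clone_col,
        }
    )
    barcoded = cells["clone_id"].notna()
    observed = np.ones(n_cells, dtype=bool)
    if config.detection_dropout > 0:
        drop = rng.random(n_cells) < config.detection_dropout
        observed = ~(drop & barcoded.values)
    cells["observed"] = observed & barcoded.values

    clones = pd.DataFrame(
        {
            "clone_id": tags,
            "regime": regime_labels,
            "expected_output": regime_vals,
            "hspc_cells": h,
            "downstream_cells": d,
            "m_seeded": m_seeded,
            "seeded_lineages": seeded_sets,
            "biased": biased,
        }
    )
    for j, lin in enumerate(config.lineages):
        clones[lin] = lin_counts[:, j]
    return SimTruth(config=config, clones=clones, cells=cells)


def _apply_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii"), len(hit)


def emit_reads(
    truth: SimTruth,
    path_r1: str | Path,
    path_r2: str | Path,
    qual_char: str = "I",
) -> pd.DataFrame:
    """Write paired FASTQ for every observed barcoded cell and return the
    read manifest.

    Read 1 is cell barcode (20) + UMI (10); read 2 embeds
    anchor + tag + anchor at a random feasible offset inside random
    stuffer sequence, truncated/padded to the configured length.
    Substitution errors are applied per region at the configured rates
    and counted per read in the manifest (columns ``n_cell_err``,
    ``n_umi_err``, ``n_up_err``, ``n_tag_err``, ``n_down_err``), so
    capture decisions can be checked against the realized errors.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 1_000_003)
    spec = config.construct
    cassette_len = len(spec.upstream_anchor) + spec.tag_length + len(spec.downstream_anchor)
    max_offset = config.read2_length - cassette_len

    cells = truth.cells.loc[truth.cells["clone_id"].notna() & truth.cells["observed"]]
    r1_records: list[tuple[str, str, str]] = []
    r2_records: list[tuple[str, str, str]] = []
    manifest_rows = []
    serial = 0
    q30 = qual_char * 30
    q_read2 = qual_char * config.read2_length
    for cell_id, clone_tag in zip(cells["cell_id"], cells["clone_id"]):
        n_umis = int(config.umis_per_cell.sample(rng, 1)[0])
        umis = _BASES[rng.integers(0, 4, size=(n_umis, 10))].view("<U10").ravel()
        for umi in umis:
            n_reads = int(config.reads_per_umi.sample(rng, 1)[0])
            for _ in range(n_reads):
                rid = f"sim-{serial}"
                serial += 1
                cb_err, n_cb = _apply_errors(cell_id, config.cell_barcode_error_rate, rng)
                umi_err, n_umi = _apply_errors(str(umi), config.umi_error_rate, rng)
                up_err, n_up = _apply_errors(spec.upstream_anchor, config.anchor_error_rate, rng)
                down_err, n_down = _apply_errors(
                    spec.downstream_anchor, config.anchor_error_rate, rng
                )
                tag_err, n_tag = _apply_errors(clone_tag, config.tag_error_rate, rng)
                offset = int(rng.integers(0, max_offset + 1))
                stuffer = _BASES[rng.integers(0, 4, size=config.read2_length)]
                read2 = (
                    "".join(stuffer[:offset])
                    + up_err
                    + tag_err
                    + down_err
                    + "".join(stuffer[offset + cassette_len :])
                )
                r1_records.append((rid, cb_err + umi_err, q30))
                r2_records.append((rid, read2, q_read2))
                manifest_rows.append(
                    {
                        "read_id": rid,
                        "cell_id": cell_id,
                        "umi": str(umi),
                        "clone_id": clone_tag,
                        "offset": offset,
                        "n_cell_err": n_cb,
                        "n_umi_err": n_umi,
                        "n_up_err": n_up,
                        "n_tag_err": n_tag,
                        "n_down_err": n_down,
                    }
                )
    write_fastq(r1_records, path_r1)
    write_fastq(r2_records, path_r2)
    return pd.DataFrame(
        manifest_rows,
        columns=[
            "read_id",
            "cell_id",
            "umi",
            "clone_id",
            "offset",
            "n_cell_err",
            "n_umi_err",
            "n_up_err",
            "n_tag_err",
            "n_down_err",
        ],
    )


def evaluate_recovery(
    fate_results: pd.DataFrame,
    truth: SimTruth,
    bias_labels: Optional[pd.Series] = None,
) -> dict:
    """Score estimated fate results against the simulation truth.

    Reports the regime-by-class confusion matrix, per-regime output-value
    mean/bias/RMSE, potency exact-match and never-exceeds rates, and —
    when ``bias_labels`` is given — precision/recall of the biased-clone
    labels against the truth's ``biased`` flags.
    """
    est = fate_results.set_index("clone_tag")
    tr = truth.clones.set_index("clone_id")
    common = est.index.intersection(tr.index)
    if len(common) == 0:
        raise ValueError("no overlap between estimated and true clone ids")
    est = est.loc[common]
    tr = tr.loc[common]

    confusion = (
        pd.crosstab(tr["regime"], est["output_class"]).reindex(
            index=sorted(tr["regime"].unique()), fill_value=0
        )
    )
    per_regime = {}
    for regime, sub in est.groupby(tr["regime"]):
        target = float(tr.loc[sub.index, "expected_output"].iloc[0])
        vals = sub["output_value"].astype(float)
        per_regime[regime] = {
            "target": target,
            "n": int(len(sub)),
            "mean": float(vals.mean()),
            "bias": float(vals.mean() - target),
            "rmse": float(np.sqrt(((vals - target) ** 2).mean())),
            "class_accuracy": float((sub["output_class"] == regime).mean()),
        }
    m_est = est["m_value"].astype(int)
    m_true = tr["m_seeded"].astype(int)
    report = {
        "n_clones_scored": int(len(common)),
        "confusion": {r: confusion.loc[r].to_dict() for r in confusion.index},
        "per_regime": per_regime,
        "potency_exact_rate": float((m_est == m_true).mean()),
        "potency_within_truth_rate": float((m_est <= m_true).mean()),
    }
    if bias_labels is not None:
        called = bias_labels.reindex(common).fillna("none") != "none"
        true_biased = tr["biased"].astype(bool)
        tp = int((called & true_biased).sum())
        report["bias_precision"] = tp / int(called.sum()) if called.sum() else float("nan")
        report["bias_recall"] = tp / int(true_biased.sum()) if true_biased.sum() else float("nan")
    return report
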