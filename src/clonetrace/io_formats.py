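"""Readers and writers for the pipeline's external file formats.

All tabular exchange is tab-separated text with a mandatory header row,
matching single-cell metadata conventions. FASTQ is read in paired mode
with transparent gzip support (by ``.gz`` extension); read-id pairing
strips a trailing ``/1``/``/2`` and any space-delimited comment, which
covers the common FASTQ dialects.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadPair",
    "read_fastq_pairs",
    "write_fastq",
    "read_cell_annotation",
    "write_cell_annotation",
    "FATE_RESULT_COLUMNS",
    "write_fate_results",
    "read_fate_results",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadPair:
    """One mate pair: read 1 carries cell barcode + UMI, read 2 the cDNA."""

    read_id: str
    read1_seq: str
    read1_qual: str
    read2_seq: str
    read2_qual: str

    def __post_init__(self) -> None:
        if len(self.read1_seq) != len(self.read1_qual):
            raise ValueError(f"{self.read_id}: read1 sequence/quality length mismatch")
        if len(self.read2_seq) != len(self.read2_qual):
            raise ValueError(f"{self.read_id}: read2 sequence/quality length mismatch")


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _strip_read_id(title: str) -> str:
    """Canonical read id: drop the comment and a trailing /1 or /2."""
    rid = title.split()[0] if title else title
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> Iterator[ReadPair]:
    """Stream matched read pairs from two FASTQ files.

    Records are yielded in file order. Record counts must be equal and the
    ids must match pairwise (after suffix stripping); the first divergence
    is a hard error naming the offending record.
    """
    _SENTINEL = object()
    with _open_text(path_r1) as h1, _open_text(path_r2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        n = 0
        while True:
            n += 1
            try:
                rec1 = next(it1, _SENTINEL)
            except ValueError as err:
                raise ValueError(
                    f"{path_r1}: truncated FASTQ record near line {4 * (n - 1) + 1}: {err}"
                ) from err
            try:
                rec2 = next(it2, _SENTINEL)
            except ValueError as err:
                raise ValueError(
                    f"{path_r2}: truncated FASTQ record near line {4 * (n - 1) + 1}: {err}"
                ) from err
            if rec1 is _SENTINEL and rec2 is _SENTINEL:
                return
            if rec1 is _SENTINEL or rec2 is _SENTINEL:
                short = path_r1 if rec1 is _SENTINEL else path_r2
                present = rec2 if rec1 is _SENTINEL else rec1
                raise ValueError(
                    f"record count mismatch: {short} ends before record {n} "
                    f"(unpaired id {_strip_read_id(present[0])!r})"
                )
            t1, s1, q1 = rec1
            t2, s2, q2 = rec2
            id1, id2 = _strip_read_id(t1), _strip_read_id(t2)
            if id1 != id2:
                raise ValueError(
                    f"read id mismatch at record {n}: {id1!r} (R1) vs {id2!r} (R2)"
                )
            yield ReadPair(id1, s1.upper(), q1, s2.upper(), q2)


def write_fastq(records: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    """Write ``(read_id, seq, qual)`` records as FASTQ (gzip by extension)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:  # type: ignore[operator]
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


_ANNOT_REQUIRED = ("cell_id", "lineage", "compartment")


def read_cell_annotation(
    path: str | Path, lineages: Sequence[str] | None = None, hspc_label: str = "HSPC"
) -> pd.DataFrame:
    """Read the per-cell lineage annotation table.

    Required columns: ``cell_id``, ``lineage``, ``compartment`` (``HSPC`` or
    ``downstream``); optional ``qc_pass`` (default True) and ``doublet``
    (default False). Returns a DataFrame with an added boolean ``is_hspc``.
    When ``lineages`` is supplied, labels outside it (plus the HSPC label)
    are rejected. Duplicate cell ids are a hard error, as is a cell in the
    HSPC compartment whose lineage is not the HSPC label (and vice versa).
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "lineage": str, "compartment": str})
    missing = [c for c in _ANNOT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dup = df["cell_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate cell_id {df.loc[dup, 'cell_id'].iloc[0]!r}")
    bad_comp = ~df["compartment"].isin(["HSPC", "downstream"])
    if bad_comp.any():
        raise ValueError(
            f"{path}: compartment must be 'HSPC' or 'downstream', "
            f"got {df.loc[bad_comp, 'compartment'].iloc[0]!r}"
        )
    df["is_hspc"] = df["compartment"] == "HSPC"
    inconsistent = df["is_hspc"] != (df["lineage"] == hspc_label)
    if inconsistent.any():
        row = df[inconsistent].iloc[0]
        raise ValueError(
            f"{path}: cell {row['cell_id']!r} has lineage {row['lineage']!r} but "
            f"compartment {row['compartment']!r}"
        )
    if lineages is not None:
        allowed = set(lineages) | {hspc_label}
        unknown = ~df["lineage"].isin(allowed)
        if unknown.any():
            raise ValueError(
                f"{path}: unknown lineage label {df.loc[unknown, 'lineage'].iloc[0]!r}"
            )
    if "qc_pass" not in df.columns:
        df["qc_pass"] = True
    else:
        df["qc_pass"] = df["qc_pass"].astype(bool)
    if "doublet" not in df.columns:
        df["doublet"] = False
    else:
        df["doublet"] = df["doublet"].astype(bool)
    return df[["cell_id", "lineage", "compartment", "is_hspc", "qc_pass", "doublet"]]


def write_cell_annotation(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["cell_id", "lineage", "compartment", "qc_pass", "doublet"]
    df[cols].to_csv(path, sep="\t", index=False)


FATE_RESULT_COLUMNS = [
    "clone_tag",
    "n_hspc",
    "n_downstream_total",
    "O1",
    "O2",
    "output_value",
    "output_class",
    "m_value",
    "potency_class",
    "top_bias_lineage",
    "top_bias_score",
]


def write_fate_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write per-clone fate results as TSV, floats at 6 decimals for
    byte-stable output. An empty table produces a header-only file."""
    missing = [c for c in FATE_RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"fate results missing column(s) {missing}")
    results[FATE_RESULT_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_fate_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"clone_tag": str})
    missing = [c for c in FATE_RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df
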