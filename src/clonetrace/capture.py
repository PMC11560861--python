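"""Clone-tag capture from read pairs.

Each integrated lentiviral cassette carries a random 20-base clone tag
between two fixed anchor sequences. Capture slides both anchors over
read 2 at every ungapped offset (Hamming matching, no indels), requires
the gap between the anchor ends to equal the tag length, and applies
per-base quality control to the tag. Read 1 supplies the cell barcode
(bases 1-20) and the UMI (bases 21-30).

UMI collapse follows the one-mismatch rule: within a (cell, tag) group a
UMI one substitution away from a strictly better-supported UMI is merged
into it. Cells are then assigned their tag set, and cells carrying too
many tags are resolved: one tag stands alone, two or three tags are
concatenated into a composite clone id, four or more disqualify the cell.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .io_formats import ReadPair

__all__ = [
    "CaptureStatus",
    "Resolution",
    "ConstructSpec",
    "BarcodeCall",
    "CellCloneRecord",
    "CaptureStats",
    "locate_tag",
    "capture_read_pairs",
    "correct_umis",
    "assign_cells",
    "resolve_multibarcode",
]

CELL_BARCODE_LEN = 20
UMI_LEN = 10


class CaptureStatus(str, enum.Enum):
    CAPTURED = "captured"
    NO_ANCHOR = "no_anchor"
    BAD_LENGTH = "bad_length"
    LOW_QUALITY = "low_quality"
    AMBIGUOUS = "ambiguous"


class Resolution(str, enum.Enum):
    SINGLE = "single"
    MERGED = "merged"
    DROPPED = "dropped"


class ConstructSpec(BaseModel):
    """Layout of the barcoded cassette and capture thresholds.

    The anchors are the fixed sequences flanking the clone tag in the
    construct; they are experiment-specific inputs, never hard-coded.
    ``max_anchor_mismatches`` bounds the Hamming distance tolerated per
    anchor; ``min_tag_qual`` is the per-base Phred floor for tag bases;
    ``min_umi_support`` is the number of distinct (collapsed) UMIs a tag
    needs to be kept for a cell.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    upstream_anchor: str
    downstream_anchor: str
    tag_length: int = 20
    max_anchor_mismatches: int = 1
    min_tag_qual: int = 20
    min_umi_support: int = 1

    @field_validator("upstream_anchor", "downstream_anchor")
    @classmethod
    def _check_anchor(cls, v: str) -> str:
        v = v.upper()
        if len(v) < 12:
            raise ValueError("anchors must be at least 12 bases")
        if not set(v) <= set("ACGT"):
            raise ValueError("anchors must contain only A/C/G/T (no N)")
        return v

    @model_validator(mode="after")
    def _check_model(self) -> "ConstructSpec":
        if self.tag_length <= 0:
            raise ValueError("tag_length must be positive")
        if self.min_umi_support < 1:
            raise ValueError("min_umi_support must be >= 1")
        if self.min_tag_qual < 0:
            raise ValueError("min_tag_qual must be >= 0")
        shortest = min(len(self.upstream_anchor), len(self.downstream_anchor))
        if not 0 <= self.max_anchor_mismatches < shortest / 4:
            raise ValueError(
                "max_anchor_mismatches must be in [0, min(anchor length)/4)"
            )
        return self


@dataclass(frozen=True)
class BarcodeCall:
    """One captured (cell, UMI, clone tag) triple with read support."""

    cell_id: str
    umi: str
    clone_tag: Optional[str]
    read_support: int
    status: CaptureStatus

    def __post_init__(self) -> None:
        if (self.status is CaptureStatus.CAPTURED) != (self.clone_tag is not None):
            raise ValueError("clone_tag must be set iff status is captured")
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")


@dataclass
class CellCloneRecord:
    """Per-cell clone-tag assignment, before or after multi-tag resolution."""

    cell_id: str
    clone_tags: tuple[str, ...]
    umi_support: Mapping[str, int]
    merged_clone_id: Optional[str] = None
    resolution: Optional[Resolution] = None


@dataclass
class CaptureStats:
    reads_seen: int = 0
    short_read1: int = 0
    status_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "reads_seen": self.reads_seen,
            "short_read1": self.short_read1,
            "status_counts": {k: v for k, v in sorted(self.status_counts.items())},
        }


def _anchor_mismatch_profile(seq: str, anchor: str) -> np.ndarray:
    """Hamming mismatch count of ``anchor`` at every ungapped offset of ``seq``."""
    if len(seq) < len(anchor):
        return np.empty(0, dtype=np.int64)
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    a = np.frombuffer(anchor.encode("ascii"), dtype=np.uint8)
    windows = sliding_window_view(s, len(a))
    return (windows != a).sum(axis=1)


def locate_tag(
    read2_seq: str, read2_qual: str, spec: ConstructSpec
) -> tuple[Optional[str], CaptureStatus]:
    """Find the clone tag between the two anchors in one read-2 sequence.

    Every ungapped placement of each anchor with at most
    ``max_anchor_mismatches`` substitutions is considered; a valid pair of
    placements must leave a gap of exactly ``tag_length`` bases between the
    upstream anchor's end and the downstream anchor's start. Among valid
    pairs the lowest total mismatch count wins; ties yielding different
    tags are ambiguous. A captured tag must be N-free with every base at
    or above the Phred floor, else the read is low-quality.
    """
    seq = read2_seq.upper()
    lu = len(spec.upstream_anchor)
    max_mm = spec.max_anchor_mismatches
    up = _anchor_mismatch_profile(seq, spec.upstream_anchor)
    down = _anchor_mismatch_profile(seq, spec.downstream_anchor)
    up_hits = np.flatnonzero(up <= max_mm)
    down_hits = np.flatnonzero(down <= max_mm)
    if up_hits.size == 0 or down_hits.size == 0:
        return None, CaptureStatus.NO_ANCHOR

    down_ok = set(down_hits.tolist())
    best_total: Optional[int] = None
    best_tags: list[str] = []
    for i in up_hits.tolist():
        j = i + lu + spec.tag_length
        if j not in down_ok:
            continue
        total = int(up[i]) + int(down[j])
        if best_total is None or total < best_total:
            best_total = total
            best_tags = [seq[i + lu : j]]
        elif total == best_total:
            best_tags.append(seq[i + lu : j])
    if best_total is None:
        return None, CaptureStatus.BAD_LENGTH
    if len(set(best_tags)) > 1:
        return None, CaptureStatus.AMBIGUOUS

    # unique best tag; recover its coordinates for the quality check
    tag = best_tags[0]
    if "N" in tag:
        return None, CaptureStatus.LOW_QUALITY
    # quality of the tag bases at the (unique-tag) best placement
    for i in up_hits.tolist():
        j = i + lu + spec.tag_length
        if j in down_ok and int(up[i]) + int(down[j]) == best_total:
            quals = read2_qual[i + lu : j]
            break
    if any(ord(q) - 33 < spec.min_tag_qual for q in quals):
        return None, CaptureStatus.LOW_QUALITY
    return tag, CaptureStatus.CAPTURED


def capture_read_pairs(
    pairs: Iterable[ReadPair], spec: ConstructSpec
) -> tuple[list[BarcodeCall], CaptureStats]:
    """Run tag capture over a stream of read pairs.

    Captured reads are aggregated into one :class:`BarcodeCall` per
    (cell barcode, UMI, tag) with summed read support. Rejections are
    tallied in the returned :class:`CaptureStats` by status. Read-1
    records shorter than cell barcode + UMI are counted and skipped.
    """
    stats = CaptureStats()
    counts: dict[tuple[str, str, str], int] = defaultdict(int)
    min_r1 = CELL_BARCODE_LEN + UMI_LEN
    for pair in pairs:
        stats.reads_seen += 1
        if len(pair.read1_seq) < min_r1:
            stats.short_read1 += 1
            continue
        tag, status = locate_tag(pair.read2_seq, pair.read2_qual, spec)
        stats.status_counts[status.value] = stats.status_counts.get(status.value, 0) + 1
        if status is CaptureStatus.CAPTURED:
            cell = pair.read1_seq[:CELL_BARCODE_LEN]
            umi = pair.read1_seq[CELL_BARCODE_LEN:min_r1]
            counts[(cell, umi, tag)] += 1
    calls = [
        BarcodeCall(cell, umi, tag, n, CaptureStatus.CAPTURED)
        for (cell, umi, tag), n in sorted(counts.items())
    ]
    return calls, stats


def _hamming1(a: str, b: str) -> bool:
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > 1:
                return False
    return mismatches == 1


def correct_umis(calls: Sequence[BarcodeCall]) -> list[BarcodeCall]:
    """Collapse 1-mismatch UMIs onto the most supported UMI.

    Within each (cell, tag) group, UMIs are visited in descending order of
    read support (ties broken lexicographically). A UMI at Hamming
    distance 1 from an already-kept UMI with strictly greater original
    support is merged into it (the best-supported such target, ties
    lexicographic); total read support is conserved.
    """
    groups: dict[tuple[str, str], list[BarcodeCall]] = defaultdict(list)
    for call in calls:
        if call.status is not CaptureStatus.CAPTURED:
            raise ValueError("correct_umis expects captured calls only")
        groups[(call.cell_id, call.clone_tag)].append(call)

    out: list[BarcodeCall] = []
    for (cell, tag), group in sorted(groups.items()):
        support = {c.umi: c.read_support for c in group}
        order = sorted(support, key=lambda u: (-support[u], u))
        merged: dict[str, int] = {}  # canonical umi -> accumulated support
        for umi in order:
            candidates = [
                k for k in merged if support[k] > support[umi] and _hamming1(k, umi)
            ]
            if candidates:
                target = min(candidates, key=lambda u: (-support[u], u))
                merged[target] += support[umi]
            else:
                merged[umi] = support[umi]
        for umi in sorted(merged):
            out.append(BarcodeCall(cell, umi, tag, merged[umi], CaptureStatus.CAPTURED))
    return out


def assign_cells(
    calls: Sequence[BarcodeCall], spec: ConstructSpec
) -> list[CellCloneRecord]:
    """Group collapsed calls per cell and apply the UMI-support floor.

    A clone tag is retained for a cell when it is backed by at least
    ``spec.min_umi_support`` distinct UMIs. Cells retaining no tag yield
    no record (they are unbarcoded for downstream purposes).
    """
    per_cell: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for call in calls:
        if call.status is not CaptureStatus.CAPTURED:
            raise ValueError("assign_cells expects captured calls only")
        per_cell[call.cell_id][call.clone_tag] += 1  # one call per distinct UMI

    records = []
    for cell in sorted(per_cell):
        kept = {
            tag: n for tag, n in per_cell[cell].items() if n >= spec.min_umi_support
        }
        if kept:
            records.append(
                CellCloneRecord(
                    cell_id=cell,
                    clone_tags=tuple(sorted(kept)),
                    umi_support=dict(sorted(kept.items())),
                )
            )
    return records


def resolve_multibarcode(records: Sequence[CellCloneRecord]) -> list[CellCloneRecord]:
    """Resolve cells carrying multiple clone tags.

    One tag: the cell's clone id is the tag itself. Two or three tags: the
    tags are concatenated (sorted, "+"-joined) into a composite clone id
    treated downstream as an ordinary clone. Four or more tags: the cell
    is dropped as untraceable. Idempotent.
    """
    out = []
    for rec in records:
        n = len(rec.clone_tags)
        if n == 0:
            raise ValueError(f"cell {rec.cell_id!r} has no clone tags")
        if n == 1:
            out.append(
                replace(rec, merged_clone_id=rec.clone_tags[0], resolution=Resolution.SINGLE)
            )
        elif n <= 3:
            out.append(
                replace(
                    rec,
                    merged_clone_id="+".join(sorted(rec.clone_tags)),
                    resolution=Resolution.MERGED,
                )
            )
        else:
            out.append(replace(rec, merged_clone_id=None, resolution=Resolution.DROPPED))
    return out
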