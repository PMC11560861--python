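"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the stated rules with naive
data structures (pure-Python scans, no numpy, no shared helpers), so a
bug in the implementation cannot hide in its oracle.
"""

from __future__ import annotations

from collections import defaultdict


def brute_locate(
    seq: str,
    qual: str,
    upstream: str,
    downstream: str,
    tag_length: int,
    max_mm: int,
    min_qual: int,
) -> tuple[str | None, str]:
    """Exhaustive anchor scan: every offset, Hamming mismatch counting."""
    seq = seq.upper()

    def hits(anchor):
        out = []
        for i in range(len(seq) - len(anchor) + 1):
            mm = sum(a != b for a, b in zip(seq[i : i + len(anchor)], anchor))
            if mm <= max_mm:
                out.append((i, mm))
        return out

    ups = hits(upstream)
    downs = hits(downstream)
    if not ups or not downs:
        return None, "no_anchor"
    down_mm = dict(downs)
    pairs = []
    for i, mu in ups:
        j = i + len(upstream) + tag_length
        if j in down_mm:
            pairs.append((mu + down_mm[j], i))
    if not pairs:
        return None, "bad_length"
    best = min(p[0] for p in pairs)
    tags = []
    quals = []
    for total, i in pairs:
        if total == best:
            start = i + len(upstream)
            tags.append(seq[start : start + tag_length])
            quals.append(qual[start : start + tag_length])
    if len(set(tags)) > 1:
        return None, "ambiguous"
    tag, q = tags[0], quals[0]
    if "N" in tag or any(ord(c) - 33 < min_qual for c in q):
        return None, "low_quality"
    return tag, "captured"


def brute_umi_collapse(support: dict[str, int]) -> dict[str, int]:
    """One-mismatch UMI collapse by repeated literal application of the rule."""

    def hd(a, b):
        return sum(x != y for x, y in zip(a, b))

    orig = dict(support)
    order = sorted(orig, key=lambda u: (-orig[u], u))
    kept: dict[str, int] = {}
    for u in order:
        targets = [k for k in kept if orig[k] > orig[u] and hd(k, u) == 1]
        if targets:
            targets.sort(key=lambda k: (-orig[k], k))
            kept[targets[0]] += orig[u]
        else:
            kept[u] = orig[u]
    return kept


def brute_fate_tally(cells, lineages):
    """Recount the clone fate table with plain dict loops.

    ``cells`` is an iterable of (clone_id-or-None, lineage, is_hspc,
    qc_pass) tuples. Returns (clone -> {compartment: count}, hspc_total,
    lineage_totals).
    """
    clone_counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    hspc_total = 0
    lineage_totals = {lin: 0 for lin in lineages}
    for clone, lineage, is_hspc, qc_pass in cells:
        if not qc_pass:
            continue
        if is_hspc:
            hspc_total += 1
        else:
            lineage_totals[lineage] += 1
        if clone is not None and clone == clone and clone != "":  # NaN-safe
            key = "HSPC" if is_hspc else lineage
            clone_counts[clone][key] += 1
    return clone_counts, hspc_total, lineage_totals
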