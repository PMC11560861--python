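# Methods

## Tag capture model

Read 2 is assumed to contain the transcribed cassette
`…stuffer — upstream anchor — N20 tag — downstream anchor — stuffer…`
at an unknown offset. Capture slides each anchor over the read at every
ungapped offset and counts Hamming mismatches (an `N` in the read always
mismatches); placements with at most `max_anchor_mismatches`
substitutions (default 1) are candidates. A valid placement pair must
leave a gap of exactly `tag_length` bases (default 20) between the end
of the upstream anchor and the start of the downstream anchor. Among
valid pairs the lowest total mismatch count wins; ties that yield
different tag sequences are reported `ambiguous` rather than guessed.
A read with no candidate placement for either anchor is `no_anchor`;
candidates for both but no correctly spaced pair is `bad_length`; a
winning tag containing `N` or any base below `min_tag_qual` (default
Phred 20) is `low_quality`.

The matching model is deliberately substitution-only (no indels): it
keeps an exhaustive brute-force oracle cheap enough to check every read
in the tests, and cassette indels are rare relative to substitutions in
short-read data. Anchors are experiment-specific configuration — they
are never hard-coded, and the defaults shipped with the simulator are
synthetic 18-mers, not any real vector's flanks.

Cell barcode (read 1, bases 1–20) is taken as-is; whitelist correction
belongs to the upstream droplet-processing suite and is out of scope.
UMIs (bases 21–30) are collapsed within each (cell, tag) group: visiting
UMIs in descending read support (ties lexicographic), a UMI at Hamming
distance 1 from an already-kept UMI with strictly greater original
support merges into the best-supported such target. The procedure
conserves total read support and never increases the distinct-UMI count.
A tag is kept for a cell when backed by at least `min_umi_support`
distinct collapsed UMIs (default 1 — a single molecule is accepted,
since the capture already demands two anchor hits and clean tag bases).

Cells with one retained tag keep it as their clone id; cells with two
or three tags become one composite clone (tags sorted and "+"-joined) —
two-tag merging follows the tracing convention for doubly transduced
founders, and three-tag cells extend the same rule; cells with four or
more tags are dropped as untraceable. The resolution step is idempotent.

## Per-cell QC

Three conjunctive filters: (1) genes-per-cell inside
[Q1 − IQR, Q3 + IQR], with quartiles computed by linear interpolation
between order statistics (the "type 7" convention — the rule names no
method, so the common default is used and logged); removal is strict,
so boundary cells and degenerate (IQR = 0) distributions pass; (2)
mitochondrial fraction ≤ 0.10, strictly-greater removed; (3) doublet
flags, consumed as an input column (doublet detection is an external
tool's job). The gene fence is applied once to the whole table, not per
cluster. An identical fence on UMI counts exists but is off by default,
because the stated removal rule targets gene counts only.

## Fate statistics

Definitions as in the README. Numerical/denominator choices:

- "Downstream" means every QC-passed non-HSPC cell; D2's universe is
  the downstream compartment (parallel to O1's), not HSPC-inclusive.
- Denominators include non-barcoded cells: the statistics are shares of
  compartments, not shares of the barcoded subset. Both of these are
  deliberate readings of ambiguous prose; the run log records them.
- Output classes use strict inequalities with explicit `unclassified`
  for boundary/gap values ([0.4, 0.8] and [1.2, 2.0]) rather than
  nearest-bin assignment, so class membership is never an artifact of
  rounding.
- Statistics are defined for HSPC clones (≥ 1 HSPC cell); asking for a
  non-HSPC clone is an error, as is a bias score for a clone absent
  downstream (D2 = 0).
- Bias labels: the lymphoid/myeloid grouping is dataset configuration.
  A clone is labelled when its group-aggregated score (group counts in
  D1, group total as denominator) exceeds `threshold` (default 2.0)
  while the opposite group scores below 1; clones with fewer than
  `min_clone_cells` (default 10) downstream cells are unlabelled. No
  published cutoff exists for this call; the default demands 2-fold
  over-representation and is exposed in config.
- Ties for the top bias lineage break by lineage order, for
  determinism.
- The algebraic identity Σ_ℓ score_ℓ·(d_ℓ/D) = 1 (for D2 > 0) is tested
  to 1e-12 on every simulated dataset.

The transduction summary reports barcoded fractions per lineage and
their ratio to the global fraction ("subset bias", 1 under
lineage-independent transduction). The empty-loading rate
(vector-positive cells with no recoverable tag / vector-positive cells)
requires an explicit vector-positive flag — barcode absence alone
cannot distinguish empty loading from detection dropout — and is
reported as missing without one.

## Simulator

The generator emulates the counting universe of the statistics, not the
biology that produced it: output regimes are parameterized directly by
the expected output value rather than by birth–death rates, so recovery
tests map one-to-one onto the output classes.

Per clone: a unique random 20-mer tag (rejection-sampled against
collisions, mirroring a ~10⁶-tag library used well below saturation); a
regime drawn by share; an HSPC cell count `h` from the clone-size
distribution; a seeded-lineage count `m` from the potency distribution
(default weights proportional to m, reflecting pluripotency-dominated
grafts); a downstream count `d ~ Poisson(value · h · ρ)` floored at `m`,
where ρ = `downstream_per_hspc`; and a lineage allocation of one cell
per seeded lineage plus a Dirichlet-multinomial remainder
(`dirichlet_alpha`, default 5, optionally multiplied on one focal
lineage for biased clones).

Background: unbarcoded HSPC cells top the HSPC compartment up to
`unbarcoded_fraction` (default 0.8, matching a ~20% barcoded fraction
after QC in barcoded grafts), and unbarcoded downstream cells
(uniformly spread over lineages) top the downstream compartment up to
ρ·H (default ρ = 9, an HSPC compartment of ~10% of cells). Fixing the
downstream total at ρ·H makes each clone's expected output value equal
its regime target exactly. This is feasible only while the clones'
expected progeny fit, i.e. share-weighted mean output value ≤
1/(1 − `unbarcoded_fraction`); the simulator warns when a configuration
violates it (realized values then compress below target).

Detection dropout hides a barcoded cell's tag (the cell stays in the
table, unbarcoded for analysis) — it biases M downward and never adds
lineages, which the tests use as a monotonicity bound. Because every
seeded lineage receives at least one cell, zero dropout implies the
realized M equals the seeded count exactly.

Read emission inverts capture: read 1 = cell barcode + UMI (UMI and
read counts per cell from configurable distributions), read 2 = random
stuffer with the cassette at a random feasible offset (exercising
position invariance), constant Phred 40 qualities, and independent
per-base substitution errors per region (cell barcode / UMI / anchors /
tag) at configured rates, with realized error counts recorded per read
in the manifest so capture decisions can be audited read by read.

All randomness flows from a single integer seed through one
`numpy.random.Generator` (the read emitter derives a fixed offset from
it), and outputs are byte-identical across runs with the same seed.

What the simulator does not model: expression matrices (lineage labels
are taken as given, so annotation/clustering error is outside the
tests' scope), doublet transcriptomes, PCR chimeras, cassette indels,
and cell-barcode collisions with real whitelists. Passing recovery
tests therefore validate the capture/statistics machinery under the
stated noise model, not the upstream transcriptome processing.

## Validation study sizes

The test suite and `scripts/acceptance.py` use: ~10,000 read pairs for
the capture-vs-brute-force study (2% per-base anchor errors); 200
clones (~4,700 barcoded cells, ~12,000 reads) for the noiseless
round trip; 300 clones of 50–80 HSPC cells for output-class recovery;
150 clones for the potency/dropout study; and 250 clones (20% biased
with a 5× focal weight, ≥ 100 downstream cells scored) for bias
recovery. Biased clones are simulated as a minority because a
population dominated by clones biased toward the same lineage inflates
that lineage's total and deflates D1 for everyone — a composition
effect of the population, not a property of the score.

## Known limitations

- Anchor matching tolerates substitutions only; a single indel inside
  an anchor or tag loses the read (status, not error).
- Merged multi-tag clone ids are treated as ordinary clones downstream;
  if the same two founders were also captured separately in other
  cells, those are distinct clone ids.
- The IQR fence assumes a unimodal genes-per-cell distribution; strongly
  bimodal libraries would need per-population QC, which is out of scope.
- The empty-loading and transduction-rate definitions depend on an
  external vector-positive call; the package only does the counting.
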