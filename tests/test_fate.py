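import numpy as np
import pandas as pd
import pytest

from clonetrace import (
    CloneFateTable,
    OutputClass,
    OutputResult,
    PotencyClass,
    PotencyResult,
    bias_score,
    bias_scores,
    build_fate_table,
    call_bias,
    classify_output,
    compute_fate_results,
    label_pl_hspcs,
    m_value,
    output_value,
    subset_for_trajectory,
    transduction_summary,
)
from oracles import brute_fate_tally

NINE = tuple("L%d" % i for i in range(1, 10))


def make_table(clone_rows, lineages, hspc_total, lineage_totals):
    """Build a CloneFateTable directly from count dicts."""
    counts = pd.DataFrame(
        [
            {"clone_id": cid, "HSPC": row.get("HSPC", 0), **{l: row.get(l, 0) for l in lineages}}
            for cid, row in clone_rows.items()
        ]
    ).set_index("clone_id")
    return CloneFateTable(
        lineages=tuple(lineages),
        counts=counts[["HSPC", *lineages]].astype(int).sort_index(),
        hspc_total=hspc_total,
        lineage_totals=pd.Series(lineage_totals, index=list(lineages)).astype(int),
    )


class TestBuildFateTable:
    def test_toy_counts(self, toy_cells):
        table = build_fate_table(toy_cells, ["A", "B"])
        assert table.hspc_total == 10
        assert table.downstream_total == 100
        assert table.lineage_totals.tolist() == [50, 50]
        row = table.clone_row("X")
        assert row["HSPC"] == 2 and row["A"] == 30 and row["B"] == 10

    def test_unbarcoded_cells_enter_totals_only(self, toy_cells):
        table = build_fate_table(toy_cells, ["A", "B"])
        assert table.counts[["A", "B"]].to_numpy().sum() == 40 < table.downstream_total

    def test_qc_fail_cells_excluded(self, toy_cells):
        toy_cells.loc[toy_cells["cell_id"] == "d99", "qc_pass"] = False
        table = build_fate_table(toy_cells, ["A", "B"])
        assert table.downstream_total == 99

    def test_unknown_lineage_is_hard_error(self, toy_cells):
        toy_cells.loc[5, "lineage"] = "Mystery"
        toy_cells.loc[5, "is_hspc"] = False
        with pytest.raises(ValueError, match="Mystery"):
            build_fate_table(toy_cells, ["A", "B"])

    def test_matches_bruteforce_tally_on_simulation(self, small_truth):
        cells = small_truth.analysis_frame()
        table = build_fate_table(cells, small_truth.config.lineages)
        tally, hspc_total, lin_totals = brute_fate_tally(
            cells[["clone_id", "lineage", "is_hspc", "qc_pass"]].itertuples(index=False),
            small_truth.config.lineages,
        )
        assert table.hspc_total == hspc_total
        assert table.lineage_totals.to_dict() == lin_totals
        assert set(table.clone_ids) == set(tally)
        for cid in table.clone_ids:
            row = table.clone_row(cid)
            for comp in ["HSPC", *small_truth.config.lineages]:
                assert int(row[comp]) == tally[cid].get(comp, 0), (cid, comp)


class TestOutputValue:
    def test_arithmetic(self):
        table = make_table(
            {"X": {"HSPC": 5, "L1": 30}}, ["L1"], hspc_total=50, lineage_totals={"L1": 200}
        )
        res = output_value("X", table)
        assert res.O1 == pytest.approx(30 / 200)
        assert res.O2 == pytest.approx(5 / 50)
        assert res.output_value == pytest.approx(1.5)
        assert res.output_class is OutputClass.UNCLASSIFIED  # 1.5 in the (1.2, 2.0] gap

    def test_boundary_value_two_is_unclassified(self):
        table = make_table(
            {"X": {"HSPC": 2, "L1": 40}}, ["L1"], hspc_total=10, lineage_totals={"L1": 100}
        )
        res = output_value("X", table)
        assert res.output_value == pytest.approx(2.0)
        assert res.output_class is OutputClass.UNCLASSIFIED

    def test_hspc_only_clone_has_zero_output(self):
        table = make_table(
            {"X": {"HSPC": 3}}, ["L1"], hspc_total=10, lineage_totals={"L1": 100}
        )
        res = output_value("X", table)
        assert res.O1 == 0 and res.output_value == 0
        assert res.output_class is OutputClass.LOW

    def test_non_hspc_clone_is_an_error(self):
        table = make_table(
            {"X": {"L1": 5}}, ["L1"], hspc_total=10, lineage_totals={"L1": 100}
        )
        with pytest.raises(ValueError, match="not an HSPC clone"):
            output_value("X", table)
        with pytest.raises(ValueError, match="not an HSPC clone"):
            m_value("X", table)


@pytest.mark.parametrize(
    "value,expected",
    [
        (0.0, "low"),
        (0.39, "low"),
        (0.4, "unclassified"),
        (0.8, "unclassified"),
        (1.0, "med"),
        (1.2, "unclassified"),
        (2.0, "unclassified"),
        (2.5, "high"),
    ],
)
def test_output_class_boundaries_are_strict(value, expected):
    assert classify_output(value).value == expected


def test_negative_output_value_rejected():
    with pytest.raises(ValueError):
        classify_output(-0.1)


class TestPotency:
    def _table(self, present):
        row = {"HSPC": 1, **{l: 1 for l in present}}
        return make_table({"X": row}, NINE, 20, {l: 10 for l in NINE})

    @pytest.mark.parametrize(
        "n_lineages,cls",
        [(9, PotencyClass.PLURIPOTENT), (1, PotencyClass.UNIPOTENT),
         (3, PotencyClass.MULTIPOTENT), (8, PotencyClass.MULTIPOTENT),
         (0, PotencyClass.NONE)],
    )
    def test_m_value_classes(self, n_lineages, cls):
        res = m_value("X", self._table(NINE[:n_lineages]))
        assert res.m_value == n_lineages
        assert res.potency_class is cls

    def test_output_zero_iff_m_zero(self, small_truth):
        from clonetrace import build_fate_table

        table = build_fate_table(small_truth.analysis_frame(), small_truth.config.lineages)
        for cid in table.clone_ids:
            if int(table.clone_row(cid)["HSPC"]) < 1:
                continue
            out = output_value(cid, table)
            pot = m_value(cid, table)
            assert (out.output_value == 0) == (pot.m_value == 0)


class TestBias:
    def test_arithmetic(self):
        lins = ["A", "B"]
        table = make_table(
            {"X": {"HSPC": 1, "A": 30, "B": 20}},
            lins,
            hspc_total=10,
            lineage_totals={"A": 900, "B": 100},
        )
        res = bias_score("X", "B", table)
        assert res.D1 == pytest.approx(20 / 100)
        assert res.D2 == pytest.approx(50 / 1000)
        assert res.score == pytest.approx(4.0)

    def test_proportional_clone_scores_one_everywhere(self):
        lins = ["A", "B", "C"]
        table = make_table(
            {"X": {"HSPC": 1, "A": 6, "B": 3, "C": 1}},
            lins,
            hspc_total=5,
            lineage_totals={"A": 60, "B": 30, "C": 10},
        )
        for lin in lins:
            assert bias_score("X", lin, table).score == pytest.approx(1.0)

    def test_absent_lineage_scores_zero(self):
        table = make_table(
            {"X": {"HSPC": 1, "A": 5}}, ["A", "B"], 10, {"A": 50, "B": 50}
        )
        assert bias_score("X", "B", table).score == 0.0

    def test_clone_absent_downstream_is_error(self):
        table = make_table({"X": {"HSPC": 2}}, ["A"], 10, {"A": 50})
        with pytest.raises(ValueError, match="absent downstream"):
            bias_score("X", "A", table)

    def test_weighted_normalization_identity(self, small_truth):
        table = build_fate_table(small_truth.analysis_frame(), small_truth.config.lineages)
        weights = table.lineage_totals / table.downstream_total
        for cid in table.clone_ids:
            if int(table.clone_row(cid)[list(table.lineages)].sum()) == 0:
                continue
            sc = bias_scores(cid, table)
            total = float((sc["score"].values * weights.values).sum())
            assert abs(total - 1.0) < 1e-12, cid


class TestCallBias:
    GROUPS = {"lymphoid": ["A", "B"], "myeloid": ["C", "D"]}

    def _table(self, rows):
        return make_table(
            rows, ["A", "B", "C", "D"], 10, {"A": 100, "B": 100, "C": 100, "D": 100}
        )

    def test_pure_lymphoid_clone_labelled(self):
        table = self._table({"X": {"HSPC": 1, "A": 10, "B": 10}})
        labels = call_bias(table, self.GROUPS, threshold=1.0, min_clone_cells=10)
        assert labels["X"] == "lymphoid"

    def test_proportional_clone_is_none(self):
        table = self._table({"X": {"HSPC": 1, "A": 5, "B": 5, "C": 5, "D": 5}})
        assert call_bias(table, self.GROUPS, 2.0, 10)["X"] == "none"

    def test_small_clones_are_none(self):
        table = self._table({"X": {"HSPC": 1, "A": 3}})
        assert call_bias(table, self.GROUPS, 2.0, min_clone_cells=10)["X"] == "none"

    def test_incomplete_grouping_is_error(self):
        table = self._table({"X": {"HSPC": 1, "A": 5}})
        with pytest.raises(ValueError, match="partition"):
            call_bias(table, {"lymphoid": ["A"], "myeloid": ["C", "D"]}, 2.0, 1)


class TestPLHspcsAndSubsets:
    def _results(self, combos):
        outs, pots = [], []
        for cid, (ocls, pcls) in combos.items():
            outs.append(OutputResult(cid, 0.1, 0.1, 1.0, ocls))
            pots.append(PotencyResult(cid, 9, pcls))
        return outs, pots

    def test_definition(self):
        outs, pots = self._results(
            {
                "a": (OutputClass.LOW, PotencyClass.PLURIPOTENT),
                "b": (OutputClass.MED, PotencyClass.PLURIPOTENT),
                "c": (OutputClass.HIGH, PotencyClass.PLURIPOTENT),
                "d": (OutputClass.MED, PotencyClass.MULTIPOTENT),
                "e": (OutputClass.UNCLASSIFIED, PotencyClass.PLURIPOTENT),
            }
        )
        assert label_pl_hspcs(outs, pots) == {"a", "b"}

    def test_mismatched_clone_sets_error(self):
        outs, pots = self._results({"a": (OutputClass.LOW, PotencyClass.PLURIPOTENT)})
        with pytest.raises(ValueError):
            label_pl_hspcs(outs, pots[:0])

    def test_subset_for_trajectory_counts(self):
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(6)],
                "clone_id": ["X", "X", "Y", None, "X", "Y"],
            }
        )
        labels = pd.Series({"X": "lymphoid", "Y": "none"}).rename_axis("clone_id")
        assert subset_for_trajectory(cells, labels, "lymphoid") == ["c0", "c1", "c4"]
        assert subset_for_trajectory(cells, labels, "myeloid") == []


class TestTransduction:
    def _cells(self, clone_ids, lineages):
        return pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(len(clone_ids))],
                "clone_id": clone_ids,
                "lineage": lineages,
                "qc_pass": True,
            }
        )

    def test_all_barcoded_gives_unit_bias(self):
        cells = self._cells(["X"] * 10, ["A"] * 5 + ["B"] * 5)
        summary = transduction_summary(cells)
        assert summary.barcoded_fraction == 1.0
        assert all(v == 1.0 for v in summary.subset_bias.values())

    def test_subset_bias_arithmetic(self):
        # 40/100 barcoded globally; subset B: 4/10 barcoded -> bias 1.0
        clone = ["X"] * 36 + [None] * 54 + ["X"] * 4 + [None] * 6
        lineage = ["A"] * 90 + ["B"] * 10
        summary = transduction_summary(self._cells(clone, lineage))
        assert summary.barcoded_fraction == pytest.approx(0.4)
        assert summary.subset_bias["B"] == pytest.approx(1.0)

    def test_empty_loading_rate_needs_flags(self):
        cells = self._cells(["X", None, None, None], ["A"] * 4)
        assert transduction_summary(cells).empty_loading_rate is None
        vp = pd.Series([True, True, False, False])
        summary = transduction_summary(cells, vector_positive=vp)
        assert summary.empty_loading_rate == pytest.approx(0.5)

    def test_zero_vector_positive_reported_missing(self):
        cells = self._cells(["X", None], ["A", "A"])
        vp = pd.Series([False, False])
        assert transduction_summary(cells, vp).empty_loading_rate is None

    def test_lineage_independent_labelling_bias_near_one(self):
        rng = np.random.default_rng(21)
        n = 4000
        lineage = rng.choice(["A", "B", "C", "D"], size=n)
        barcoded = rng.random(n) < 0.3
        clone = np.where(barcoded, "X", None)
        summary = transduction_summary(self._cells(clone.tolist(), lineage.tolist()))
        p = summary.barcoded_fraction
        for lin, frac in summary.subset_barcoded_fraction.items():
            n_lin = int((lineage == lin).sum())
            ci = 3 * np.sqrt(p * (1 - p) / n_lin)
            assert abs(frac - p) < ci, lin


class TestDropoutMonotonicity:
    def test_removing_downstream_cells_never_increases_o1_or_m(self, small_truth):
        cells = small_truth.analysis_frame()
        table = build_fate_table(cells, small_truth.config.lineages)
        rng = np.random.default_rng(9)
        # hide 30% of downstream clone cells (dropout), recount
        mask = cells["clone_id"].notna() & ~cells["is_hspc"] & (rng.random(len(cells)) < 0.3)
        degraded = cells.copy()
        degraded.loc[mask, "clone_id"] = None
        table2 = build_fate_table(degraded, small_truth.config.lineages)
        for cid in table2.clone_ids:
            if int(table2.clone_row(cid)["HSPC"]) < 1:
                continue
            assert output_value(cid, table2).O1 <= output_value(cid, table).O1 + 1e-15
            assert m_value(cid, table2).m_value <= m_value(cid, table).m_value


def test_compute_fate_results_matches_per_clone_calls(small_truth):
    table = build_fate_table(small_truth.analysis_frame(), small_truth.config.lineages)
    results = compute_fate_results(table)
    hspc_clones = [c for c in table.clone_ids if int(table.clone_row(c)["HSPC"]) >= 1]
    assert results["clone_tag"].tolist() == hspc_clones
    for _, row in results.iterrows():
        out = output_value(row["clone_tag"], table)
        pot = m_value(row["clone_tag"], table)
        assert row["output_value"] == pytest.approx(out.output_value)
        assert row["output_class"] == out.output_class.value
        assert row["m_value"] == pot.m_value
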