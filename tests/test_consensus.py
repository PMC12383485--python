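import json

import numpy as np
import pandas as pd
import pytest

from refstab import (
    MethodRanks,
    WorkflowConfig,
    abundance_filter,
    aggregate_ranks,
    coregulation_filter,
    default_3t3l1_config,
    render_report,
    run_workflow,
    simulate_ct,
)
from refstab.bestkeeper import IndexRegression, TargetCorrelation
from refstab.genorm import StabilityThresholds

from conftest import make_table


def ranks_frame(data):
    return MethodRanks(pd.DataFrame(data).T.astype(float))


class TestAggregateRanks:
    def test_unanimous_first_place_gives_exactly_one(self):
        mr = ranks_frame({"hprt": [1, 1, 1, 1], "x": [2, 2, 2, 2]})
        res = aggregate_ranks(mr)
        assert res.geomean_rank["hprt"] == 1.0
        assert res.order[0] == "hprt"

    def test_constant_ranks_pass_through(self):
        mr = ranks_frame({"a": [2, 2, 2, 2], "b": [1, 1, 1, 1]})
        assert aggregate_ranks(mr).geomean_rank["a"] == pytest.approx(2.0)

    def test_mixed_ranks_hand_geometric_mean(self):
        mr = ranks_frame({"a": [1, 2, 2, 4], "b": [1, 1, 1, 1]})
        assert aggregate_ranks(mr).geomean_rank["a"] == pytest.approx(2.0)

    def test_geomean_one_only_for_unanimous_winner(self):
        mr = ranks_frame({"a": [1, 1, 2, 1], "b": [2, 2, 1, 2]})
        assert aggregate_ranks(mr).geomean_rank["a"] > 1.0

    def test_missing_method_skipped(self):
        mr = ranks_frame({"a": [1, np.nan, 2, 4], "b": [2, np.nan, 1, 1]})
        geo = aggregate_ranks(mr).geomean_rank
        assert geo["a"] == pytest.approx((1 * 2 * 4) ** (1 / 3))


class TestAbundanceFilter:
    @staticmethod
    def _table(gap):
        n = 6
        rng = np.random.default_rng(0)
        hkg = 20 + rng.normal(0, 0.1, n)
        other = 22 + rng.normal(0, 0.1, n)
        tgt = hkg.mean() + gap + rng.normal(0, 0.1, n) - 0.0
        tgt = tgt - (tgt.mean() - (hkg.mean() + gap))  # pin the exact gap
        return make_table(
            np.column_stack([hkg, other, tgt]), ["hkg", "other", "tgt"],
            ["g"] * n, target="tgt",
        )

    def test_wide_gap_excluded(self):
        res = abundance_filter(self._table(7.5))
        assert not res.at["hkg", "passed"]

    def test_boundary_gap_retained(self):
        res = abundance_filter(self._table(5.0))
        assert res.at["hkg", "passed"]
        assert res.at["hkg", "gap_cycles"] == pytest.approx(5.0, abs=1e-9)

    def test_zero_gap_retained(self):
        res = abundance_filter(self._table(0.0))
        assert res.at["hkg", "passed"]


class TestCoregulationFilter:
    @staticmethod
    def _inputs(r, p, slope):
        corr = TargetCorrelation(
            pd.DataFrame({"a": {"r": r, "p_value": p}}), "tgt"
        )
        reg = IndexRegression(
            pd.DataFrame({"a": {"r": 0.8, "r_squared": 0.64, "intercept": 0.0,
                                "slope": slope, "slope_se": 0.1, "p_value": 0.001}})
        )
        return corr, reg

    def test_strong_significant_correlation_excluded(self):
        res = coregulation_filter(*self._inputs(0.759, 0.001, 1.0))
        assert not res.at["a", "passed"]

    def test_null_correlation_retained(self):
        res = coregulation_filter(*self._inputs(-0.002, 0.992, 1.0))
        assert res.at["a", "passed"]

    def test_moderate_correlation_retained(self):
        res = coregulation_filter(*self._inputs(0.512, 0.001, 1.0))
        assert res.at["a", "passed"]

    def test_divergent_slope_flagged_not_excluded(self):
        res = coregulation_filter(*self._inputs(0.3, 0.1, 1.31))
        assert res.at["a", "slope_divergence"]
        assert res.at["a", "passed"]


class TestWorkflow:
    def test_stressed_panel_excludes_the_confounded_genes(self, stressed_panel):
        report = run_workflow(stressed_panel)
        assert report.status == "ok"
        assert "18S" not in report.survivors
        assert "GAPDH" not in report.survivors
        assert set(report.best_triplet) == {"HPRT", "36B4", "HMBS"}
        steps = {e["gene"]: e["step"] for e in report.decision_log
                 if e.get("action") == "excluded"}
        assert steps["18S"] == 2

    def test_identical_stable_copies_no_exclusions(self):
        profile = np.array([20.0, 20.1, 20.2, 20.0, 20.1, 20.2])
        t = make_table(
            np.column_stack([profile] * 4), list("abcd"),
            ["g1"] * 3 + ["g2"] * 3,
        )
        report = run_workflow(t)
        assert report.survivors == list("abcd")
        assert report.consensus.order == list("abcd")  # tie-break = input order

    def test_all_candidates_too_abundant_insufficient(self):
        rng = np.random.default_rng(2)
        cols = [10 + rng.normal(0, 0.1, 6) for _ in range(3)]
        tgt = 30 + rng.normal(0, 0.1, 6)
        t = make_table(
            np.column_stack(cols + [tgt]), ["a", "b", "c", "tgt"],
            ["g1"] * 3 + ["g2"] * 3, target="tgt",
        )
        report = run_workflow(t)
        assert report.status == "insufficient stable genes"
        assert report.survivors == []
        assert report.best_triplet is None

    def test_invariant_to_gene_and_sample_order(self, stressed_panel):
        report = run_workflow(stressed_panel)
        shuffled = stressed_panel.ct.iloc[::-1, ::-1]
        t2 = make_table(
            shuffled.to_numpy(), list(shuffled.columns),
            list(stressed_panel.groups.iloc[::-1]),
            target="PPARG", sample_ids=list(shuffled.index),
        )
        report2 = run_workflow(t2)
        assert set(report.survivors) == set(report2.survivors)
        assert report.best_gene == report2.best_gene
        assert set(report.best_triplet) == set(report2.best_triplet)

    def test_survivor_consistency_after_removing_excluded(self, stressed_panel):
        report = run_workflow(stressed_panel)
        excluded = [g for g in stressed_panel.candidate_genes
                    if g not in report.survivors]
        keep = [g for g in stressed_panel.genes if g not in excluded]
        report2 = run_workflow(stressed_panel.subset(keep))
        assert report2.best_gene == report.best_gene
        assert report2.best_pair == report.best_pair
        assert report2.best_triplet == report.best_triplet

    def test_custom_threshold_config_respected(self, stressed_panel):
        thr = StabilityThresholds(abundance_gap_cycles=20.0, coregulation_r=0.999)
        report = run_workflow(stressed_panel, WorkflowConfig(thresholds=thr))
        assert "18S" in report.survivors  # gap filter relaxed
        assert "Actb" in report.survivors  # co-regulation filter relaxed


class TestRendering:
    def test_bundle_written_and_json_loads(self, tmp_path, stressed_panel):
        report = run_workflow(stressed_panel)
        written = render_report(report, tmp_path, formats=("md", "json", "csv"))
        names = {p.name for p in written}
        assert {"report.md", "report.json", "consensus.csv"} <= names
        data = json.loads((tmp_path / "report.json").read_text())
        assert data["best_gene"] == report.best_gene
        assert data["status"] == "ok"

    def test_markdown_has_a_section_per_method(self, tmp_path, stressed_panel):
        report = run_workflow(stressed_panel)
        render_report(report, tmp_path, formats=("md",))
        text = (tmp_path / "report.md").read_text()
        for title in ["geNorm", "NormFinder", "BestKeeper", "ΔCt", "ANOVA",
                      "Decision log"]:
            assert title in text

    def test_csv_round_trip_matches_in_memory(self, tmp_path, stressed_panel):
        report = run_workflow(stressed_panel)
        render_report(report, tmp_path, formats=("csv",))
        back = pd.read_csv(tmp_path / "consensus.csv", index_col=0)
        pd.testing.assert_frame_equal(
            back, report.consensus.to_frame(), atol=1e-12, rtol=0,
            check_dtype=False,
        )

    def test_chart_rendered(self, tmp_path, stressed_panel):
        report = run_workflow(stressed_panel)
        written = render_report(report, tmp_path, formats=("png",))
        assert (tmp_path / "consensus_ranking.png").exists()
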