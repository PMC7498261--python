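"""Network summaries: counts, hubs, unions, NPS subset, contrasts."""

import numpy as np
import pandas as pd
import pytest

import painconn as pc
from painconn import lmm, report as report_mod
from painconn.permutation import NullDistribution, SignificanceReport


def make_report(edge_list, significant, condition="counting", t_values=None):
    """Construct a SignificanceReport from explicit edge and flag lists."""
    n = len(edge_list)
    t = np.asarray(
        t_values if t_values is not None else [-5.0] * n, dtype=float
    )
    edges = pd.DataFrame(
        {
            "region_a": [a for a, _ in edge_list],
            "region_b": [b for _, b in edge_list],
            "beta": t,
            "se": np.ones(n),
            "t": t,
            "skipped": [False] * n,
            "attenuation_encoding": t < 0,
            "p_corrected": np.where(significant, 0.01, 0.5),
            "significant": list(significant),
        }
    )
    return SignificanceReport(
        edges=edges, threshold_t=3.0, alpha=0.05, n_perms=100,
        model="M1", condition=condition,
    )


class TestCounting:
    def test_empty_report_all_zeros(self):
        rep = make_report([("a", "b"), ("a", "c")], [False, False])
        assert pc.count_significant(rep) == {
            "total": 0, "attenuation_encoding": 0, "opposite_sign": 0,
        }

    def test_sign_counts_sum_to_total(self):
        rng = np.random.default_rng(30)
        edges = [(f"r{i}", f"q{i}") for i in range(20)]
        sig = rng.random(20) < 0.4
        t = rng.normal(0, 4, 20)
        counts = pc.count_significant(make_report(edges, sig, t_values=t))
        assert counts["attenuation_encoding"] + counts["opposite_sign"] == counts["total"]
        assert counts["total"] == int(sig.sum())


class TestHubs:
    def test_star_graph_single_hub(self):
        edges = [("hub", f"leaf{i}") for i in range(5)]
        rep = make_report(edges, [True] * 5)
        hubs = pc.hub_regions(rep, min_degree=3)
        assert hubs.iloc[0]["region"] == "hub"
        assert hubs.iloc[0]["degree"] == 5
        assert hubs["hub"].sum() == 1

    def test_min_degree_one_lists_every_touched_region(self):
        edges = [("a", "b"), ("c", "d")]
        rep = make_report(edges, [True, True])
        hubs = pc.hub_regions(rep, min_degree=1)
        assert set(hubs.loc[hubs["hub"], "region"]) == {"a", "b", "c", "d"}

    def test_handshake_lemma_on_random_reports(self):
        rng = np.random.default_rng(31)
        regions = [f"r{i}" for i in range(12)]
        for _ in range(10):
            edges = []
            for i in range(len(regions)):
                for j in range(i + 1, len(regions)):
                    edges.append((regions[i], regions[j]))
            sig = rng.random(len(edges)) < 0.3
            rep = make_report(edges, sig)
            hubs = pc.hub_regions(rep, min_degree=3)
            assert hubs["degree"].sum() == 2 * int(sig.sum())


class TestCrossCondition:
    def test_identical_reports_union_unchanged(self):
        edges = [("hub", f"leaf{i}") for i in range(4)]
        rep = make_report(edges, [True] * 4)
        union = pc.cross_condition_union({"a": rep, "b": rep}, min_degree=3)
        assert union == ["hub"]

    def test_disjoint_hub_sets_add_up(self):
        rep1 = make_report([("h1", f"x{i}") for i in range(3)], [True] * 3, "c1")
        rep2 = make_report([("h2", f"y{i}") for i in range(3)], [True] * 3, "c2")
        union = pc.cross_condition_union({"c1": rep1, "c2": rep2})
        assert union == ["h1", "h2"]

    def test_empty_reports_give_empty_union(self):
        rep = make_report([("a", "b")], [False])
        assert pc.cross_condition_union({"c": rep}) == []

    def test_conjunction_of_disjoint_sets_is_empty(self):
        rep1 = make_report([("a", "b"), ("c", "d")], [True, False], "c1")
        rep2 = make_report([("a", "b"), ("c", "d")], [False, True], "c2")
        conj = report_mod.conjunction_edges({"c1": rep1, "c2": rep2})
        assert conj.empty


class TestNps:
    def test_two_region_set_averages_single_edge(self, planted_tensor, planted_sim):
        atlas = pc.ParcelAtlas.simple(8, nps=["r001", "r002"])
        res = pc.nps_trial_analysis(planted_tensor, atlas, "counting")
        assert res.n_edges == 1
        k = planted_tensor.edge_index.index_of("r001", "r002")
        rows = lmm.select_condition_rows(
            planted_tensor.trials, "counting", "unmodulated"
        )
        np.testing.assert_allclose(
            res.per_trial["mean_z"].to_numpy(), planted_tensor.z[rows, k]
        )

    def test_planted_negative_coupling_detected(self, planted_tensor):
        atlas = pc.ParcelAtlas.simple(8, nps=["r001", "r002", "r005"])
        res = pc.nps_trial_analysis(planted_tensor, atlas, "counting")
        assert res.beta < 0
        assert abs(res.tstat) > 2
        assert res.p_uncorrected < 0.05

    def test_all_regions_equals_grand_mean_analysis(self, planted_tensor):
        atlas = pc.ParcelAtlas.simple(8, nps=[f"r{i+1:03d}" for i in range(8)])
        res = pc.nps_trial_analysis(planted_tensor, atlas, "counting")
        rows = lmm.select_condition_rows(
            planted_tensor.trials, "counting", "unmodulated"
        )
        np.testing.assert_allclose(
            res.per_trial["mean_z"].to_numpy(),
            np.nanmean(planted_tensor.z[rows], axis=1),
        )

    def test_single_flagged_region_rejected(self, planted_tensor):
        atlas = pc.ParcelAtlas.simple(8, nps=["r001"])
        with pytest.raises(ValueError, match="at least 2"):
            pc.nps_trial_analysis(planted_tensor, atlas, "counting")


class TestConditionContrast:
    def test_unique_edges_concentrate_in_stronger_condition(self):
        # one condition's interaction stats carry a planted boost; the
        # contrast report should flag edges only for that condition
        stats = {}
        nulls = {}
        rng = np.random.default_rng(5)
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        for cond, boost in (("counting", 8.0), ("safeplace", 0.0)):
            t = rng.normal(0, 1, 3)
            if boost:
                t[0] += boost
            frame = pd.DataFrame(
                {
                    "region_a": [p[0] for p in pairs],
                    "region_b": [p[1] for p in pairs],
                    "beta": t, "se": np.ones(3), "t": t,
                    "skipped": [False] * 3,
                    "attenuation_encoding": t < 0,
                }
            )
            stats[cond] = frame
            nulls[cond] = NullDistribution(
                condition=cond, model="M2",
                max_abs_t=np.abs(rng.standard_normal(199)),
                n_perms=199, seed=1,
            )
        out = pc.condition_contrast_report(stats, nulls, alpha=0.05)
        assert out["unique_counts"]["counting"] >= 1
        assert out["unique_counts"]["safeplace"] == 0
        sig_count = out["unique_edges"]["counting"]
        assert ("a", "b") in set(zip(sig_count["region_a"], sig_count["region_b"]))


class TestMatrices:
    def test_signed_matrix_mirrored(self):
        rep = make_report(
            [("a", "b"), ("b", "c")], [True, True], t_values=[-4.0, 4.0]
        )
        mat = pc.significance_matrix(rep)
        assert mat.loc["a", "b"] == 1 and mat.loc["b", "a"] == 1
        assert mat.loc["b", "c"] == -1 and mat.loc["c", "b"] == -1
        assert (np.diag(mat.to_numpy()) == 0).all()

    def test_recomputable_from_serialized_artifacts(self, planted_tensor, tmp_path):
        # reports must be a pure function of EdgeStats + NullDistribution
        from painconn import io

        stats_df = lmm.mass_fit(planted_tensor, model="M1", condition="counting")
        null = pc.build_null(
            planted_tensor, model="M1", condition="counting", n_perms=60, seed=2
        )
        io.write_edge_stats(stats_df, tmp_path / "stats.tsv")
        io.write_null(null, tmp_path / "null.tsv")
        stats2 = io.read_edge_stats(tmp_path / "stats.tsv")
        null2 = io.read_null(tmp_path / "null.tsv")
        rep1 = pc.corrected_pvalues(stats_df, null)
        rep2 = pc.corrected_pvalues(stats2, null2)
        assert rep1.edges["significant"].equals(rep2.edges["significant"])
        assert pc.count_significant(rep1) == pc.count_significant(rep2)
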