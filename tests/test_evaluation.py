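import numpy as np
import pytest

from normrank.counts_io import GeneList
from normrank.de_test import DEResult
from normrank.evaluation import (
    CRITERION_DIRECTIONS,
    ControlPanel,
    EvaluationError,
    common_deg_matrix,
    intersect_all,
    loocv_prediction_errors,
    method_rank_dendrogram,
    select_informative_genes,
    sensitivity_specificity,
    summarize_ranks,
)


def gl(*ids, role="generic"):
    return GeneList(tuple(ids), role=role)


def de_result(gene_ids, adj_p, method="TMM", alpha=0.05):
    adj = np.asarray(adj_p, dtype=float)
    return DEResult(
        gene_ids=list(gene_ids),
        log2_fold_change=np.zeros(len(adj)),
        p_value=adj,
        base_mean=np.ones(len(adj)),
        method=method,
        adj_p_value=adj,
        is_deg=adj < alpha,
        alpha=alpha,
    )


class TestSensitivitySpecificity:
    panel = ControlPanel(
        positives=gl(*[f"p{i}" for i in range(44)], role="positive_control"),
        negatives=gl(*[f"n{i}" for i in range(44)], role="negative_control"),
    )

    def test_all_positives_found(self):
        sens, spec = sensitivity_specificity(
            gl(*[f"p{i}" for i in range(44)]), self.panel
        )
        assert sens == 100.0 and spec == 100.0

    def test_five_of_fortyfour(self):
        degs = gl(*[f"p{i}" for i in range(5)], "x1", "x2")
        sens, spec = sensitivity_specificity(degs, self.panel)
        assert sens == pytest.approx(100 * 5 / 44)
        assert round(sens, 1) == 11.4
        assert spec == 100.0

    def test_negatives_in_degs_cut_specificity(self):
        degs = gl("n0", "n1", "other")
        _, spec = sensitivity_specificity(degs, self.panel)
        assert spec == pytest.approx(100 * 42 / 44)

    def test_invariant_to_non_panel_genes(self, rng):
        degs = gl("p0", "n3", *[f"z{i}" for i in range(30)])
        fewer = gl("p0", "n3")
        assert sensitivity_specificity(degs, self.panel) == sensitivity_specificity(
            fewer, self.panel
        )

    def test_overlapping_panel_rejected(self):
        with pytest.raises(EvaluationError, match="overlap"):
            ControlPanel(gl("a", "b"), gl("b", "c"))


class TestInformativeGenes:
    @pytest.mark.parametrize("n_samples,expected", [(41, 30), (16, 12), (27, 20)])
    def test_seventyfive_percent_floored(self, n_samples, expected):
        de = de_result([f"g{i}" for i in range(40)], np.linspace(0, 1, 40))
        assert len(select_informative_genes(de, n_samples)) == expected

    def test_top_genes_by_adjusted_p(self):
        de = de_result(["a", "b", "c", "d"], [0.4, 0.01, 0.2, 0.01])
        got = select_informative_genes(de, 4, fraction=0.75)  # floor(3)
        assert got.ids == ("b", "d", "c")  # tie at 0.01 broken by input order

    def test_short_supply_warns(self):
        de = de_result(["a", "b"], [0.1, 0.2])
        with pytest.warns(UserWarning, match="only 2"):
            assert len(select_informative_genes(de, 40)) == 2


class TestLoocv:
    def test_separable_groups_zero_error(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 6)), rng.normal(10, 1, (10, 6))])
        y = np.array(["A"] * 10 + ["B"] * 10)
        res = loocv_prediction_errors(X, y, seed=7)
        assert res.mean_error == 0.0
        assert len(res.errors_pct) == 5

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.normal(0, 1, (20, 6))
        y = np.array(["A", "B"] * 10)
        res = loocv_prediction_errors(X, y, seed=7)
        assert 35.0 <= res.mean_error <= 65.0

    def test_run_count_equals_samples(self, rng):
        # error percentages are multiples of 100/n: one run per sample
        X = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(4, 1, (6, 3))])
        y = np.array(["A"] * 5 + ["B"] * 6)
        res = loocv_prediction_errors(X, y, seed=1)
        assert res.n_samples == 11
        for err in res.errors_pct.values():
            assert (err * 11 / 100) == pytest.approx(round(err * 11 / 100))

    def test_ci_is_centered_t_interval(self, rng):
        X = rng.normal(0, 1, (12, 4))
        y = np.array(["A", "B"] * 6)
        res = loocv_prediction_errors(X, y, seed=3)
        lo, hi = res.ci95
        assert lo <= res.mean_error <= hi
        assert (lo + hi) / 2 == pytest.approx(res.mean_error)

    def test_needs_both_groups(self, rng):
        with pytest.raises(EvaluationError):
            loocv_prediction_errors(rng.normal(size=(6, 2)), np.array(["A"] * 6), seed=0)


class TestCommonDegs:
    def test_identical_lists_all_hundred(self):
        lists = {m: gl("a", "b", "c") for m in ("x", "y", "z")}
        cdm = common_deg_matrix(lists)
        assert (cdm.pct.to_numpy() == 100.0).all()
        assert (cdm.method_scores() == 100.0).all()

    def test_disjoint_lists_zero_off_diagonal(self):
        cdm = common_deg_matrix({"x": gl("a"), "y": gl("b")})
        assert cdm.pct.loc["x", "y"] == 0.0 and cdm.pct.loc["y", "x"] == 0.0

    def test_hand_asymmetric_pair(self):
        x = gl(*[f"g{i}" for i in range(10)])
        y = gl(*[f"g{i}" for i in range(5)], *[f"h{i}" for i in range(15)])
        cdm = common_deg_matrix({"x": x, "y": y})
        assert cdm.pair_counts.loc["x", "y"] == 5
        assert cdm.pct.loc["x", "y"] == 50.0  # 5 of x's 10
        assert cdm.pct.loc["y", "x"] == 25.0  # 5 of y's 20
        assert cdm.pct_avg.loc["x", "y"] == 37.5
        np.testing.assert_allclose(cdm.pct_avg.to_numpy(), cdm.pct_avg.to_numpy().T)

    def test_empty_list_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            cdm = common_deg_matrix({"x": gl("a"), "y": gl("a", "b"), "z": gl()})
        assert cdm.methods == ["x", "y"]

    def test_intersection_matches_set_algebra(self, rng):
        universe = [f"g{i}" for i in range(40)]
        lists = {}
        for m in "abc":
            chosen = rng.choice(40, size=20, replace=False)
            lists[m] = gl(*[universe[i] for i in sorted(chosen)])
        expected = set(lists["a"].ids) & set(lists["b"].ids) & set(lists["c"].ids)
        assert set(intersect_all(lists).ids) == expected

    def test_intersect_identity_and_empty(self):
        a = gl("a", "b")
        assert intersect_all([a, a]).ids == ("a", "b")
        assert intersect_all([a, gl()]).ids == ()


class TestDendrogram:
    def test_identical_rankings_merge_at_zero(self):
        de1 = de_result(["a", "b", "c"], [0.001, 0.002, 0.003], "x")
        de2 = de_result(["a", "b", "c"], [0.01, 0.02, 0.03], "y")
        res = method_rank_dendrogram({"x": de1, "y": de2})
        assert res.distance_matrix.loc["x", "y"] == 0.0
        assert res.linkage[0, 2] == 0.0

    def test_reversed_rankings_distance(self):
        de1 = de_result(["a", "b", "c"], [0.001, 0.002, 0.003], "x")
        de2 = de_result(["a", "b", "c"], [0.003, 0.002, 0.001], "y")
        res = method_rank_dendrogram({"x": de1, "y": de2})
        # rank vectors (1,2,3) vs (3,2,1): Euclidean distance sqrt(8)
        assert res.distance_matrix.loc["x", "y"] == pytest.approx(np.sqrt(8))

    def test_leaf_count_and_common_restriction(self):
        des = {
            m: de_result(["a", "b", "c", "d"], p, m)
            for m, p in {
                "x": [0.001, 0.002, 0.003, 0.9],
                "y": [0.003, 0.002, 0.001, 0.9],
                "z": [0.002, 0.001, 0.003, 0.9],
            }.items()
        }
        res = method_rank_dendrogram(des)
        assert len(res.methods) == 3
        assert res.linkage.shape == (2, 4)
        assert set(res.common_genes) == {"a", "b", "c"}

    def test_too_few_common_genes_errors(self):
        de1 = de_result(["a", "b"], [0.001, 0.9], "x")
        de2 = de_result(["a", "b"], [0.9, 0.001], "y")
        with pytest.raises(EvaluationError, match="alpha"):
            method_rank_dendrogram({"x": de1, "y": de2})


class TestSummarizeRanks:
    def test_published_style_final_rank_arithmetic(self):
        # a method ranked (5, 5, 5, 1.5, 5, 5) across six criteria averages 26.5/6
        ranks = np.array([5.0, 5.0, 5.0, 1.5, 5.0, 5.0])
        assert ranks.mean() == pytest.approx(26.5 / 6)
        criteria = {
            "bias": {"u": 1.0, "v": 2.0},
            "variance": {"u": 1.0, "v": 2.0},
            "sensitivity": {"u": 80.0, "v": 10.0},
        }
        report = summarize_ranks(criteria)
        assert report.final_rank["u"] == 1.0 and report.final_rank["v"] == 2.0
        assert report.recommended == "u"

    def test_dominant_method_ranks_first(self, rng):
        criteria = {
            "bias": {"good": 0.1, "bad": 0.9, "mid": 0.5},
            "prediction_error": {"good": 1.0, "bad": 30.0, "mid": 10.0},
            "common_degs": {"good": 90.0, "bad": 10.0, "mid": 50.0},
        }
        report = summarize_ranks(criteria)
        assert report.final_rank["good"] == 1.0

    def test_criterion_order_irrelevant(self):
        criteria = {
            "bias": {"u": 1.0, "v": 2.0},
            "specificity": {"u": 50.0, "v": 60.0},
        }
        a = summarize_ranks(dict(criteria))
        b = summarize_ranks(dict(reversed(list(criteria.items()))))
        assert a.final_rank.to_dict() == b.final_rank.to_dict()

    def test_incomplete_criterion_dropped(self):
        criteria = {
            "bias": {"u": 1.0, "v": 2.0},
            "sensitivity": {"u": 10.0},
        }
        with pytest.warns(UserWarning, match="dropped"):
            report = summarize_ranks(criteria)
        assert list(report.ranks.columns) == ["bias"]

    def test_direction_table_covers_known_criteria(self):
        assert CRITERION_DIRECTIONS["bias"] == "lower_better"
        assert CRITERION_DIRECTIONS["sensitivity"] == "higher_better"
        with pytest.raises(EvaluationError, match="direction"):
            summarize_ranks({"mystery": {"u": 1.0, "v": 2.0}})
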