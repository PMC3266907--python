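import numpy as np
import pytest

from thermoclade import gmyc, synthetic, treeio
from thermoclade.gmyc import (
    GmycParams,
    classify_nodes,
    delimitation_table,
    entity_confidence,
    fit_at_threshold,
    fit_multiple_threshold,
    fit_null,
    fit_single_threshold,
    loglik_gmyc,
    loglik_null,
    lr_test,
)
from thermoclade.treeio import branching_schedule, parse_newick

from oracles import brute_force_gmyc_loglik, yule_lambda_closed_form


class TestClassify:
    @pytest.mark.parametrize(
        "T, expected",
        [
            (1.5, [("cluster", ("A", "B")), ("singleton", ("C",))]),
            (0.5, [("singleton", ("A",)), ("singleton", ("B",)), ("singleton", ("C",))]),
            (2.5, [("cluster", ("A", "B", "C"))]),
        ],
    )
    def test_toy_partitions(self, toy_tree, T, expected):
        a = classify_nodes(toy_tree, T)
        got = sorted(
            (e.kind, tuple(sorted(toy_tree.label[t] for t in e.tips)))
            for e in a.entities
        )
        assert got == sorted(expected)

    def test_extremes(self, separated_tree):
        tree, _ = separated_tree
        assert classify_nodes(tree, tree.root_depth * 2).n_entities == 1
        assert classify_nodes(tree, 0.0).n_entities == tree.n_tips

    def test_negative_threshold_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            classify_nodes(toy_tree, -0.1)

    def test_every_tip_in_exactly_one_entity(self, separated_tree):
        tree, _ = separated_tree
        a = classify_nodes(tree, 0.01)
        seen = [t for e in a.entities for t in e.tips]
        assert sorted(seen) == sorted(tree.tips)


class TestNullModel:
    def test_hand_computed_values(self, toy_schedule):
        assert loglik_null(toy_schedule, 0.2, 1.0) == pytest.approx(
            np.log(0.4) - 1.0, abs=1e-12
        )
        assert loglik_null(toy_schedule, 1.0, 0.0) == pytest.approx(-2.0)

    def test_diverges_as_rate_vanishes(self, toy_schedule):
        assert loglik_null(toy_schedule, 1e-12, 1.0) < -20
        with pytest.raises(ValueError):
            loglik_null(toy_schedule, 0.0, 1.0)

    def test_closed_form_rate_estimate(self, toy_schedule):
        fit = fit_null(toy_schedule, fix_p=1.0)
        assert fit.lam == pytest.approx(0.2, abs=1e-9)
        assert fit.lam == pytest.approx(yule_lambda_closed_form(toy_schedule))

    def test_rate_recovery_on_large_yule_tree(self):
        tree = synthetic.simulate_yule_tree(100, lam=1.0, seed=11)
        fit = fit_null(branching_schedule(tree), fix_p=1.0)
        assert 0.8 < fit.lam < 1.2

    def test_free_exponent_fit_at_least_as_good(self, toy_schedule):
        fixed = fit_null(toy_schedule, fix_p=1.0)
        free = fit_null(toy_schedule)
        assert free.loglik >= fixed.loglik - 1e-9

    def test_eventless_schedule_rejected(self):
        s = branching_schedule(parse_newick("(A:1,B:1);"))
        with pytest.raises(ValueError):
            fit_null(s)


class TestMixedLoglik:
    def test_hand_computed_toy(self, toy_tree):
        a = classify_nodes(toy_tree, 1.5)
        ll = loglik_gmyc(toy_tree, a, GmycParams(1.0, 1.0, 1.0, 1.0))
        assert ll == pytest.approx(np.log(2) - 2.0, abs=1e-12)

    @pytest.mark.parametrize("lam,p", [(0.2, 1.0), (1.0, 0.0), (0.7, 1.6)])
    def test_all_singleton_assignment_reduces_to_null(self, toy_tree, toy_schedule, lam, p):
        a = classify_nodes(toy_tree, 0.0)
        assert loglik_gmyc(
            toy_tree, a, GmycParams(lam, p, 1.0, 1.0)
        ) == pytest.approx(loglik_null(toy_schedule, lam, p), abs=1e-12)

    def test_vanishing_coalescent_rate_with_coalescent_event(self, toy_tree):
        a = classify_nodes(toy_tree, 1.5)
        assert loglik_gmyc(toy_tree, a, GmycParams(1.0, 1.0, 0.0, 1.0)) == -np.inf


class TestFitAtThreshold:
    def test_toy_boundary_maximization(self, toy_tree):
        params, ll = fit_at_threshold(toy_tree, 1.5, fix_p=(1.0, 1.0))
        assert ll == pytest.approx(np.log(2) - 1.0, abs=1e-6)
        assert params.lam2 == pytest.approx(1.0, abs=1e-4)
        assert params.lam1 <= 1e-6  # no diversification event below the root

    def test_nesting_at_true_threshold(self, separated_tree):
        tree, truth = separated_tree
        null = fit_null(branching_schedule(tree))
        _, ll = fit_at_threshold(tree, truth.entities[0].threshold)
        assert ll >= null.loglik - 1e-9

    def test_deterministic(self, separated_tree):
        tree, _ = separated_tree
        p1, ll1 = fit_at_threshold(tree, 0.01)
        p2, ll2 = fit_at_threshold(tree, 0.01)
        assert ll1 == ll2
        assert (p1.lam1, p1.p1, p1.lam2, p1.p2) == (p2.lam1, p2.p1, p2.lam2, p2.p2)


class TestSingleThreshold:
    def test_recovers_separated_species(self, separated_tree):
        tree, truth = separated_tree
        res = fit_single_threshold(tree)
        assert res.n_entities == 5
        got = sorted(
            tuple(sorted(tree.label[t] for t in e.tips))
            for e in res.assignment.entities
        )
        want = sorted(
            tuple(sorted(tree.label[t] for t in e.tips))
            for e in truth.entities
        )
        assert got == want
        assert res.lr >= 0
        assert res.ci[0] <= res.n_entities <= res.ci[1]

    def test_requires_three_tips(self):
        with pytest.raises(Exception):
            fit_single_threshold(parse_newick("(A:1,B:1);"))

    def test_pure_coalescent_tree_weak_signal(self):
        tree = synthetic.simulate_coalescent_tree(12, theta=0.05, seed=5)
        res = fit_single_threshold(tree)
        assert res.lr >= 0  # nesting still holds on structureless input

    def test_scan_includes_null_reduction_candidate(self, separated_tree):
        tree, _ = separated_tree
        res = fit_single_threshold(tree)
        # the all-singleton candidate ties the null exactly
        row = res.scan[res.scan.n_entities == tree.n_tips]
        assert len(row) >= 1
        assert row.loglik.max() >= res.null.loglik - 1e-6

    def test_matches_brute_force_grid_on_small_tree(self):
        tree, _ = synthetic.simulate_gmyc_tree(
            synthetic.GmycSimConfig(k=3, m=2, separation=5.0, theta=0.1, seed=1)
        )
        res = fit_single_threshold(tree, fix_p=(1.0, 1.0))
        assert res.loglik == pytest.approx(
            brute_force_gmyc_loglik(tree), abs=1e-3
        )

    def test_delimitation_table_covers_all_tips(self, separated_tree):
        tree, _ = separated_tree
        res = fit_single_threshold(tree)
        table = delimitation_table(tree, res)
        assert sorted(table.tip) == sorted(tree.tip_labels)
        assert set(table.kind) <= {"cluster", "singleton"}
        assert res.n_entities == table.entity.nunique()


class TestMultipleThreshold:
    def test_fixed_point_on_clean_tree(self, separated_tree):
        tree, _ = separated_tree
        single = fit_single_threshold(tree)
        multi = fit_multiple_threshold(tree, single=single)
        assert multi.loglik >= single.loglik - 1e-9
        if multi.n_accepted_moves == 0:
            assert multi.n_entities == single.n_entities

    def test_improves_on_two_coalescent_depth_regimes(self):
        # two species with deep within-species structure, two shallow
        deep = "((a1:0.30,a2:0.30):1.7,(b1:0.28,b2:0.28):1.72):1.0"
        shallow = "((c1:0.01,c2:0.01):1.99,(d1:0.012,d2:0.012):1.988):1.0"
        tree = parse_newick(f"({deep},{shallow});")
        single = fit_single_threshold(tree)
        multi = fit_multiple_threshold(tree, single=single)
        assert multi.loglik > single.loglik + 1e-6
        assert multi.model == "multiple"

    def test_loglik_never_below_single(self):
        for seed in (0, 3):
            tree, _ = synthetic.simulate_gmyc_tree(
                synthetic.GmycSimConfig(k=4, m=3, separation=4.0, seed=seed)
            )
            single = fit_single_threshold(tree)
            multi = fit_multiple_threshold(tree, single=single)
            assert multi.loglik >= single.loglik - 1e-9


class TestLrAndConfidence:
    def test_lr_statistic_and_floor(self):
        lr, p = lr_test(10.0, 12.5)
        assert lr == pytest.approx(5.0)
        lr0, p0 = lr_test(3.0, 3.0)
        assert (lr0, p0) == (0.0, 1.0)
        with pytest.warns(UserWarning):
            lr_neg, _ = lr_test(5.0, 4.0)
        assert lr_neg == 0.0

    def test_chi_square_three_df_reference(self):
        _, p = lr_test(0.0, 7.815 / 2.0)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_confidence_set_window(self):
        import pandas as pd

        scan = pd.DataFrame(
            {"threshold": [1, 2, 3], "loglik": [10.0, 9.5, 7.5], "n_entities": [5, 4, 8]}
        )
        assert entity_confidence(scan) == (4, 5)
        assert entity_confidence(scan.iloc[:1]) == (5, 5)
        with pytest.raises(ValueError):
            entity_confidence(scan.iloc[:0])
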