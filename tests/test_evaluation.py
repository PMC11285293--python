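"""Grouped splitting, ranking metrics, bootstrap, curve aggregation."""

import numpy as np
import pytest

from oncostump.evaluation import (
    aggregate_curves,
    average_precision,
    bootstrap_metric,
    grouped_kfold,
    grouped_split,
    model_selection,
    pr_points,
    robustness_runs,
    roc_auc,
    roc_points,
)


def mann_whitney_auc(labels, scores):
    """Independent oracle: (concordant + 0.5 * tied) / (n1 * n0)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = (pos[:, None] > neg[None, :]).sum()
    tied = (pos[:, None] == neg[None, :]).sum()
    return (conc + 0.5 * tied) / (len(pos) * len(neg))


def brute_force_ap(labels, scores):
    """Independent oracle: step sum over distinct descending thresholds."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    n_pos = labels.sum()
    for t in thresholds:
        called = scores >= t
        tp = (labels[called] == 1).sum()
        recall = tp / n_pos
        precision = tp / called.sum()
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def random_instance(rng, max_n=200):
    n = int(rng.integers(4, max_n + 1))
    labels = rng.integers(0, 2, size=n)
    labels[0], labels[1] = 0, 1
    if rng.random() < 0.5:
        scores = rng.normal(size=n)
    else:  # heavy ties
        scores = rng.integers(0, 5, size=n).astype(float)
    return labels, scores


class TestGroupedSplit:
    def test_singleton_groups_give_plain_split(self):
        groups = [("P", i) for i in range(100)]
        split = grouped_split(groups, test_frac=0.2, seed=0)
        assert len(split.test_idx) == 20 and len(split.train_idx) == 80

    def test_small_group_can_be_test_side(self):
        groups = [("P", 1)] * 8 + [("P", 2)] * 2
        seen_small_test = False
        for seed in range(20):
            split = grouped_split(groups, test_frac=0.2, seed=seed)
            sides = ({groups[i] for i in split.train_idx},
                     {groups[i] for i in split.test_idx})
            assert not sides[0] & sides[1]
            if set(split.test_idx) == {8, 9}:
                seen_small_test = True
        assert seen_small_test

    def test_no_group_leak_over_random_structures(self, rng):
        for trial in range(200):
            n_groups = int(rng.integers(2, 30))
            groups = [(f"P{rng.integers(5)}", int(rng.integers(n_groups)))
                      for _ in range(int(rng.integers(10, 60)))]
            if len(set(groups)) < 2:
                continue
            split = grouped_split(groups, seed=trial)
            train_groups = {groups[i] for i in split.train_idx}
            test_groups = {groups[i] for i in split.test_idx}
            assert not train_groups & test_groups
            assert len(split.train_idx) + len(split.test_idx) == len(groups)

    def test_same_seed_same_split(self):
        groups = [("P", i % 7) for i in range(40)]
        a = grouped_split(groups, seed=5)
        b = grouped_split(groups, seed=5)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            grouped_split([("P", 1)] * 10)


class TestGroupedKfold:
    def test_five_equal_groups_one_per_fold(self):
        groups = [(f"P", g) for g in range(5) for _ in range(4)]
        folds = grouped_kfold(groups, k=5, seed=1)
        assert sorted(len(f) for f in folds) == [4, 4, 4, 4, 4]

    def test_partition_property(self, rng):
        groups = [("P", int(rng.integers(12))) for _ in range(50)]
        folds = grouped_kfold(groups, k=5, seed=2)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(50))
        for i in range(5):
            fold_groups = {groups[j] for j in folds[i]}
            for other in folds[i + 1:]:
                assert not fold_groups & {groups[j] for j in other}

    def test_balance_no_worse_than_round_robin(self, rng):
        for trial in range(50):
            sizes = rng.integers(1, 10, size=int(rng.integers(5, 20)))
            groups = [("P", g) for g, s in enumerate(sizes) for _ in range(s)]
            folds = grouped_kfold(groups, k=5, seed=trial)
            fold_sizes = np.array([len(f) for f in folds])
            rr = np.zeros(5)
            for i, s in enumerate(sizes):
                rr[i % 5] += s
            spread = fold_sizes.max() - fold_sizes.min()
            rr_spread = rr.max() - rr.min()
            assert spread <= rr_spread + 1e-9

    def test_k_exceeding_groups_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold([("P", 1), ("P", 2)] * 3, k=5)


class TestRoc:
    def test_perfect_ranking(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.4, 0.2]) == 1.0

    def test_half_concordant_pairs(self):
        # 2 of 4 (pos, neg) pairs concordant -> AUC 0.5
        assert roc_auc([1, 0, 0, 1], [0.9, 0.8, 0.4, 0.2]) == pytest.approx(0.5)

    def test_matches_mann_whitney_on_random_instances(self, rng):
        for _ in range(500):
            labels, scores = random_instance(rng)
            assert roc_auc(labels, scores) == pytest.approx(
                mann_whitney_auc(labels, scores), abs=1e-12)

    def test_curve_endpoints(self, rng):
        labels, scores = random_instance(rng)
        pts = roc_points(labels, scores)
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.2, 0.3, 0.4])


class TestAveragePrecision:
    def test_alternating_ranked_labels(self):
        # ranked labels [1,0,1,0]: AP = 0.5*1 + 0.5*(2/3) = 5/6
        assert average_precision([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2]) == \
            pytest.approx(5 / 6)

    def test_all_positives_first(self):
        assert average_precision([1, 1, 0, 0], [4, 3, 2, 1]) == 1.0

    def test_matches_brute_force_step_sum(self, rng):
        for _ in range(500):
            labels, scores = random_instance(rng)
            assert average_precision(labels, scores) == pytest.approx(
                brute_force_ap(labels, scores), abs=1e-12)

    def test_pr_curve_padded_at_recall_zero(self):
        pts = pr_points([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2])
        assert tuple(pts[0]) == (0.0, 1.0)

    def test_zero_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0, 0], [0.1, 0.2])


class TestBootstrap:
    def test_perfectly_separated_auc_has_zero_sd(self):
        labels = np.array([1] * 20 + [0] * 20)
        scores = np.concatenate([np.linspace(2, 3, 20), np.linspace(0, 1, 20)])
        summary = bootstrap_metric(labels, scores, "roc_auc", n_boot=200, seed=0)
        assert summary.point_estimate == 1.0
        assert summary.bootstrap_sd == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        labels, scores = random_instance(rng)
        a = bootstrap_metric(labels, scores, n_boot=100, seed=9)
        b = bootstrap_metric(labels, scores, n_boot=100, seed=9)
        assert a == b

    def test_point_estimate_within_three_sd(self, rng):
        hits = total = 0
        for _ in range(40):
            labels, scores = random_instance(rng, max_n=80)
            s = bootstrap_metric(labels, scores, n_boot=300, seed=1)
            if s.bootstrap_sd > 0:
                total += 1
                hits += abs(s.point_estimate - s.bootstrap_mean) <= 3 * s.bootstrap_sd
        assert hits / total >= 0.9

    def test_sd_scales_as_inverse_sqrt_n(self, rng):
        """Bootstrap AUC sd shrinks roughly as 1/sqrt(n) on i.i.d. scores."""
        sds = []
        for n in (100, 400):
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            scores = labels * 0.5 + rng.normal(size=n)
            sds.append(bootstrap_metric(labels, scores, n_boot=400, seed=3).bootstrap_sd)
        ratio = sds[0] / sds[1]
        assert 2.0 * 0.75 <= ratio <= 2.0 * 1.25


class TestAggregateCurves:
    def test_single_curve_bands_collapse(self):
        curve = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.7, 1.0]))
        cs = aggregate_curves([curve])
        np.testing.assert_allclose(cs.q10, cs.median)
        np.testing.assert_allclose(cs.q90, cs.median)
        np.testing.assert_allclose(cs.median, np.interp(cs.grid, *curve))

    def test_two_constant_curves_closed_form(self):
        low = (np.array([0.0, 1.0]), np.array([0.2, 0.2]))
        high = (np.array([0.0, 1.0]), np.array([0.8, 0.8]))
        cs = aggregate_curves([low, high])
        np.testing.assert_allclose(cs.median, 0.5)
        np.testing.assert_allclose(cs.q10, 0.26)  # 0.2 + 0.1*(0.8-0.2)
        np.testing.assert_allclose(cs.q90, 0.74)

    def test_grid_endpoints_and_band_order(self, rng):
        curves = []
        for _ in range(7):
            x = np.sort(rng.random(6))
            curves.append((np.concatenate([[0], x, [1]]), rng.random(8)))
        cs = aggregate_curves(curves)
        assert cs.grid[0] == 0.0 and cs.grid[-1] == 1.0 and len(cs.grid) == 30
        assert (np.diff(cs.grid) > 0).all()
        assert (cs.q10 <= cs.median + 1e-12).all()
        assert (cs.median <= cs.q90 + 1e-12).all()

    def test_non_monotone_x_rejected(self):
        with pytest.raises(ValueError):
            aggregate_curves([(np.array([0.0, 0.6, 0.4, 1.0]), np.zeros(4))])


class TestModelSelection:
    def make_data(self, rng, n=80):
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] + 0.8 * rng.normal(size=n) > 0).astype(int)
        groups = [("P", int(g)) for g in rng.integers(0, 20, size=n)]
        return X, y, groups

    def test_single_cell_returned(self, rng):
        X, y, groups = self.make_data(rng)
        best, table = model_selection(X, y, groups, {"n_rounds": [5]}, seed=0)
        assert best == {"n_rounds": 5} and len(table) == 1

    def test_duplicated_cell_identical_auc(self, rng):
        X, y, groups = self.make_data(rng)
        _, table = model_selection(
            X, y, groups, {"n_rounds": [5, 5]}, seed=0)
        assert table["mean_auc"].iloc[0] == table["mean_auc"].iloc[1]

    def test_dominant_cell_wins(self, rng):
        X, y, groups = self.make_data(rng, n=120)
        best, table = model_selection(
            X, y, groups, {"n_rounds": [0, 15], "eta": [0.3]}, seed=0)
        assert best["n_rounds"] == 15
        by_cell = table.set_index("n_rounds")["mean_auc"]
        assert by_cell[15] > by_cell[0]

    def test_tie_prefers_fewest_rounds(self, rng):
        X, y, groups = self.make_data(rng)
        # 0 extra rounds after saturation: identical folds AUC for both cells
        best, table = model_selection(X, y, groups, {"n_rounds": [5], "eta": [0.3, 0.3]},
                                      seed=0)
        assert best == {"n_rounds": 5, "eta": 0.3}

    def test_empty_grid_rejected(self, rng):
        X, y, groups = self.make_data(rng)
        with pytest.raises(ValueError):
            model_selection(X, y, groups, {})


class TestRobustness:
    def test_fixed_seed_pipeline_has_zero_spread(self):
        df = robustness_runs(lambda seed: {"auc": 0.9}, n_seeds=5)
        assert df["auc"].std() == 0.0

    def test_different_seeds_reach_pipeline(self):
        df = robustness_runs(lambda seed: {"auc": seed / 100}, n_seeds=10)
        assert df["auc"].nunique() == 10
        assert list(df["seed"]) == list(range(10))
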