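"""Metrics vs independent oracles, exact Wilcoxon vs enumeration,
stratified CV harness, differential-feature ranking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import multikano as mk


# -- confusion matrix and metrics ------------------------------------------

class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        cm = mk.confusion_matrix(["A", "B", "A"], ["A", "B", "A"])
        assert np.array_equal(cm.counts, [[2, 0], [0, 1]])

    def test_hand_count(self):
        cm = mk.confusion_matrix(["A", "A", "B"], ["A", "B", "B"])
        assert np.array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_row_sums_are_class_sizes(self):
        rng = np.random.default_rng(0)
        truth = rng.choice(list("ABC"), 60)
        pred = rng.choice(list("ABC"), 60)
        cm = mk.confusion_matrix(truth, pred)
        for i, c in enumerate(cm.classes):
            assert cm.counts[i].sum() == (truth == c).sum()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mk.confusion_matrix(["A"], ["A", "B"])


class TestKappaAndF1:
    def test_perfect_agreement(self):
        cm = mk.ConfusionMatrix(np.diag([5, 3, 2]), ["a", "b", "c"])
        assert mk.cohen_kappa(cm) == 1.0
        assert mk.f1_macro(cm) == 1.0

    def test_kappa_hand_formula(self):
        cm = mk.ConfusionMatrix([[40, 10], [20, 30]], ["x", "y"])
        assert mk.cohen_kappa(cm) == pytest.approx(0.4, abs=1e-12)

    def test_kappa_zero_for_independent_table(self):
        # counts = outer(row, col) / N is exactly chance agreement
        row = np.array([40, 60])
        col = np.array([70, 30])
        cm = mk.ConfusionMatrix(np.outer(row, col) // 100, ["x", "y"])
        assert mk.cohen_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_f1_hand_computation(self):
        cm = mk.ConfusionMatrix([[40, 10], [20, 30]], ["x", "y"])
        f1_x = 2 * (40 / 60) * (40 / 50) / (40 / 60 + 40 / 50)
        f1_y = 2 * (30 / 40) * (30 / 50) / (30 / 40 + 30 / 50)
        assert mk.f1_macro(cm) == pytest.approx((f1_x + f1_y) / 2, abs=1e-12)
        assert mk.f1_macro(cm) == pytest.approx(0.6970, abs=5e-5)

    def test_absent_class_contributes_zero_not_nan(self):
        cm = mk.ConfusionMatrix([[3, 0, 0], [0, 2, 0], [0, 0, 0]], ["a", "b", "c"])
        assert mk.f1_macro(cm) == pytest.approx(2 / 3)

    def test_degenerate_single_class_perfect(self):
        cm = mk.ConfusionMatrix([[7]], ["only"])
        assert mk.cohen_kappa(cm) == 1.0

    def test_metrics_match_sklearn_oracles(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        for _ in range(200):
            k = rng.integers(2, 6)
            n = rng.integers(10, 60)
            classes = [f"c{i}" for i in range(k)]
            truth = rng.choice(classes, n)
            pred = rng.choice(classes, n)
            cm = mk.confusion_matrix(truth, pred, classes=classes)
            assert mk.accuracy(cm) == pytest.approx(
                sklearn.accuracy_score(truth, pred), abs=1e-12)
            assert mk.cohen_kappa(cm) == pytest.approx(
                sklearn.cohen_kappa_score(truth, pred, labels=classes), abs=1e-12)
            assert mk.f1_macro(cm) == pytest.approx(
                sklearn.f1_score(truth, pred, labels=classes, average="macro",
                                 zero_division=0), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_kappa_invariant_under_class_permutation(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        counts = rng.integers(0, 20, size=(k, k))
        if counts.sum() == 0:
            counts[0, 0] = 1
        cm = mk.ConfusionMatrix(counts, [f"c{i}" for i in range(k)])
        perm = rng.permutation(k)
        cm_p = mk.ConfusionMatrix(counts[np.ix_(perm, perm)],
                                  [f"c{i}" for i in perm])
        assert mk.cohen_kappa(cm) == pytest.approx(mk.cohen_kappa(cm_p), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_accuracy_equals_one_minus_error_rate(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 50))
        truth = rng.choice(list("AB"), n)
        pred = rng.choice(list("AB"), n)
        cm = mk.confusion_matrix(truth, pred, classes=["A", "B"])
        assert mk.accuracy(cm) == pytest.approx(1.0 - (truth != pred).mean(), abs=1e-12)


# -- exact Wilcoxon signed-rank --------------------------------------------

def enumeration_wilcoxon(diffs):
    """Full 2^n sign-flip enumeration over observed midranks."""
    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(ranks)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= w_obs - 1e-9:
            count += 1
    return count / 2 ** n


class TestWilcoxonExact:
    def test_all_positive_n3(self):
        assert mk.wilcoxon_signed_rank_exact([1.0, 2.0, 0.5]) == pytest.approx(0.125)

    def test_all_positive_is_two_to_minus_n(self):
        for n in (1, 5, 10, 20, 30):
            p = mk.wilcoxon_signed_rank_exact(np.arange(1, n + 1, dtype=float))
            assert p == pytest.approx(2.0 ** -n, rel=1e-12)

    def test_matches_enumeration_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(1, 13))
            diffs = rng.integers(-4, 5, size=n).astype(float)  # integers force ties
            if np.all(diffs == 0):
                diffs[0] = 1.0
            assert mk.wilcoxon_signed_rank_exact(diffs) == pytest.approx(
                enumeration_wilcoxon(diffs), abs=1e-12
            )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(5, 20))
            diffs = rng.normal(size=n)  # continuous: no ties, no zeros
            ours = mk.wilcoxon_signed_rank_exact(diffs)
            ref = stats.wilcoxon(diffs, alternative="greater", method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_zeros_dropped_and_all_zero_errors(self):
        assert mk.wilcoxon_signed_rank_exact([0.0, 1.0, 2.0, 0.0, 3.0]) == pytest.approx(0.125)
        with pytest.raises(ValueError, match="zero"):
            mk.wilcoxon_signed_rank_exact([0.0, 0.0])

    def test_normal_approximation_branch_is_sane(self):
        rng = np.random.default_rng(4)
        diffs = rng.normal(0.5, 1.0, size=80)
        p_approx = mk.wilcoxon_signed_rank_exact(diffs, exact_max_n=50)
        p_exact_dp = mk.wilcoxon_signed_rank_exact(diffs, exact_max_n=100)
        assert p_approx == pytest.approx(p_exact_dp, rel=0.5, abs=1e-4)


# -- stratified CV ---------------------------------------------------------

class TestStratifiedFolds:
    def test_per_class_fold_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(["a", "b", "c"], p=[0.5, 0.3, 0.2], size=200)
        folds = mk.stratified_folds(labels, 5, seed=1)
        for c in "abc":
            sizes = np.bincount(folds[labels == c], minlength=5)
            assert sizes.max() - sizes.min() <= 1

    def test_folds_partition_cells(self):
        labels = np.repeat(["a", "b"], 25)
        folds = mk.stratified_folds(labels, 5, seed=0)
        assert set(folds) == set(range(5))
        assert len(folds) == 50

    def test_small_class_errors_by_name(self):
        with pytest.raises(ValueError, match="rare"):
            mk.stratified_folds(["rare"] * 2 + ["ok"] * 10, 5)


class TestCrossValidate:
    def test_cv_recovers_separable_types(self, tiny_dataset, fast_train_config):
        res = mk.cross_validate(
            tiny_dataset,
            mk.PreprocessConfig(n_hvg=30),
            fast_train_config,
            plan=mk.AugmentationPlan(),
            n_folds=3,
            seed=0,
        )
        assert len(res.per_fold) == 3
        assert res.mean("accuracy") > 0.8

    def test_cv_requires_labels(self, tiny_dataset):
        unlabeled = mk.PairedDataset(rna=tiny_dataset.rna, atac=tiny_dataset.atac)
        with pytest.raises(ValueError, match="labels"):
            mk.cross_validate(unlabeled)


def test_celltype_removal_trajectory_length(tiny_dataset, fast_train_config):
    steps = mk.celltype_removal_robustness(
        tiny_dataset, mk.PreprocessConfig(n_hvg=30), fast_train_config,
        n_folds=3, seed=0,
    )
    assert len(steps) == 1  # 3 classes -> exactly K - 2 = 1 removal step
    remaining, result = steps[0]
    assert len(remaining) == 2
    assert len(result.class_names) == 2


# -- differential features -------------------------------------------------

class TestRankDiffFeatures:
    def _toy(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (10, 5))
        group = np.array([True] * 5 + [False] * 5)
        x[:, 0] = np.where(group, 10.0, -10.0)  # perfectly separated
        x[:, 4] = 3.14                          # constant
        return x, group

    def test_separated_feature_ranks_first_constant_last(self):
        x, group = self._toy()
        ranked = mk.rank_diff_features(x, group)
        assert ranked.feature_ids[0] == "0"
        assert ranked.feature_ids[-1] == "4"
        assert ranked.pvalue[-1] == 1.0

    def test_pvalues_close_to_exact_enumeration(self):
        """Normal-approximation p-values vs exact permutation enumeration on
        a 10-cell toy; the approximation is documented to within ~0.05."""
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (10, 4))
        group = np.array([True] * 5 + [False] * 5)
        ranked = mk.rank_diff_features(x, group)
        for fid, p in zip(ranked.feature_ids, ranked.pvalue):
            col = x[:, int(fid)]
            ranks = stats.rankdata(col)
            w_obs = ranks[group].sum()
            mu = ranks.sum() / 2
            count = sum(
                abs(sum(ranks[list(c)]) - mu) >= abs(w_obs - mu) - 1e-9
                for c in itertools.combinations(range(10), 5)
            )
            exact = count / 252
            assert p == pytest.approx(exact, abs=0.05)

    def test_group_must_be_nonempty(self):
        with pytest.raises(ValueError, match="nonempty"):
            mk.rank_diff_features(np.ones((4, 2)), np.array([True] * 4))


class TestTopkOverlap:
    def test_identical_lists(self):
        x, group = np.random.default_rng(8).normal(size=(10, 6)), None
        group = np.array([True] * 5 + [False] * 5)
        a = mk.rank_diff_features(x, group)
        frac, shared = mk.topk_overlap(a, a, 3)
        assert frac == 1.0
        assert len(shared) == 3

    def test_disjoint_universes(self):
        a = mk.RankedFeatureList(np.array(["a", "b"]), np.zeros(2), np.zeros(2))
        b = mk.RankedFeatureList(np.array(["c", "d"]), np.zeros(2), np.zeros(2))
        frac, shared = mk.topk_overlap(a, b, 2)
        assert frac == 0.0 and shared == []

    def test_random_permutations_match_hypergeometric_expectation(self):
        rng = np.random.default_rng(9)
        universe = np.array([f"f{i}" for i in range(1000)])
        fracs = []
        for _ in range(30):
            a = mk.RankedFeatureList(rng.permutation(universe)[:100], None, None)
            b = mk.RankedFeatureList(rng.permutation(universe)[:100], None, None)
            fracs.append(mk.topk_overlap(a, b, 100)[0])
        # E[overlap] = k/N = 0.1; 3-sigma band for the mean of 30 repeats
        se = np.sqrt(0.1 * 0.9 / (100 * 30))
        assert abs(np.mean(fracs) - 0.1) < 3 * se

    def test_invalid_k(self):
        a = mk.RankedFeatureList(np.array(["a"]), None, None)
        with pytest.raises(ValueError):
            mk.topk_overlap(a, a, 0)
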