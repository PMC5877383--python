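import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

import myoselect as ms


def matrix_from_classes(columns_by_class, feature_names=None):
    """Build a FeatureMatrix from {class: 2-D array (windows x features)}."""
    classes = sorted(columns_by_class)
    values = np.vstack([np.atleast_2d(columns_by_class[c]) for c in classes])
    labels = np.concatenate(
        [[c] * np.atleast_2d(columns_by_class[c]).shape[0] for c in classes]
    )
    names = feature_names or [f"F{j + 1}" for j in range(values.shape[1])]
    return ms.FeatureMatrix(values, names, labels)


# ---------------------------------------------------------------- oracles


def fisher_ratio_by_enumeration(a, b):
    """Direct pair enumeration of the Fisher discrimination ratio."""
    cross = np.mean([(x - y) ** 2 for x in a for y in b])
    within_a = np.mean([(a[i] - a[j]) ** 2 for i in range(len(a)) for j in range(i + 1, len(a))])
    within_b = np.mean([(b[i] - b[j]) ** 2 for i in range(len(b)) for j in range(i + 1, len(b))])
    return cross / (within_a + within_b)


def rfe_by_stepwise_elimination(values, labels, c=1.0):
    """Literal recursive elimination: at each step retrain a linear SVM on
    the surviving features and drop the one with the smallest squared weight."""
    x = StandardScaler().fit_transform(values)
    remaining = list(range(values.shape[1]))
    eliminated = []
    while len(remaining) > 1:
        svc = SVC(kernel="linear", C=c).fit(x[:, remaining], labels)
        w2 = (svc.coef_**2).sum(axis=0)
        eliminated.append(remaining.pop(int(np.argmin(w2))))
    return remaining + eliminated[::-1]


# ---------------------------------------------------------------- EC


class TestEntropyCriterion:
    def test_equal_variances_give_maximum_entropy(self, rng):
        fm = matrix_from_classes(
            {"a": rng.standard_normal((200, 1)), "b": rng.standard_normal((200, 1))}
        )
        j = ms.ec_score(fm).sv["F1"]
        assert j == pytest.approx(np.log(2), abs=0.01)

    def test_degenerate_variance_gives_zero(self):
        fm = matrix_from_classes(
            {"a": np.array([[0.0], [1.0], [2.0]]), "b": np.array([[5.0], [5.0], [5.0]])}
        )
        assert ms.ec_score(fm).sv["F1"] == pytest.approx(0.0)

    def test_known_variance_split(self):
        """Class variances 2 and 6 -> V = (0.25, 0.75) -> J ~ 0.5623."""
        # three points with sample variance v: {-sqrt(v), 0, +sqrt(v)}
        a = np.array([[-np.sqrt(2.0)], [0.0], [np.sqrt(2.0)]])
        b = np.array([[-np.sqrt(6.0)], [0.0], [np.sqrt(6.0)]])
        j = ms.ec_score(matrix_from_classes({"a": a, "b": b})).sv["F1"]
        expected = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        assert j == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5623, abs=1e-4)

    def test_ranked_ascending(self, planted_features):
        rep = ms.ec_score(planted_features)
        svs = [rep.sv[f] for f in rep.order]
        assert svs == sorted(svs)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), n_classes=st.integers(2, 5))
    def test_entropy_bounds(self, seed, n_classes):
        rng = np.random.default_rng(seed)
        fm = matrix_from_classes(
            {f"c{k}": rng.standard_normal((5, 3)) * (k + 1) for k in range(n_classes)}
        )
        rep = ms.ec_score(fm)
        for v in rep.sv.values():
            assert -1e-12 <= v <= np.log(n_classes) + 1e-12

    def test_missing_class_windows_raise(self):
        fm = matrix_from_classes({"a": np.zeros((1, 2)), "b": np.ones((5, 2))})
        with pytest.raises(ValueError, match="fewer than 2"):
            ms.ec_score(fm)


# ---------------------------------------------------------------- FD


class TestFisherDiscrimination:
    def test_hand_example_matches_enumeration(self):
        a, b = np.array([0.0, 1.0]), np.array([3.0, 4.0])
        assert ms.fisher_ratio(a, b) == pytest.approx(4.75)
        assert fisher_ratio_by_enumeration(a, b) == pytest.approx(4.75)

    def test_identical_classes_example(self):
        """a = b = {0,1,2}: cross pairs include same-index pairs -> J = 1/3."""
        a = np.array([0.0, 1.0, 2.0])
        assert ms.fisher_ratio(a, a) == pytest.approx(1 / 3)
        assert fisher_ratio_by_enumeration(a, a) == pytest.approx(1 / 3)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000), na=st.integers(2, 8), nb=st.integers(2, 8))
    def test_closed_form_equals_enumeration(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(na), 2 + rng.standard_normal(nb)
        assert ms.fisher_ratio(a, b) == pytest.approx(
            fisher_ratio_by_enumeration(a, b), rel=1e-9
        )

    def test_degenerate_within_class_distance_flags_infinity(self):
        with pytest.warns(UserWarning, match="infinite"):
            val = ms.fisher_ratio(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert np.isinf(val)

    @settings(deadline=None, max_examples=25)
    @given(
        seed=st.integers(0, 10_000),
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 50),
    )
    def test_translation_and_scale_invariance(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(6), 1 + rng.standard_normal(6)
        base = ms.fisher_ratio(a, b)
        assert ms.fisher_ratio(a + shift, b + shift) == pytest.approx(base, rel=1e-6)
        assert ms.fisher_ratio(a * scale, b * scale) == pytest.approx(base, rel=1e-6)

    def test_multiclass_one_versus_all_mean(self, rng):
        """4-class FD equals the mean of the four class-vs-rest binary ratios."""
        blocks = {c: k + rng.standard_normal((10, 2)) for k, c in enumerate("abcd")}
        fm = matrix_from_classes(blocks)
        rep = ms.fd_score(fm)
        for fi, name in enumerate(fm.feature_names):
            ratios = []
            for c in "abcd":
                mask = fm.labels == c
                ratios.append(
                    ms.fisher_ratio(fm.values[mask, fi], fm.values[~mask, fi])
                )
            assert rep.sv[name] == pytest.approx(np.mean(ratios), rel=1e-9)

    def test_ranked_descending(self, planted_features):
        rep = ms.fd_score(planted_features)
        svs = [rep.sv[f] for f in rep.order]
        assert svs == sorted(svs, reverse=True)


# ---------------------------------------------------------------- RFE


class TestRecursiveFeatureElimination:
    def test_noise_feature_eliminated_first(self, rng):
        sig = np.concatenate([np.zeros(20), np.ones(20)])
        values = np.column_stack([sig + 0.05 * rng.standard_normal(40),
                                  rng.standard_normal(40)])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        rep = ms.rfe_rank(ms.FeatureMatrix(values, ["signal", "noise"], labels))
        assert rep.order == ["signal", "noise"]

    def test_rank_is_permutation(self, planted_features):
        rep = ms.rfe_rank(planted_features)
        assert sorted(rep.order) == sorted(planted_features.feature_names)
        assert sorted(rep.sv.values()) == list(range(1, 21))

    @pytest.mark.parametrize("d", [3, 4])
    def test_matches_stepwise_elimination_oracle(self, d, rng):
        values = rng.standard_normal((60, d))
        labels = np.array(["a"] * 30 + ["b"] * 30)
        values[labels == "b", 0] += 2.0  # one informative feature
        values[labels == "b", 1] += 0.5  # one weak feature
        fm = ms.FeatureMatrix(values, [f"F{j + 1}" for j in range(d)], labels)
        rep = ms.rfe_rank(fm)
        oracle = rfe_by_stepwise_elimination(values, labels)
        assert rep.order == [fm.feature_names[i] for i in oracle]


# ---------------------------------------------------------------- sweeps etc.


class TestOFNSweep:
    @pytest.fixture(scope="class")
    def sweep(self):
        fm = ms.generate_planted_features(20, 10, [1, 4, 7], 2.5, seed=9)
        report = ms.fd_score(fm)
        config = ms.ClassifierConfig(kind="svm", svm_c_grid=(10.0,))
        return fm, ms.ofn_sweep(fm, report, config, folds=5, seed=0)

    def test_curve_covers_all_subset_sizes(self, sweep):
        fm, result = sweep
        assert len(result.accuracy_curve) == fm.n_features

    def test_plateau_near_planted_count(self, sweep):
        _, result = sweep
        assert result.ofn <= 5
        assert max(result.accuracy_curve[:5]) >= 0.95 * max(result.accuracy_curve)

    def test_tie_break_returns_smallest_size(self):
        fm = ms.generate_planted_features(20, 4, [], 0.0, seed=2, classes=("a", "b"))
        report = ms.fd_score(fm)
        config = ms.ClassifierConfig(kind="knn")
        result = ms.ofn_sweep(fm, report, config, folds=5, seed=0)
        best = max(result.accuracy_curve)
        assert result.ofn == result.accuracy_curve.index(best) + 1


class TestAggregation:
    @staticmethod
    def report(order, svs, method="FD"):
        return ms.SeparabilityReport(
            method=method, sv=dict(zip(order, svs)), order=list(order), n_classes=2
        )

    def test_single_report_identity(self):
        rep = self.report(["A", "B", "C"], [3.0, 2.0, 1.0])
        out = ms.aggregate_selection({("s1", "ch1"): rep}, subset_size=2)
        assert out.selected == ["A", "B"]

    def test_rfe_frequency_ceiling_is_report_count(self):
        """Nine subjects x two channels -> a feature can appear at most 18 times."""
        reports = {}
        for s in range(9):
            for ch in ("ECU", "ECR"):
                reports[(f"S{s + 1}", ch)] = self.report(
                    ["A", "B", "C", "D"], [1.0, 2.0, 3.0, 4.0], method="RFE"
                )
        out = ms.aggregate_selection(reports, subset_size=2)
        assert max(out.scores.values()) == 18
        assert out.scores["A"] == out.scores["B"] == 18
        assert out.scores["C"] == out.scores["D"] == 0

    def test_reversed_channel_ranks_tie_broken_by_name_order(self):
        r1 = self.report(["A", "B"], [2.0, 1.0])
        r2 = self.report(["B", "A"], [1.0, 2.0])
        r2.sv = {"A": 1.0, "B": 2.0}
        out = ms.aggregate_selection(
            {("s1", "ch1"): r1, ("s1", "ch2"): r2}, subset_size=1
        )
        assert out.scores["A"] == out.scores["B"]
        assert out.selected == ["A"]  # canonical order breaks the tie

    def test_mixed_methods_rejected(self):
        r1 = self.report(["A"], [1.0], "EC")
        r2 = self.report(["A"], [1.0], "FD")
        with pytest.raises(ValueError, match="same method"):
            ms.aggregate_selection({("s", "c1"): r1, ("s", "c2"): r2}, 1)


class TestChannelRanking:
    @pytest.fixture(scope="class")
    def ranking(self):
        signal_fm = ms.generate_planted_features(12, 6, [0, 1, 2], 2.5, seed=3)
        noise_fm = ms.generate_planted_features(12, 6, [], 0.0, seed=4)
        config = ms.ClassifierConfig(kind="knn", cv_folds=4)
        return ms.rank_channels(
            {"signal": signal_fm, "noise": noise_fm}, config, top_n=1
        )

    def test_signal_channel_ranked_first(self, ranking):
        assert ranking.order[0] == "signal"
        assert ranking.selected == ["signal"]

    def test_six_pairwise_accuracies_for_four_classes(self, ranking):
        assert ranking.table.shape == (2, 7)  # 6 pairs + mean

    def test_duplicate_channels_tie_deterministically(self):
        fm = ms.generate_planted_features(12, 6, [0, 1], 2.0, seed=6)
        config = ms.ClassifierConfig(kind="knn", cv_folds=4)
        out = ms.rank_channels({"first": fm, "second": fm}, config)
        assert out.table.loc["first", "mean"] == out.table.loc["second", "mean"]
        assert out.order == ["first", "second"]  # stable tie-break
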