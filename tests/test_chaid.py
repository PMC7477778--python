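"""CHAID tests: chi-square primitive, category merging, split selection,
tree growth, prediction, and serialization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import emrfrailty as ef
from emrfrailty.chaid import (
    ChaidClassifier,
    ChaidParams,
    best_split,
    chisq_2xk,
    kass_multiplier,
    merge_categories,
)


class TestChiSquare:
    def test_perfect_independence(self):
        stat, p = chisq_2xk([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_closed_form_2x2(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 80*(900-100)^2/40^4 = 20
        stat, p = chisq_2xk([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0)

    def test_all_zero_column_is_uninformative(self):
        stat, p = chisq_2xk([[12, 0], [7, 0]])
        assert p == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chisq_2xk([[1, -2], [3, 4]])

    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 5)
            t = rng.integers(1, 30, size=(2, k))
            stat, p = chisq_2xk(t)
            s2, p2, _, _ = chi2_contingency(t, correction=False)
            assert stat == pytest.approx(s2)
            assert p == pytest.approx(p2)


class TestMerging:
    def test_binary_predictor_untouched(self):
        vals = [0] * 20 + [1] * 20
        y = np.array([0, 1] * 20)
        assert merge_categories(vals, y, alpha_merge=0.05) == [(0,), (1,)]

    def test_identical_categories_merged(self):
        # categories a and b have identical class distributions; c differs
        vals = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        y = np.array([0] * 10 + [1] * 10 + [0] * 10 + [1] * 10 + [0] * 18 + [1] * 2)
        groups = merge_categories(vals, y, alpha_merge=0.05)
        assert ("a", "b") in groups and ("c",) in groups

    def test_planted_partition_matches_exhaustive_search(self):
        """Greedy merging recovers the partition an exhaustive search over all
        set partitions (scored by the final chi-square p) would pick."""
        rng = np.random.default_rng(42)
        cats = np.repeat(["a", "b", "c", "d"], 50)
        rates = {"a": 0.1, "b": 0.12, "c": 0.85, "d": 0.9}
        y = np.array([rng.random() < rates[c] for c in cats]).astype(int)

        def table_for(partition):
            t = np.zeros((2, len(partition)))
            for gi, grp in enumerate(partition):
                mask = np.isin(cats, grp)
                t[0, gi] = np.sum(mask & (y == 0))
                t[1, gi] = np.sum(mask & (y == 1))
            return t

        def partitions(items):
            if len(items) == 1:
                yield [items]
                return
            first, rest = items[0], items[1:]
            for part in partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [[first] + part[i]] + part[i + 1:]
                yield [[first]] + part

        best_p, best_part = np.inf, None
        for part in partitions(["a", "b", "c", "d"]):
            if len(part) < 2:
                continue
            _, p = chisq_2xk(table_for(part))
            if p < best_p:
                best_p, best_part = p, sorted(tuple(sorted(g)) for g in part)
        greedy = sorted(tuple(g) for g in merge_categories(cats, y, 0.05))
        assert greedy == best_part


def test_kass_partition_coefficients():
    assert kass_multiplier(2, 2) == 1
    assert kass_multiplier(3, 2) == 3
    assert kass_multiplier(4, 2) == 7
    assert kass_multiplier(4, 3) == 6
    assert kass_multiplier(5, 5) == 1
    assert kass_multiplier(6, 1) == 1


class TestBestSplit:
    def test_perfect_separator_survives_bonferroni(self):
        rng = np.random.default_rng(1)
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        X = pd.DataFrame({
            "noise" + str(j): rng.integers(0, 2, n) for j in range(5)
        })
        X["signal"] = y
        cand = best_split(X, y, ChaidParams(alpha=0.05))
        assert cand.feature == "signal"
        assert cand.p_adjusted < 1e-6

    def test_identical_features_tie_break_lexicographic(self):
        y = np.array([0] * 25 + [1] * 15)
        col = np.array([0] * 20 + [1] * 20)
        X = pd.DataFrame({"b_feat": col, "a_feat": col})
        cand = best_split(X, y, ChaidParams(alpha=0.3))
        assert cand.feature == "a_feat"

    def test_permuted_labels_rarely_split(self):
        rng = np.random.default_rng(2)
        none_count = 0
        runs = 60
        for _ in range(runs):
            X = pd.DataFrame(rng.integers(0, 2, size=(80, 30)).astype(float))
            X.columns = [f"f{j}" for j in range(30)]
            y = rng.permutation([1] * 20 + [0] * 60)
            if best_split(X, y, ChaidParams(alpha=0.05)) is None:
                none_count += 1
        assert none_count >= int(0.9 * runs)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            best_split(pd.DataFrame(columns=["a"]), np.array([]), ChaidParams())


def _counts_conserved(node):
    if node.is_leaf:
        return True
    total = np.zeros(2)
    for child in node.children.values():
        total += np.array(child.n_per_class)
        if not _counts_conserved(child):
            return False
    return tuple(total.astype(int)) == tuple(node.n_per_class)


class TestGrow:
    def test_pure_noise_gives_single_leaf(self, noise_matrix):
        X, y = noise_matrix
        est = ChaidClassifier(alpha=0.01, max_height=4).fit(X, y)
        assert est.tree_.is_leaf
        assert est.predict(X).sum() == 0   # majority class: not frail

    def test_root_splits_on_a_planted_feature(self, study_cohort):
        _, _, _, fm, y = study_cohort
        est = ChaidClassifier(alpha=0.12, max_height=4).fit(fm.X, y)
        planted = {"ed_icd9_290", "med_atc_C03", "med_word_vitamins",
                   "bil_word_obstruction"}
        assert est.tree_.feature in planted
        assert est.tree_.p_adjusted <= 0.12

    def test_height_cap(self):
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame({"signal": y, "other": np.tile([0, 1], 30)})
        est = ChaidClassifier(alpha=0.05, max_height=1).fit(X, y)
        assert est.depth_ == 1
        assert len(est.tree_.children) == 2

    def test_single_class_input_single_leaf(self):
        X = pd.DataFrame({"a": [0, 1, 0, 1]})
        est = ChaidClassifier().fit(X, np.zeros(4, dtype=int))
        assert est.tree_.is_leaf
        assert (est.predict(X) == 0).all()

    def test_class_counts_conserved(self, study_cohort):
        _, _, _, fm, y = study_cohort
        est = ChaidClassifier(alpha=0.2, max_height=4).fit(fm.X, y)
        assert _counts_conserved(est.tree_)

    def test_internal_nodes_significant(self, study_cohort):
        _, _, _, fm, y = study_cohort
        est = ChaidClassifier(alpha=0.12, max_height=4).fit(fm.X, y)

        def check(node):
            if node.is_leaf:
                return
            assert node.p_adjusted <= 0.12
            for c in node.children.values():
                check(c)

        check(est.tree_)

    def test_larger_alpha_never_shallower(self, study_cohort):
        _, _, _, fm, y = study_cohort
        depths = []
        for alpha in (0.01, 0.12, 0.29):
            est = ChaidClassifier(alpha=alpha, max_height=4).fit(fm.X, y)
            depths.append(est.depth_)
        assert depths == sorted(depths)


class TestPredict:
    def test_single_leaf_constant(self, noise_matrix):
        X, y = noise_matrix
        est = ChaidClassifier(alpha=0.001).fit(X, y)
        assert len(np.unique(est.predict(X))) == 1

    def test_depth_one_training_predictions_match_leaf_majorities(self):
        y = np.array([0] * 30 + [1] * 10 + [1] * 15 + [0] * 5)
        X = pd.DataFrame({"f": [0] * 40 + [1] * 20})
        est = ChaidClassifier(alpha=0.05, max_height=1, min_node_size=5).fit(X, y)
        pred = est.predict(X)
        assert (pred[:40] == 0).all() and (pred[40:] == 1).all()

    def test_missing_feature_treated_as_zero(self, study_cohort):
        _, _, _, fm, y = study_cohort
        est = ChaidClassifier(alpha=0.12, max_height=2).fit(fm.X, y)
        root = est.tree_.feature
        dropped = fm.X.drop(columns=[root])
        zeroed = fm.X.copy()
        zeroed[root] = 0.0
        assert (est.predict(dropped) == est.predict(zeroed)).all()

    def test_generalization_to_fresh_cohort(self):
        """A tree trained on one planted cohort keeps its sensitivity on a
        fresh cohort from the same generating process (within 10 points)."""
        sig = (ef.SignalFeature("encounter_diagnosis_icd9", "290", 3.0, 0.15),)
        reports = []
        for seed in (21, 22):
            cfg = ef.SimConfig(n_physicians=134, signal_spec=sig, seed=seed)
            tables, assessments = ef.generate_cohort(cfg)
            labels = ef.dichotomize(assessments)
            fm = ef.build_feature_matrix(tables, labels)
            y = labels.labels.reindex(fm.X.index).to_numpy()
            reports.append((fm.X, y))
        (Xa, ya), (Xb, yb) = reports
        est = ChaidClassifier(alpha=0.12, max_height=4).fit(Xa, ya)

        def sens(X, y):
            pred = est.predict(X)
            return ((pred == 1) & (y == 1)).sum() / y.sum()

        assert abs(sens(Xa, ya) - sens(Xb, yb)) < 0.10


def test_json_roundtrip_preserves_predictions(tmp_path, study_cohort):
    _, _, _, fm, y = study_cohort
    est = ChaidClassifier(alpha=0.12, max_height=3).fit(fm.X, y)
    path = tmp_path / "tree.json"
    est.to_json(path)
    back = ChaidClassifier.from_json(path)
    assert (back.predict(fm.X) == est.predict(fm.X)).all()
    assert back.alpha == est.alpha and back.max_height == est.max_height


def test_sklearn_param_interface():
    est = ChaidClassifier(alpha=0.2)
    assert est.get_params()["alpha"] == 0.2
    est.set_params(max_height=2)
    assert est.max_height == 2
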