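"""Evaluation tests: confusion matrices, binomial CIs, pooled CV, and
bootstrap tuning."""

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyClassifier

import emrfrailty as ef
from emrfrailty.chaid import ChaidClassifier
from emrfrailty.evaluation import (
    ConfusionMatrix,
    bootstrap_tune,
    confusion,
    exact_binomial_ci,
    kfold_cv,
    metrics,
    wilson_cc_ci,
)


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert (cm.fp, cm.fn) == (0, 0)

    def test_all_negative_predictor(self):
        lab = np.array([1] * 155 + [0] * 720)
        cm = confusion(np.zeros_like(lab), lab)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (0, 155, 720, 0)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion([1, 2], [0, 1])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1], [0, 1])


class TestMetrics:
    def test_reference_counts_give_published_percentages(self):
        cm = ConfusionMatrix(tp=43, fp=32, fn=112, tn=688)
        rep = metrics(cm)
        pct = rep.to_percent_frame().set_index("metric")["estimate"]
        assert pct["sensitivity"] == 27.74
        assert pct["specificity"] == 95.56
        assert pct["ppv"] == 57.33
        assert pct["npv"] == 86.00
        assert pct["accuracy"] == 83.54

    def test_perfect_classifier(self):
        rep = metrics(ConfusionMatrix(10, 0, 0, 10))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert getattr(rep, name).estimate == 1.0

    def test_degenerate_predictor_ppv_undefined(self):
        rep = metrics(ConfusionMatrix(0, 0, 155, 720))
        assert rep.sensitivity.estimate == 0.0
        assert rep.specificity.estimate == 1.0
        assert rep.ppv is None
        assert rep.accuracy.estimate == pytest.approx(720 / 875)

    def test_estimates_inside_their_intervals(self):
        rep = metrics(ConfusionMatrix(43, 32, 112, 688))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m = getattr(rep, name)
            assert m.lower <= m.estimate <= m.upper
            assert 0.0 <= m.lower and m.upper <= 1.0

    def test_ppv_identity_with_sensitivity(self):
        # PPV*(TP+FP) and sensitivity*(TP+FN) both recover TP
        cm = ConfusionMatrix(43, 32, 112, 688)
        rep = metrics(cm)
        tp_a = rep.ppv.estimate * (cm.tp + cm.fp)
        tp_b = rep.sensitivity.estimate * (cm.tp + cm.fn)
        assert tp_a == pytest.approx(tp_b) == pytest.approx(cm.tp)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 0, 0))


class TestBinomialCI:
    def test_clopper_pearson_frozen_values(self):
        # computed independently from beta quantiles
        assert exact_binomial_ci(43, 155) == pytest.approx(
            (0.2086046004, 0.3549543109), abs=1e-9)
        assert exact_binomial_ci(688, 720) == pytest.approx(
            (0.9378343651, 0.9694045628), abs=1e-9)

    def test_boundaries(self):
        lo, hi = exact_binomial_ci(0, 20)
        assert lo == 0.0
        lo, hi = exact_binomial_ci(20, 20)
        assert hi == 1.0

    def test_wilson_cc_matches_r_prop_test(self):
        # oracle values from R: prop.test(x, n)$conf.int
        cases = {
            (43, 155): (0.2100645538, 0.3560253260),
            (688, 720): (0.9371315258, 0.9689246228),
            (7, 19): (0.1723002082, 0.6136729256),
            (1, 8): (0.0065599169, 0.5332108143),
            (30, 60): (0.3773502424, 0.6226497576),
        }
        for (x, n), expected in cases.items():
            assert wilson_cc_ci(x, n) == pytest.approx(expected, abs=1e-9)

    def test_invalid_counts(self):
        for fn in (exact_binomial_ci, wilson_cc_ci):
            with pytest.raises(ValueError):
                fn(5, 4)
            with pytest.raises(ValueError):
                fn(-1, 10)

    def test_clopper_pearson_coverage(self):
        """Exact intervals cover the true p with probability >= 0.95;
        checked by enumerating the full binomial distribution (stronger than
        a finite simulation, and free of Monte Carlo noise)."""
        from scipy.stats import binom
        p, n = 0.3, 155
        coverage = sum(
            binom.pmf(x, n, p)
            for x in range(n + 1)
            if exact_binomial_ci(x, n)[0] <= p <= exact_binomial_ci(x, n)[1]
        )
        assert coverage >= 0.95


class TestKfoldCV:
    def test_constant_majority_learner(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.integers(0, 2, (875, 5)).astype(float))
        y = np.array([1] * 155 + [0] * 720)
        rep, oof = kfold_cv(DummyClassifier(strategy="most_frequent"), X, y,
                            k=10, seed=0)
        assert rep.sensitivity.estimate == 0.0
        assert rep.specificity.estimate == 1.0
        assert rep.cm.n == 875

    def test_every_record_predicted_once(self, study_cohort):
        _, _, _, fm, y = study_cohort
        est = ChaidClassifier(alpha=0.12, max_height=2)
        rep, oof = kfold_cv(est, fm.X, y, k=10, seed=0)
        assert len(oof) == len(y)
        assert set(np.unique(oof)) <= {0, 1}
        assert rep.cm.positives == int(y.sum())
        assert rep.cm.negatives == int((1 - y).sum())

    def test_same_seed_identical_report(self, study_cohort):
        _, _, _, fm, y = study_cohort
        est = ChaidClassifier(alpha=0.12, max_height=2)
        r1, _ = kfold_cv(est, fm.X, y, k=5, seed=3)
        r2, _ = kfold_cv(est, fm.X, y, k=5, seed=3)
        assert r1.to_dict() == r2.to_dict()

    def test_k_larger_than_n_rejected(self):
        X = pd.DataFrame(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            kfold_cv(DummyClassifier(), X, np.array([0, 1, 0, 1, 0]), k=10)

    def test_planted_signal_beats_chance(self):
        """Cross-validated sensitivity of the tree exceeds the prevalence-
        matched chance level on cohorts with one strong planted feature."""
        sig = (ef.SignalFeature("encounter_diagnosis_icd9", "290", 3.0, 0.15),)
        wins = 0
        seeds = (31, 32, 33)
        for seed in seeds:
            cfg = ef.SimConfig(signal_spec=sig, seed=seed)
            tables, assessments = ef.generate_cohort(cfg)
            labels = ef.dichotomize(assessments)
            fm = ef.build_feature_matrix(tables, labels)
            y = labels.labels.reindex(fm.X.index).to_numpy()
            rep, _ = kfold_cv(ChaidClassifier(alpha=0.12, max_height=4),
                              fm.X, y, k=10, seed=seed)
            chance = y.mean()  # random classifier matched to prevalence
            wins += rep.sensitivity.estimate > chance
        assert wins == len(seeds)


class TestBootstrapTune:
    def test_singleton_grid_selected(self, noise_matrix):
        X, y = noise_matrix
        res = bootstrap_tune(pd.DataFrame(X), y, grid=[(0.12, 3)], B=5, seed=0)
        assert (res.best_alpha, res.best_height) == (0.12, 3)

    def test_pure_noise_youden_near_zero(self, noise_matrix):
        X, y = noise_matrix
        res = bootstrap_tune(pd.DataFrame(X), y,
                             grid=[(0.05, 2), (0.05, 4)], B=20, seed=1)
        youden = res.table["youden_mean"].to_numpy()
        assert np.nanmax(np.abs(youden)) < 0.15

    def test_strong_signal_prefers_shallow_tree(self):
        rng = np.random.default_rng(7)
        hits = 0
        runs = 5
        for seed in range(runs):
            rng = np.random.default_rng(200 + seed)
            n = 400
            x = rng.integers(0, 2, n)
            y = np.where(rng.random(n) < np.where(x == 1, 0.85, 0.1), 1, 0)
            X = pd.DataFrame({
                "signal": x.astype(float),
                **{f"n{j}": rng.integers(0, 2, n).astype(float) for j in range(8)},
            })
            res = bootstrap_tune(X, y, grid=[(0.12, h) for h in (2, 4, 6)],
                                 B=15, seed=seed)
            hits += res.best_height <= 2
        assert hits >= int(0.8 * runs)

    def test_deterministic_given_seed(self, noise_matrix):
        X, y = noise_matrix
        a = bootstrap_tune(pd.DataFrame(X), y, grid=[(0.1, 2)], B=10, seed=5)
        b = bootstrap_tune(pd.DataFrame(X), y, grid=[(0.1, 2)], B=10, seed=5)
        assert a.table.equals(b.table)

    def test_curves_long_format(self, noise_matrix):
        X, y = noise_matrix
        res = bootstrap_tune(pd.DataFrame(X), y, grid=[(0.1, 2)], B=5, seed=0)
        curves = res.curves()
        assert set(curves["metric"]) == {"sensitivity", "specificity", "ppv",
                                         "npv", "youden"}
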