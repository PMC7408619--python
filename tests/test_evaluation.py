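import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.cross_decomposition import PLSRegression

from seraspec import (
    CohortConfig,
    SplitPlan,
    confusion_metrics,
    default_profile,
    fit_split,
    generate_cohort,
    majority_vote,
    permute_patient_labels,
    resample_evaluate,
    roc_auc,
    split_patients,
    tune_hyperparameters,
)
from seraspec.chemometrics import FeatureMatrix, cohen_kappa
from seraspec.evaluation import _grouped_folds

from test_chemometrics import make_fm


@pytest.fixture(scope="module")
def balanced_cohort():
    """25+25-patient control/GBM cohort (compact axis work, default noise)."""
    config = CohortConfig(
        profiles={
            "control": (default_profile("control"), 25),
            "GBM": (default_profile("GBM"), 25),
        },
        seed=77,
    )
    return generate_cohort(config)


class TestSplitPatients:
    def test_stratified_counts(self, balanced_cohort):
        train, test = split_patients(
            balanced_cohort, "GBM", "control", 0.7, np.random.default_rng(0)
        )
        labels = balanced_cohort.patient_labels()
        assert len(train) == 36 and len(test) == 14  # round(0.7*25)=18 per class
        for cls in ("GBM", "control"):
            assert sum(labels[p] == cls for p in train) == 18
            assert sum(labels[p] == cls for p in test) == 7

    def test_no_patient_on_both_sides(self, balanced_cohort):
        for seed in range(5):
            train, test = split_patients(
                balanced_cohort, "GBM", "control", 0.7, np.random.default_rng(seed)
            )
            assert not set(train) & set(test)
            assert set(train) | set(test) == set(balanced_cohort.patient_ids)

    def test_same_seed_same_split(self, balanced_cohort):
        a = split_patients(balanced_cohort, "GBM", "control", 0.7, np.random.default_rng(3))
        b = split_patients(balanced_cohort, "GBM", "control", 0.7, np.random.default_rng(3))
        assert a == b

    def test_missing_class_errors(self, balanced_cohort):
        with pytest.raises(ValueError, match="nosuch"):
            split_patients(balanced_cohort, "nosuch", "control", 0.7, 0)


class TestTuning:
    def test_singleton_grid_short_circuits(self):
        fm = make_fm(np.random.default_rng(0).normal(size=(20, 3)),
                     np.r_[np.zeros(10), np.ones(10)])
        best, _ = tune_hyperparameters(fm, "plsda", [4], rng=0)
        assert best == 4

    def test_folds_partition_patients(self):
        patients = [f"p{i // 9}" for i in range(90)]  # 10 patients x 9 spectra
        folds = _grouped_folds(patients, 5, np.random.default_rng(1))
        union = set().union(*folds)
        assert union == set(f"p{i}" for i in range(10))
        assert sum(len(f) for f in folds) == 10  # disjoint cover

    def test_two_informative_directions_need_ncomp_two(self):
        """A response carried by two orthogonal feature directions: the
        kappa-CV pick matches a brute-force CV oracle and is >= 2."""
        rng = np.random.default_rng(6)
        n = 120
        X = rng.normal(size=(n, 6))
        # direction 1 strong, direction 2 needed to resolve the rest
        score = 1.0 * X[:, 0] + 1.0 * X[:, 1] * 2.0
        y = (score > 0).astype(int)
        patients = [f"p{i // 3}" for i in range(n)]  # 40 patients x 3 spectra
        fm = make_fm(X, y, patients=patients)
        grid = [1, 2, 3, 4, 5]
        best, table = tune_hyperparameters(
            fm, "plsda", grid, cv_folds=5, rng=np.random.default_rng(10)
        )

        # brute-force oracle over the identical folds
        folds = _grouped_folds(patients, 5, np.random.default_rng(10))
        pid = np.array(patients, dtype=object)
        oracle = []
        for g in grid:
            ks = []
            for fold in folds:
                val = np.isin(pid, list(fold))
                est = PLSRegression(n_components=g, scale=False)
                est.fit(X[~val], y[~val].astype(float))
                pred = (est.predict(X[val]).ravel() >= 0.5).astype(int)
                ks.append(cohen_kappa(y[val], pred))
            oracle.append(np.mean(ks))
        assert best == grid[int(np.argmax(oracle))]
        assert best >= 2
        np.testing.assert_allclose(table["kappa"], oracle, atol=1e-12)

    def test_fewer_patients_than_folds_errors(self):
        fm = make_fm(np.random.default_rng(0).normal(size=(4, 3)),
                     [0, 0, 1, 1], patients=["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="fewer patients"):
            tune_hyperparameters(fm, "plsda", [1, 2], cv_folds=5, rng=0)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "preds, expected",
        [([1, 1, 1, 1, 1, 0, 0, 0, 0], 1), ([0] * 9, 0), ([1] * 9, 1)],
    )
    def test_odd_count_modal_class(self, preds, expected):
        assert majority_vote(preds) == expected

    def test_even_tie_broken_by_mean_score(self):
        preds = [1, 1, 1, 1, 0, 0, 0, 0]
        high = [0.6, 0.6, 0.6, 0.6, 0.4, 0.4, 0.4, 0.4]  # mean 0.5 >= threshold
        low = [0.55, 0.55, 0.55, 0.55, 0.1, 0.1, 0.1, 0.1]  # mean 0.35
        assert majority_vote(preds, high) == 1
        assert majority_vote(preds, low) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestConfusionMetrics:
    def test_worked_ratios(self):
        """TP=29, FN=1, TN=26, FP=2 -> 96.67 / 92.86 / 94.76."""
        truths = [1] * 30 + [0] * 28
        preds = [1] * 29 + [0] + [0] * 26 + [1] * 2
        sens, spec, ba = confusion_metrics(truths, preds)
        assert sens == pytest.approx(96.67, abs=0.01)
        assert spec == pytest.approx(92.86, abs=0.01)
        assert ba == pytest.approx(94.76, abs=0.01)

    def test_perfect_prediction(self):
        assert confusion_metrics([1, 0, 1], [1, 0, 1]) == (100.0, 100.0, 100.0)

    def test_all_positive_predictions(self):
        sens, spec, ba = confusion_metrics([1, 1, 0, 0], [1, 1, 1, 1])
        assert (sens, spec, ba) == (100.0, 0.0, 50.0)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            confusion_metrics([1, 1], [1, 0])


class TestROC:
    def test_perfect_separation(self):
        curve = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)
        assert curve.fpr[0] == 0.0 and curve.tpr[-1] == 1.0

    def test_identical_scores_degenerate(self):
        curve = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert curve.auc == pytest.approx(0.5)
        np.testing.assert_array_equal(curve.fpr, [0.0, 1.0])
        np.testing.assert_array_equal(curve.tpr, [0.0, 1.0])

    def test_matches_mann_whitney_oracle(self):
        """AUC equals U/(n1*n2) on 200 randomly scored patients, to 1e-12."""
        rng = np.random.default_rng(12)
        truths = rng.integers(0, 2, size=200)
        while len(np.unique(truths)) < 2:
            truths = rng.integers(0, 2, size=200)
        scores = rng.normal(size=200) + 0.3 * truths
        curve = roc_auc(scores, truths)
        u = mannwhitneyu(scores[truths == 1], scores[truths == 0]).statistic
        n1, n0 = (truths == 1).sum(), (truths == 0).sum()
        assert curve.auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_passes_through_majority_vote_operating_point(self, balanced_cohort):
        """The pooled-score ROC contains the (FPR, TPR) point implied by the
        0.5-threshold patient predictions."""
        plan = SplitPlan(n_resamples=2, seed=4)
        summary = resample_evaluate(
            balanced_cohort, "plsda", "none", plan, "GBM", "control", grid=[3]
        )
        pooled = summary.patient_scores
        preds = (pooled["score"] >= 0.5).astype(int)
        t = pooled["truth"]
        tpr_op = ((preds == 1) & (t == 1)).sum() / (t == 1).sum()
        fpr_op = ((preds == 1) & (t == 0)).sum() / (t == 0).sum()
        on_curve = np.min(
            np.hypot(summary.roc.fpr - fpr_op, summary.roc.tpr - tpr_op)
        )
        assert on_curve < 1e-12


class TestFitSplit:
    def test_no_test_set_leakage(self, balanced_cohort):
        """Perturbing test-partition spectra changes neither the EMSC
        reference nor the fitted model coefficients."""
        train, test = split_patients(
            balanced_cohort, "GBM", "control", 0.7, np.random.default_rng(5)
        )
        kwargs = dict(grid=[3], rng=1)
        base = fit_split(
            balanced_cohort, train, test, "GBM", "control", "plsda", **kwargs
        )
        tampered_spectra = [
            s.replace(absorbances=s.absorbances + 0.5) if s.patient_id in set(test) else s
            for s in balanced_cohort.spectra
        ]
        from seraspec import SpectralDataset

        tampered = fit_split(
            SpectralDataset(tampered_spectra), train, test, "GBM", "control",
            "plsda", **kwargs
        )
        np.testing.assert_array_equal(
            base["reference"].absorbances, tampered["reference"].absorbances
        )
        np.testing.assert_array_equal(
            base["model"].estimator.coef_, tampered["model"].estimator.coef_
        )

    def test_patient_level_voting_output(self, balanced_cohort):
        train, test = split_patients(
            balanced_cohort, "GBM", "control", 0.7, np.random.default_rng(2)
        )
        result = fit_split(
            balanced_cohort, train, test, "GBM", "control", "plsda", grid=[3], rng=0
        )
        patients = result["patients"]
        assert set(patients["patient_id"]) == set(test)
        assert patients["prediction"].isin([0, 1]).all()
        assert result["balanced_accuracy"] == pytest.approx(
            (result["sensitivity"] + result["specificity"]) / 2
        )


class TestResampleEvaluate:
    def test_single_iteration_determinism(self, balanced_cohort):
        plan = SplitPlan(n_resamples=1, seed=9)
        a = resample_evaluate(balanced_cohort, "plsda", "none", plan, "GBM", "control",
                              grid=[2])
        b = resample_evaluate(balanced_cohort, "plsda", "none", plan, "GBM", "control",
                              grid=[2])
        pd.testing.assert_frame_equal(a.iterations, b.iterations)
        pd.testing.assert_frame_equal(a.patient_scores, b.patient_scores)
        assert a.balanced_accuracy_mean == b.balanced_accuracy_mean

    def test_summary_aggregates_iterations(self, balanced_cohort):
        plan = SplitPlan(n_resamples=3, seed=13)
        s = resample_evaluate(balanced_cohort, "plsda", "none", plan, "GBM", "control",
                              grid=[2, 3])
        assert s.balanced_accuracy_mean == pytest.approx(
            s.iterations["balanced_accuracy"].mean()
        )
        assert s.sensitivity_sd == pytest.approx(
            s.iterations["sensitivity"].std(ddof=1)
        )
        assert len(s.chosen_hyperparameters) == 3
        assert (
            (s.iterations["balanced_accuracy"]
             - (s.iterations["sensitivity"] + s.iterations["specificity"]) / 2)
            .abs()
            .max()
            < 1e-9
        )

    def test_effect_size_monotonicity(self):
        """Mean balanced accuracy does not decrease as the class effect grows
        (3 effect sizes, shared seeds, one pooled-SD slack)."""
        results = []
        for factor in (1.0, 1.25, 1.6):
            bumped = default_profile("control", band_scale={1550.0: factor})
            bumped.name = "case"
            ds = generate_cohort(
                CohortConfig(
                    profiles={
                        "control": (default_profile("control"), 15),
                        "case": (bumped, 15),
                    },
                    seed=21,
                )
            )
            plan = SplitPlan(n_resamples=3, seed=33)
            s = resample_evaluate(ds, "plsda", "none", plan, "case", "control",
                                  grid=[3])
            results.append((s.balanced_accuracy_mean, s.balanced_accuracy_sd))
        pooled_sd = float(np.sqrt(np.mean([sd**2 for _, sd in results])))
        assert results[1][0] >= results[0][0] - pooled_sd
        assert results[2][0] >= results[1][0] - pooled_sd
        assert results[2][0] >= results[0][0]

    def test_permuted_labels_preserve_structure(self, balanced_cohort):
        permuted = permute_patient_labels(balanced_cohort, np.random.default_rng(3))
        orig = balanced_cohort.patient_labels()
        new = permuted.patient_labels()
        assert sorted(orig.values()) == sorted(new.values())  # marginals kept
        assert orig != new  # some patient actually moved
        for s in permuted.spectra:  # all nine spectra move together
            assert s.label == new[s.patient_id]
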