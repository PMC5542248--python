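import numpy as np
import pytest

from ocri2 import (
    ConfigurationError,
    FeatureRow,
    FeatureTable,
    ModelSpec,
    OCRI2Model,
    StratificationError,
    TrainingError,
    assess_table,
    compute_ocri2,
    compute_ocri2_table,
    cross_examine,
    split_optimization_holdout,
    stratify_risk,
    tune_and_train,
)
from conftest import planted_table

FAST_RF = dict(
    hyperparameter_grid={"max_features": [2, 6], "n_estimators": [60]},
    cv_folds=3,
    cv_repeats=2,
)


class TestSplit:
    def test_stratified_counts(self):
        table = planted_table(100, seed=1)
        opt, hold = split_optimization_holdout(table, 0.7, seed=4)
        for lab in ("c", "n"):
            assert abs(opt.labels.count(lab) - 70) <= 1
            assert abs(hold.labels.count(lab) - 30) <= 1
        assert sorted(opt.case_ids + hold.case_ids) == sorted(table.case_ids)

    def test_full_fraction_leaves_empty_holdout(self):
        table = planted_table(10, seed=2)
        opt, hold = split_optimization_holdout(table, 1.0, seed=4)
        assert len(hold) == 0
        assert len(opt) == len(table)

    def test_deterministic(self):
        table = planted_table(25, seed=3)
        a = split_optimization_holdout(table, 0.7, seed=9)
        b = split_optimization_holdout(table, 0.7, seed=9)
        assert a[0].case_ids == b[0].case_ids and a[1].case_ids == b[1].case_ids

    def test_small_class_error(self):
        table = FeatureTable(
            [FeatureRow([1] + [0] * 9, "c", "c1")]
            + [FeatureRow([0] * 9 + [1], "n", f"n{i}") for i in range(4)]
        )
        with pytest.raises(StratificationError):
            split_optimization_holdout(table, 0.7, seed=1)


class TestTuneAndTrain:
    def test_separable_data_perfect_holdout(self, separable_table):
        spec = ModelSpec(model_kind="rf", seed=7, **FAST_RF)
        opt, hold = split_optimization_holdout(separable_table, 0.7, 7)
        model = tune_and_train(opt, spec)
        scores = compute_ocri2_table(model, hold)
        pred = ["c" if s >= 0.5 else "n" for s in scores]
        assert pred == hold.labels

    def test_tuning_table_shape(self, separable_table):
        spec = ModelSpec(model_kind="rf", seed=7, **FAST_RF)
        model = tune_and_train(separable_table, spec)
        assert len(model.tuning_table) == 2  # one row per candidate
        assert set(model.tuning_table["n_resamples"]) == {6}  # 3 folds x 2 repeats

    def test_reproducible_given_seed(self, separable_table):
        spec = ModelSpec(model_kind="rf", seed=13, **FAST_RF)
        m1 = tune_and_train(separable_table, spec)
        m2 = tune_and_train(separable_table, spec)
        assert m1.selected_params == m2.selected_params
        s1 = compute_ocri2_table(m1, separable_table)
        s2 = compute_ocri2_table(m2, separable_table)
        assert s1.tobytes() == s2.tobytes()

    def test_rejects_olk_rows(self, separable_table):
        rows = separable_table.rows + [FeatureRow([1] + [0] * 9, "k", "k1")]
        with pytest.raises(TrainingError, match="k"):
            tune_and_train(FeatureTable(rows), ModelSpec(seed=1, **FAST_RF))

    def test_single_class_error(self):
        rows = [FeatureRow([1] + [0] * 9, "n", f"n{i}") for i in range(12)]
        with pytest.raises(TrainingError):
            tune_and_train(FeatureTable(rows), ModelSpec(seed=1, **FAST_RF))

    def test_excessive_folds_suggests_fix(self):
        table = planted_table(4, seed=5)
        spec = ModelSpec(model_kind="rf", seed=1,
                         hyperparameter_grid={"n_estimators": [20]}, cv_folds=10)
        with pytest.raises(ConfigurationError, match="cv_folds <= 4"):
            tune_and_train(table, spec)

    @pytest.mark.parametrize("kind", ["svm", "knn", "cf"])
    def test_other_model_kinds_train_and_score(self, kind, separable_table):
        grid = {"svm": {"C": [1.0]}, "knn": {"n_neighbors": [3]},
                "cf": {"max_features": [4], "n_estimators": [60]}}[kind]
        spec = ModelSpec(model_kind=kind, seed=2, hyperparameter_grid=grid,
                         cv_folds=3, cv_repeats=1)
        model = tune_and_train(separable_table, spec)
        scores = compute_ocri2_table(model, separable_table)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_svmfull_forces_full_fraction(self):
        spec = ModelSpec(model_kind="svmfull", optimization_fraction=0.7)
        assert spec.optimization_fraction == 1.0


class TestOcri2:
    def test_vote_fraction_matches_per_tree_enumeration(self, separable_table):
        spec = ModelSpec(model_kind="rf", seed=3, **FAST_RF)
        model = tune_and_train(separable_table, spec)
        rng = np.random.default_rng(0)
        rows = [FeatureRow(list(rng.integers(0, 4, 10)), "n", f"q{i}") for i in range(20)]
        est = model.estimator
        for row in rows:
            X = np.array(row.counts, dtype=float)[None, :]
            votes = [est.classes_[int(t.predict(X)[0])] for t in est.estimators_]
            expected = votes.count("c") / len(votes)
            assert compute_ocri2(model, row) == pytest.approx(expected)

    def test_probability_bounds_random_rows(self, separable_table):
        spec = ModelSpec(model_kind="rf", seed=3, **FAST_RF)
        model = tune_and_train(separable_table, spec)
        rng = np.random.default_rng(1)
        rows = FeatureTable(
            [FeatureRow(list(rng.integers(0, 6, 10)), "k", f"r{i}") for i in range(50)]
        )
        scores = compute_ocri2_table(model, rows)
        assert np.all((scores >= 0) & (scores <= 1))


class TestStratifyRisk:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.5, "high"), (0.49, "low"), (0.0, "low"), (1.0, "high")],
    )
    def test_boundary_inclusive(self, value, expected):
        assert stratify_risk(value) == expected

    def test_domain_error(self):
        with pytest.raises(ValueError):
            stratify_risk(1.2)

    def test_assess_table(self, separable_table):
        spec = ModelSpec(model_kind="rf", seed=3, **FAST_RF)
        model = tune_and_train(separable_table, spec)
        assessments = assess_table(model, separable_table)
        for a in assessments:
            assert a.risk_class == ("high" if a.ocri2 >= 0.5 else "low")


class TestCrossExamine:
    def test_well_separated_cohorts(self):
        a = planted_table(30, seed=41)
        b = planted_table(30, seed=42)
        spec = ModelSpec(model_kind="rf", seed=6, **FAST_RF)
        r1, r2 = cross_examine(a, b, spec)
        for r in (r1, r2):
            assert r.sensitivity == 1.0
            assert r.specificity >= 0.95

    def test_resubstitution_not_worse_than_holdout(self):
        a = planted_table(30, seed=43)
        spec = ModelSpec(model_kind="rf", seed=6, **FAST_RF)
        resub, _ = cross_examine(a, a, spec)
        opt, hold = split_optimization_holdout(a, 0.7, 6)
        model = tune_and_train(opt, spec)
        scores = compute_ocri2_table(model, hold)
        from ocri2 import auc_rank

        holdout_auc = auc_rank(scores, hold.labels)
        assert resub.auc >= holdout_auc - 1e-12

    def test_olk_rows_scored_never_fitted(self):
        a = planted_table(15, seed=44)
        rows = a.rows + [FeatureRow([0] * 10, "k", "kx")]
        ak = FeatureTable(rows)
        spec = ModelSpec(model_kind="rf", seed=6, **FAST_RF)
        r1, r2 = cross_examine(ak, planted_table(15, seed=45), spec)
        # evaluation covers only c/n rows: totals match the c/n row counts
        assert r1.confusion.total == 30
        assert r2.confusion.total == 30


class TestModelResultsAPI:
    def test_fit_predict_summary(self, separable_table):
        spec = ModelSpec(model_kind="rf", seed=8, **FAST_RF)
        res = OCRI2Model(separable_table, spec).fit()
        frame = res.predict()
        assert list(frame.columns) == ["case_id", "ocri2", "risk_class"]
        assert len(frame) == len(separable_table)
        assert res.holdout_report is not None
        text = res.summary()
        assert "selected params" in text and "holdout evaluation" in text

    def test_full_fraction_has_no_holdout_report(self, separable_table):
        spec = ModelSpec(model_kind="rf", seed=8, optimization_fraction=1.0, **FAST_RF)
        res = OCRI2Model(separable_table, spec).fit()
        assert res.holdout_report is None

    def test_monotone_signal_with_aneuploid_prevalence(self, profiles):
        # raising planted aneuploid-peak prevalence in simulated leukoplakia
        # never lowers the mean OCRI2 of those cases
        from dataclasses import replace

        from ocri2 import CohortSpec, reconstruct_dataset, simulate_cohort

        train = planted_table(30, seed=46)
        spec = ModelSpec(model_kind="rf", seed=9, **FAST_RF)
        model = tune_and_train(train, spec)
        means = []
        for prev in (0.5, 0.75, 1.0):
            profile = replace(profiles["olk_high"], name="olk_high",
                              aneuploid_prevalence=prev)
            cases = simulate_cohort(CohortSpec(((profile, 30),), seed=77))
            table = reconstruct_dataset(cases)
            means.append(float(np.mean(compute_ocri2_table(model, table))))
        assert means[0] <= means[1] + 1e-9 <= means[2] + 2e-9
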