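"""Youden-threshold models, multivariate CV evaluation, SMOTE and the final
serialized model."""

import numpy as np
import pandas as pd
import pytest

from oracles import youden_bruteforce
from pirads3.models import (
    ClassifierSpec,
    FinalModel,
    PROPOSED_FAMILIES,
    ThresholdModel,
    evaluate_multivariate_cv,
    evaluate_univariate_cv,
    hectors_classifier_spec,
    jin_classifier_spec,
    smote_oversample,
    train_final_model,
    univariate_association_report,
    youden_threshold,
)
from pirads3.features.extract import HECTORS_FEATURES, JIN_FEATURES
from pirads3.selection import make_splits


class TestYoudenThreshold:
    def test_perfectly_separable(self):
        model = youden_threshold(
            np.array([0.0, 1.0, 2.0, 3.0]), np.array([0, 0, 1, 1])
        )
        assert model.youden == pytest.approx(1.0)
        assert model.direction == "above"
        assert 1.0 < model.threshold < 2.0
        assert model.predict(np.array([0.5, 2.5])).tolist() == [False, True]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_search(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=20)
        y = rng.integers(0, 2, size=20)
        y[:2], y[2:4] = 1, 0  # both classes present
        model = youden_threshold(v, y)
        assert model.youden == pytest.approx(youden_bruteforce(v, y), abs=1e-12)

    def test_null_feature_j_near_zero_in_expectation(self):
        rng = np.random.default_rng(1)
        js = []
        for _ in range(200):
            v = rng.normal(size=40)
            y = np.zeros(40, dtype=int)
            y[:13] = 1
            model = youden_threshold(v, rng.permutation(y))
            js.append(model.youden)
        # optimistic training bias makes E[J] > 0 but small at n=40
        assert 0.0 < np.mean(js) < 0.45

    def test_positive_below_direction(self):
        # representable published-style cutoffs: positives BELOW 0.47
        model = youden_threshold(
            np.array([0.3, 0.4, 0.6, 0.7]), np.array([1, 1, 0, 0])
        )
        assert model.direction == "below"
        m = ThresholdModel("regularity", 0.47, "below")
        assert m.predict(np.array([0.4, 0.5])).tolist() == [True, False]
        m2 = ThresholdModel("zone_size", 17.0, "above")
        assert m2.predict(np.array([20.0, 10.0])).tolist() == [True, False]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold(np.arange(4.0), np.ones(4, dtype=int))

    def test_training_confusion_reproducible(self, rng):
        v = rng.normal(size=30)
        y = np.zeros(30, dtype=int)
        y[:10] = 1
        model = youden_threshold(v, y)
        pred = model.predict(v)
        sens = pred[y == 1].mean()
        spec = (~pred[y == 0]).mean()
        assert sens + spec - 1.0 == pytest.approx(model.youden, abs=1e-12)


class TestUnivariateCV:
    def test_perfect_feature_gives_perfect_metrics(self):
        labels = np.zeros(40, dtype=int)
        labels[:13] = 1
        values = labels * 10.0 + np.arange(40) * 0.01
        splits = make_splits(labels, n_reps=4, n_folds=5, seed=0)
        rep = evaluate_univariate_cv(values, labels, splits, feature="x")
        assert rep.n_trials == 20
        assert rep.mean_sens == 1.0 and rep.sd_sens == 0.0
        assert rep.mean_spec == 1.0 and rep.sd_spec == 0.0

    def test_mean_sd_recomputable_from_trial_vectors(self, rng):
        labels = np.zeros(30, dtype=int)
        labels[:10] = 1
        values = labels + rng.normal(0, 1.0, 30)
        splits = make_splits(labels, 3, 5, seed=1)
        rep = evaluate_univariate_cv(values, labels, splits)
        assert rep.mean_sens == pytest.approx(np.nanmean(rep.sensitivity))
        assert rep.sd_spec == pytest.approx(np.nanstd(rep.specificity))


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        x = rng.normal(size=(10, 3))
        y = np.array([0] * 5 + [1] * 5)
        x2, y2 = smote_oversample(x, y, rng)
        np.testing.assert_array_equal(x, x2)
        np.testing.assert_array_equal(y, y2)

    def test_balances_class_counts(self, rng):
        x = rng.normal(size=(30, 4))
        y = np.array([0] * 22 + [1] * 8)
        x2, y2 = smote_oversample(x, y, rng)
        assert (y2 == 0).sum() == (y2 == 1).sum() == 22
        assert len(x2) == 44

    def test_two_minority_points_interpolate_on_segment(self, rng):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 9.0], [6.0, 8.0], [7.0, 7.0]])
        y = np.array([1, 1, 0, 0, 0])
        x2, y2 = smote_oversample(x, y, rng)
        new = x2[5:]
        # synthetic minority points lie on the segment between the two
        # minority samples: coordinates equal and within [0, 1]
        assert np.allclose(new[:, 0], new[:, 1])
        assert np.all((new >= 0.0) & (new <= 1.0))

    def test_single_minority_sample_rejected(self, rng):
        x = np.zeros((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            smote_oversample(x, y, rng)


class TestMultivariateCV:
    @pytest.fixture(scope="class")
    def setup(self):
        rng = np.random.default_rng(12)
        labels = np.zeros(40, dtype=int)
        labels[:13] = 1
        labels = rng.permutation(labels)
        feats = pd.DataFrame(
            {
                "a": labels * 1.5 + rng.normal(0, 1, 40),
                "b": labels * 1.0 + rng.normal(0, 1, 40),
                "c": rng.normal(size=40),
            }
        )
        splits = make_splits(labels, n_reps=2, n_folds=5, seed=3)
        return feats, labels, splits

    def test_all_subsets_of_three_by_six_families(self, setup):
        feats, labels, splits = setup
        specs = [ClassifierSpec(family=f) for f in PROPOSED_FAMILIES]
        reports = evaluate_multivariate_cv(
            feats, labels, splits, specs, ["a", "b", "c"], seed=0
        )
        assert len(reports) == 7 * 6
        assert len({r.model for r in reports}) == 6
        assert len({r.features for r in reports}) == 7
        assert all(r.n_trials == 10 for r in reports)
        # reports are ranked by mean Youden index
        js = [r.mean_youden for r in reports]
        assert js == sorted(js, reverse=True)

    def test_duplicate_feature_leaves_lda_performance_close(self, setup):
        feats, labels, splits = setup
        feats = feats.copy()
        feats["a_dup"] = feats["a"] + 1e-9  # avoid exact collinearity
        spec = [ClassifierSpec(family="linear_discriminant")]
        r1 = evaluate_multivariate_cv(
            feats, labels, splits, spec, ["a"], seed=0, combinations="full"
        )[0]
        r2 = evaluate_multivariate_cv(
            feats, labels, splits, spec, ["a", "a_dup"], seed=0, combinations="full"
        )[0]
        assert abs(r1.mean_youden - r2.mean_youden) < 0.25

    def test_literature_specs(self, setup):
        feats, labels, splits = setup
        for spec in (hectors_classifier_spec(), jin_classifier_spec()):
            rep = evaluate_multivariate_cv(
                feats, labels, splits, [spec], ["a", "b"], seed=1, combinations="full"
            )[0]
            assert 0.0 <= rep.mean_sens <= 1.0 and 0.0 <= rep.mean_spec <= 1.0


class TestFinalModel:
    def test_lda_roundtrip_reproduces_predictions(self, tmp_path, rng):
        labels = np.zeros(40, dtype=int)
        labels[:13] = 1
        feats = pd.DataFrame(
            {
                "u": labels + rng.normal(0, 0.7, 40),
                "v": labels + rng.normal(0, 0.9, 40),
                "w": rng.normal(size=40),
            }
        )
        model = train_final_model(
            feats, labels, ClassifierSpec(family="linear_discriminant"), ["u", "v", "w"]
        )
        assert model.weights.shape == (3,)  # per-feature weights exposed
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = FinalModel.from_json(path)
        x = feats.to_numpy(float)
        np.testing.assert_array_equal(model.predict(x), loaded.predict(x))
        np.testing.assert_array_equal(model.scores(x), loaded.scores(x))

    def test_unresolved_features_rejected(self, rng):
        feats = pd.DataFrame({"u": rng.normal(size=10)})
        with pytest.raises(ValueError, match="unresolved"):
            train_final_model(
                feats,
                np.array([0, 1] * 5),
                ClassifierSpec(family="linear_discriminant"),
                ["u", "missing"],
            )

    def test_unsupported_family_rejected(self, rng):
        feats = pd.DataFrame({"u": rng.normal(size=10)})
        with pytest.raises(ValueError, match="serializ"):
            train_final_model(
                feats, np.array([0, 1] * 5), ClassifierSpec(family="tree"), ["u"]
            )


class TestAssociationReport:
    def test_literature_inventories_give_20_plus_4_rows(self, rng):
        labels = np.array([0, 1] * 20)
        names = list(HECTORS_FEATURES) + list(JIN_FEATURES)
        feats = pd.DataFrame(
            rng.normal(size=(40, len(names))), columns=names
        )
        report = univariate_association_report(feats, labels, names)
        assert len(report) == 24
        assert report["available"].all()

    def test_missing_features_flagged_not_dropped(self, rng):
        labels = np.array([0, 1] * 10)
        feats = pd.DataFrame({"present": rng.normal(size=20)})
        report = univariate_association_report(feats, labels, ["present", "absent"])
        assert len(report) == 2
        row = report.set_index("feature").loc["absent"]
        assert not row["available"] and np.isnan(row["p_value"])

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        labels = np.zeros(60, dtype=int)
        labels[:20] = 1
        names = [f"f{i:03d}" for i in range(300)]
        feats = pd.DataFrame(rng.normal(size=(60, 300)), columns=names)
        report = univariate_association_report(feats, labels, names)
        frac = report["significant"].mean()
        assert 0.01 < frac < 0.12  # ~5% at alpha = 0.05

    def test_separating_feature_attains_minimal_p(self):
        labels = np.array([0] * 10 + [1] * 10)
        feats = pd.DataFrame({"sep": np.arange(20.0)})
        report = univariate_association_report(feats, labels, ["sep"])
        p = report["p_value"].iloc[0]
        # smallest achievable two-sided asymptotic p for 10 vs 10
        assert p < 2e-4
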