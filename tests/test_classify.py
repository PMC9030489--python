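import numpy as np
import pandas as pd
import pytest

import swaylab as sl
from swaylab.classify import (
    CLASSIFIER_ROSTER,
    KernelNaiveBayes,
    accuracy_eq1,
    cross_validate,
    extract_features,
    label_trials,
    make_classifier,
    zscore,
)
from swaylab.design import Condition
from swaylab.simulate import StudyDataset, TrialRecording


def _manual_trial(acc_pelvis, pps=5.0, cop=None, rate=60.0):
    return TrialRecording(
        subject_id=1,
        condition=Condition("P1", "flat", "0kg"),
        repetition=1,
        acc={"pelvis": acc_pelvis},
        cop=cop if cop is not None else np.zeros((80, 2)),
        pps=pps,
        acc_rate=rate,
        cop_rate=40.0,
    )


class TestExtractFeatures:
    @pytest.mark.parametrize(
        "fs,width_per_sensor", [("FS1", 21), ("FS2", 15), ("FS3", 36)]
    )
    def test_feature_widths_per_sensor(self, tiny_study, fs, width_per_sensor):
        feats = extract_features(tiny_study, "SC3", fs)
        assert feats.shape == (len(tiny_study.trials), 2 * width_per_sensor)

    def test_sc3_fs3_is_72_columns(self, tiny_study):
        assert extract_features(tiny_study, "SC3", "FS3").shape[1] == 72

    def test_unknown_names_rejected(self, tiny_study):
        with pytest.raises(ValueError):
            extract_features(tiny_study, "SC9", "FS1")
        with pytest.raises(ValueError):
            extract_features(tiny_study, "SC1", "FS4")

    def test_constant_signal_degenerate_moments(self):
        trial = _manual_trial(np.full((120, 3), 2.5))
        cfg = sl.StudyConfig(
            n_subjects=1, n_repetitions=1, trial_duration=2.0, acc_rate=60.0,
            sensor_set=("pelvis",),
        )
        ds = StudyDataset([trial], cfg)
        feats = extract_features(ds, ["pelvis"], "FS1")
        row = feats.iloc[0]
        assert row["pelvis|AP|mean"] == 2.5
        for f in ("range", "variance", "std", "skewness", "kurtosis"):
            assert row[f"pelvis|AP|{f}"] == 0.0

    def test_fft_features_locate_a_low_frequency_tone(self):
        # 10 s at 60 Hz: rfft bins are 0.1 Hz apart; a 0.3 Hz tone must
        # land its energy in the third nonzero coefficient
        t = np.arange(0, 10, 1 / 60.0)
        acc = np.zeros((len(t), 3))
        acc[:, 0] = np.sin(2 * np.pi * 0.3 * t)
        cfg = sl.StudyConfig(
            n_subjects=1, n_repetitions=1, trial_duration=10.0, acc_rate=60.0,
            sensor_set=("pelvis",),
        )
        ds = StudyDataset([_manual_trial(acc)], cfg)
        feats = extract_features(ds, ["pelvis"], "FS2")
        fft_cols = [f"pelvis|AP|fft{i}" for i in range(1, 6)]
        vals = feats.iloc[0][fft_cols]
        assert vals.idxmax() == "pelvis|AP|fft3"
        # independent oracle: direct transform magnitude at that bin
        expected = np.abs(np.fft.rfft(acc[:, 0])[3])
        assert vals.max() == pytest.approx(expected, rel=1e-9)


class TestLabeling:
    def test_pps_boundary_goes_unstable(self, tiny_config):
        trials = [
            _manual_trial(np.zeros((120, 3)), pps=v) for v in (4.99, 5.0, 0.0, 10.0)
        ]
        ds = StudyDataset(trials, tiny_config)
        labels = label_trials(ds, "pps")
        assert list(labels) == [0, 1, 0, 1]

    def test_copv_median_split_balanced(self, tiny_config):
        trials = []
        for speed in (1.0, 2.0, 3.0, 4.0):
            cop = np.zeros((80, 2))
            cop[:, 0] = np.linspace(0, speed * 2.0, 80)
            trials.append(_manual_trial(np.zeros((120, 3)), cop=cop))
        ds = StudyDataset(trials, tiny_config)
        labels = label_trials(ds, "copv_ap", cop_cutoff=15.0)
        assert list(labels) == [0, 0, 1, 1]
        assert abs(int(labels.sum()) - (len(labels) - int(labels.sum()))) <= 1

    def test_unknown_criterion_rejected(self, tiny_study):
        with pytest.raises(ValueError):
            label_trials(tiny_study, "cop_ml")


class TestZScore:
    def test_population_sd_closed_form(self):
        out, flagged = zscore(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(
            out["a"], [-1.224744871, 0.0, 1.224744871], rtol=1e-8
        )
        assert flagged == []

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.standard_normal((50, 4)))
        once, _ = zscore(df)
        twice, _ = zscore(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_column_flagged_zeroed(self):
        out, flagged = zscore(pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]}))
        assert flagged == ["b"]
        assert (out["b"] == 0).all()


class TestAccuracy:
    def test_eq1_direct(self):
        assert accuracy_eq1(40, 45, 50, 50) == 85.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy_eq1(0, 0, 0, 0)


def _blobs(rng, n=120, sep=6.0):
    x0 = rng.standard_normal((n // 2, 4))
    x1 = rng.standard_normal((n // 2, 4)) + sep
    X = np.vstack([x0, x1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestCrossValidate:
    @pytest.mark.parametrize("clf", CLASSIFIER_ROSTER)
    def test_separable_blobs_all_classifiers(self, rng, clf):
        X, y = _blobs(rng)
        res = cross_validate(X, y, clf, k=5, seed=0)
        assert res["mean_accuracy"] >= 95.0

    def test_deterministic_given_seed(self, rng):
        X, y = _blobs(rng, sep=1.0)
        a = cross_validate(X, y, "LogisticRegression", seed=3)
        b = cross_validate(X, y, "LogisticRegression", seed=3)
        assert a["fold_accuracies"] == b["fold_accuracies"]

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError):
            cross_validate(X, np.zeros(20), "GaussianNB")

    def test_unknown_classifier_rejected(self, rng):
        X, y = _blobs(rng)
        with pytest.raises(ValueError):
            cross_validate(X, y, "RandomKitchenSink")

    def test_permuted_labels_near_chance(self, rng):
        X, y = _blobs(rng, n=200, sep=4.0)
        accs = []
        for i in range(20):
            yp = rng.permutation(y)
            if len(np.unique(yp)) < 2:
                continue
            accs.append(
                cross_validate(X, yp, "LogisticRegression", seed=i)["mean_accuracy"]
            )
        assert 40.0 <= np.mean(accs) <= 60.0

    def test_grouped_folds_respect_groups(self, rng):
        X, y = _blobs(rng, n=120, sep=6.0)
        groups = np.repeat(np.arange(12), 10)
        res = cross_validate(X, y, "GaussianNB", seed=0, groups=groups)
        assert res["mean_accuracy"] >= 90.0


def test_kernel_nb_matches_gaussian_intuition(rng):
    # on well-separated 1-d classes the KDE-based NB must be near perfect
    X = np.concatenate([rng.normal(-3, 1, 100), rng.normal(3, 1, 100)])[:, None]
    y = np.array([0] * 100 + [1] * 100)
    clf = KernelNaiveBayes().fit(X, y)
    pred = clf.predict(np.array([[-3.0], [3.0], [-2.0], [2.5]]))
    assert list(pred) == [0, 1, 0, 1]


def test_roster_instantiation_complete():
    for name in CLASSIFIER_ROSTER:
        assert make_classifier(name, seed=0) is not None


class TestGridReport:
    def test_grid_shape_and_summary_consistency(self, tiny_study):
        report = sl.ClassificationGrid(
            tiny_study,
            sensor_configs=("pelvis", "SC3"),
            feature_sets=("FS1", "FS2"),
            classifiers=("GaussianNB", "LogisticRegression"),
            criterion="pps",
        ).fit(seed=0)
        assert report.accuracy.shape == (2, 4)
        full = report.with_summary_rows()
        np.testing.assert_allclose(
            full.loc["Average"], report.accuracy.mean(axis=0)
        )
        np.testing.assert_allclose(
            full.loc["Maximum"], report.accuracy.max(axis=0)
        )
        assert ((report.accuracy >= 0) & (report.accuracy <= 100)).all().all()

    def test_grid_deterministic(self, tiny_study):
        kwargs = dict(
            sensor_configs=("pelvis",),
            feature_sets=("FS1",),
            classifiers=("DecisionTree",),
            criterion="pps",
        )
        a = sl.ClassificationGrid(tiny_study, **kwargs).fit(seed=5)
        b = sl.ClassificationGrid(tiny_study, **kwargs).fit(seed=5)
        pd.testing.assert_frame_equal(a.accuracy, b.accuracy)
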