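"""Screening statistics, metrics, cross-validation protocols and noise."""

import itertools

import numpy as np
import pytest

from mfc_spectra import (
    ClassifierSpec,
    FeatureTable,
    ValidationError,
    add_noise,
    confusion_metrics,
    cv_leave_one_fold_out,
    cv_leave_one_sample_out,
    cv_stratified_kfold,
    mann_whitney_u,
    noise_sweep,
    single_feature_auc,
)
from mfc_spectra.evaluation import HYPERPARAMETER_GRIDS, screen_features
from conftest import make_series


def permutation_p_value(a, b):
    """Exact two-sided Mann-Whitney p by full label enumeration.

    Uses the symmetry of the null U distribution around n1*n2/2: the
    two-sided p is the probability of a deviation at least as large.
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)
    mu = n1 * len(b) / 2.0

    def u_stat(idx_a):
        x = pooled[list(idx_a)]
        rest = pooled[[i for i in range(len(pooled)) if i not in idx_a]]
        return sum((xi > r) + 0.5 * (xi == r) for xi in x for r in rest)

    observed = abs(u_stat(tuple(range(n1))) - mu)
    total = hits = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - mu) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_fully_separated_two_by_two(self):
        u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_not_significant(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_exact_p_matches_permutation_enumeration(self, rng):
        for n in (3, 5, 8):
            a = rng.normal(0, 1, n)
            b = rng.normal(0.8, 1, n)
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(permutation_p_value(a, b), abs=1e-12)

    def test_asymptotic_p_close_to_monte_carlo_permutation(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.7, 1, 15)
        _, p = mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        hits = 0
        n_mc = 20_000
        mu = len(a) * len(b) / 2

        def u_of(x, y):
            return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

        observed = abs(u_of(a, b) - mu)
        for _ in range(n_mc):
            perm = rng.permutation(pooled)
            hits += abs(u_of(perm[:15], perm[15:]) - mu) >= observed
        assert p == pytest.approx(hits / n_mc, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestSingleFeatureAUC:
    def test_perfect_separation(self):
        res = single_feature_auc(
            [1, 2, 3, 10, 11], ["unimproved"] * 3 + ["improved"] * 2
        )
        assert res.auc == 1.0

    def test_all_tied_values_give_half(self):
        res = single_feature_auc([5.0] * 6, ["improved"] * 3 + ["unimproved"] * 3)
        assert res.auc == 0.5

    def test_orientation_flip_recorded(self):
        res = single_feature_auc(
            [10, 11, 1, 2, 3], ["unimproved"] * 2 + ["improved"] * 3
        )
        assert res.flipped and res.auc == 1.0 and res.raw == 0.0

    def test_auc_u_identity(self, rng):
        values = rng.normal(size=20)
        labels = ["improved"] * 12 + ["unimproved"] * 8
        res = single_feature_auc(values, labels)
        pos = values[:12]
        neg = values[12:]
        u_pos = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert res.raw * 12 * 8 == pytest.approx(u_pos, abs=1e-9)


class TestConfusionMetrics:
    def test_all_positive_on_study_sized_cohort(self):
        y_true = ["improved"] * 14 + ["unimproved"] * 5
        m = confusion_metrics(y_true, ["improved"] * 19)
        assert round(m.acc, 2) == 73.68
        assert m.sens == 100.0
        assert m.spec == 0.0
        assert round(m.f1, 2) == 84.85

    def test_perfect_prediction(self):
        y = ["improved", "unimproved"] * 3
        m = confusion_metrics(y, y)
        assert (m.acc, m.sens, m.spec, m.f1) == (100.0, 100.0, 100.0, 100.0)

    def test_all_wrong_balanced(self):
        y_true = ["improved", "unimproved"] * 2
        y_pred = ["unimproved", "improved"] * 2
        m = confusion_metrics(y_true, y_pred)
        assert m.acc == 0.0 and m.f1 == 0.0

    def test_undefined_ratio_flagged(self):
        m = confusion_metrics(["improved"] * 3, ["improved"] * 3)
        assert m.spec == 0.0 and "spec_undefined" in m.flags

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion_metrics(["improved"], ["worse"])


def separable_table(n_per_class=10, gap=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x_pos = rng.normal(0.0, 0.5, (n_per_class, 2))
    x_neg = rng.normal(gap, 0.5, (n_per_class, 2))
    return FeatureTable(
        [f"s{i}" for i in range(2 * n_per_class)],
        ["f1", "f2"],
        np.vstack([x_pos, x_neg]),
        ["improved"] * n_per_class + ["unimproved"] * n_per_class,
    )


LINEAR_SVM = ClassifierSpec("svm", {"kernel": "linear", "C": 1})


class TestCrossValidation:
    def test_loso_perfect_on_separable_cohort(self):
        rep = cv_leave_one_sample_out(separable_table(), LINEAR_SVM, seed=3)
        assert rep.metrics.acc == 100.0
        assert rep.n_repeats == 20
        assert len(rep.per_iteration) == 20  # exactly n held-out predictions

    def test_loso_on_permuted_labels_is_near_chance(self):
        t = separable_table(n_per_class=15)
        rng = np.random.default_rng(11)
        permuted = list(rng.permutation(t.labels))
        tp = FeatureTable(t.subject_ids, t.feature_names, t.matrix, permuted)
        rep = cv_leave_one_sample_out(tp, LINEAR_SVM, seed=3)
        # binomial 95% band around 0.5 for n=30 is roughly [0.32, 0.68]
        assert 20.0 <= rep.metrics.acc <= 80.0

    def test_lofo_deterministic_and_perfect_on_separable(self):
        t = separable_table()
        r1 = cv_leave_one_fold_out(t, LINEAR_SVM, n_repeats=10, seed=5)
        r2 = cv_leave_one_fold_out(t, LINEAR_SVM, n_repeats=10, seed=5)
        assert r1.metrics.acc == r2.metrics.acc == 100.0
        assert [m.acc for m in r1.per_iteration] == [m.acc for m in r2.per_iteration]

    def test_lofo_class_size_guard(self):
        t = separable_table(n_per_class=4)
        with pytest.raises(ValidationError):
            cv_leave_one_fold_out(t, LINEAR_SVM, n_per_class=4)

    def test_stratified_kfold_keeps_one_minority_per_fold(self):
        rng = np.random.default_rng(2)
        t = FeatureTable(
            [f"s{i}" for i in range(19)],
            ["f1"],
            rng.normal(size=(19, 1)),
            ["improved"] * 14 + ["unimproved"] * 5,
        )
        rep = cv_stratified_kfold(t, LINEAR_SVM, k=5, seed=1)
        assert rep.n_repeats == 5
        for m in rep.per_iteration:
            assert m.tn + m.fp == 1  # exactly one unimproved subject per fold

    def test_stratified_kfold_deterministic_and_perfect_on_separable(self):
        t = separable_table()
        r1 = cv_stratified_kfold(t, LINEAR_SVM, seed=9)
        r2 = cv_stratified_kfold(t, LINEAR_SVM, seed=9)
        assert r1.metrics.acc == r2.metrics.acc == 100.0

    def test_metric_average_invariant_to_repeat_order(self):
        t = separable_table(gap=1.0)
        rep = cv_leave_one_fold_out(t, LINEAR_SVM, n_repeats=8, seed=2)
        accs = [m.acc for m in rep.per_iteration]
        assert rep.metrics.acc == pytest.approx(np.mean(accs))
        assert rep.metrics.acc == pytest.approx(np.mean(accs[::-1]))

    @pytest.mark.parametrize("kind", sorted(HYPERPARAMETER_GRIDS))
    def test_every_classifier_kind_runs_loso(self, kind):
        rep = cv_leave_one_sample_out(
            separable_table(n_per_class=5), ClassifierSpec(kind), seed=0
        )
        assert 0.0 <= rep.metrics.acc <= 100.0
        assert 0.0 <= rep.metrics.auc <= 1.0

    def test_off_grid_hyperparameter_warns(self):
        with pytest.warns(UserWarning, match="outside the declared grid"):
            ClassifierSpec("svm", {"C": 7})


class TestNoise:
    def test_zero_percent_returns_identical_series(self):
        s = make_series(np.linspace(0.1, 0.9, 50), normalized=True)
        out = add_noise(s, 0, seed=1)
        np.testing.assert_array_equal(out.values, s.values)

    def test_noise_sd_matches_requested_fraction(self, rng):
        x = rng.uniform(0.2, 0.8, 10_000)
        s = make_series(x, normalized=True)
        out = add_noise(s, 30, seed=4)
        ratio = np.std(out.values - x, ddof=1) / np.std(x, ddof=1)
        assert ratio == pytest.approx(0.30, rel=0.02)

    def test_seed_reproducibility(self):
        s = make_series(np.linspace(0.1, 0.9, 100), normalized=True)
        a = add_noise(s, 20, seed=7)
        b = add_noise(s, 20, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_negative_percent_rejected(self):
        s = make_series([0.1, 0.2], normalized=True)
        with pytest.raises(ValidationError):
            add_noise(s, -1)


class TestNoiseSweep:
    def test_level_zero_reproduces_clean_loso(self, small_cohort):
        from mfc_spectra.pipeline import extractor_for

        extractor = extractor_for("spectral")
        table = FeatureTable.from_records(
            [(s.subject_id, s.label, extractor(s)) for s in small_cohort]
        )
        clean = cv_leave_one_sample_out(table, LINEAR_SVM, seed=13)
        reports = noise_sweep(
            small_cohort, extractor, LINEAR_SVM, levels=(0, 20), seed=13
        )
        assert reports[0].metrics.acc == clean.metrics.acc
        assert reports[0].metrics.auc == clean.metrics.auc
        assert reports[0].extra["noise_percent"] == 0.0
        assert reports[1].extra["noise_percent"] == 20.0

    def test_noise_does_not_inflate_auc(self, calibrated_cohort):
        from mfc_spectra.pipeline import extractor_for

        reports = noise_sweep(
            calibrated_cohort,
            extractor_for("spectral"),
            LINEAR_SVM,
            levels=(0, 30),
            seed=3,
        )
        assert reports[1].metrics.auc <= reports[0].metrics.auc + 0.05


class TestScreening:
    def test_screen_table_columns_and_identity(self, rng):
        t = FeatureTable(
            [f"s{i}" for i in range(12)],
            ["good", "junk"],
            np.column_stack(
                [np.r_[rng.normal(3, 1, 6), rng.normal(0, 1, 6)], rng.normal(size=12)]
            ),
            ["improved"] * 6 + ["unimproved"] * 6,
        )
        df = screen_features(t)
        assert list(df["feature"]) == ["good", "junk"]
        good = df[df.feature == "good"].iloc[0]
        junk = df[df.feature == "junk"].iloc[0]
        assert good["p_value"] < junk["p_value"]
        assert good["auc"] > junk["auc"]
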