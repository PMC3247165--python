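"""Tests of metrics, outer cross-validation and the benchmark driver."""

import numpy as np
import pytest

from brierscoremf import (
    SyntheticConfig,
    TrainerConfig,
    aggregate_benchmark,
    confusion_counts,
    generate_design,
    mcc,
    outer_cv,
    predict_classes,
    reconstruction_error,
    run_benchmark,
    sample_dataset,
    sensitivity_specificity,
)


class TestConfusionCounts:
    def test_perfect_prediction(self, rng):
        Y = np.where(rng.random((10, 3)) < 0.5, -1.0, 1.0)
        tp, tn, fp, fn = confusion_counts(Y, Y)
        assert np.all(fp == 0) and np.all(fn == 0)
        assert np.all(tp + tn == 10)

    def test_inverted_prediction(self, rng):
        Y = np.where(rng.random((10, 3)) < 0.5, -1.0, 1.0)
        tp, tn, fp, fn = confusion_counts(Y, -Y)
        assert np.all(tp == 0) and np.all(tn == 0)

    def test_hand_tally(self):
        Y = np.array([[1, -1], [1, -1], [-1, 1], [-1, 1]], dtype=float)
        Yhat = np.array([[1, -1], [-1, 1], [-1, -1], [-1, 1]], dtype=float)
        tp, tn, fp, fn = confusion_counts(Y, Yhat)
        # tallied by hand one column at a time
        assert list(tp) == [1, 1]
        assert list(fn) == [1, 1]
        assert list(tn) == [2, 1]
        assert list(fp) == [0, 1]
        assert np.all(tp + tn + fp + fn == 4)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(np.ones((2, 2)), np.ones((3, 2)))


class TestRates:
    def test_sensitivity_formula(self):
        s, t = sensitivity_specificity(np.array([3.0]), np.array([5.0]), np.array([0.0]), np.array([1.0]))
        assert s[0] == pytest.approx(0.75)
        assert t[0] == pytest.approx(1.0)

    def test_empty_class_gives_undefined_marker(self):
        s, t = sensitivity_specificity(np.array([0.0]), np.array([4.0]), np.array([0.0]), np.array([0.0]))
        assert np.isnan(s[0])
        assert t[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("counts, expected", [
        ((3.0, 4.0, 0.0, 0.0), 1.0),
        ((0.0, 0.0, 2.0, 3.0), -1.0),
        ((1.0, 1.0, 1.0, 1.0), 0.0),
    ])
    def test_mcc_reference_points(self, counts, expected):
        tp, tn, fp, fn = (np.array([v]) for v in counts)
        assert mcc(tp, tn, fp, fn)[0] == pytest.approx(expected)

    def test_mcc_zero_marginal_convention(self):
        assert mcc(np.array([0.0]), np.array([5.0]), np.array([0.0]), np.array([0.0]))[0] == 0.0


class TestReconstructionError:
    def test_spanning_signals_give_zero(self, rng):
        S = rng.normal(size=(3, 8))
        X = rng.normal(size=(6, 3)) @ S  # rows of X lie in rowspace(S)
        r, per = reconstruction_error(X, S)
        assert r < 1e-10
        assert per < 1e-20

    def test_zero_signals(self, rng):
        X = rng.normal(size=(4, 6))
        r, per = reconstruction_error(X, np.zeros((2, 6)))
        assert r == pytest.approx(np.linalg.norm(X))
        assert per == pytest.approx(r**2 / X.size)

    def test_matches_projection_oracle(self, rng):
        X = rng.normal(size=(7, 5))
        S = rng.normal(size=(2, 5))
        proj = X @ np.linalg.pinv(S) @ S
        r, _ = reconstruction_error(X, S)
        assert r == pytest.approx(np.linalg.norm(X - proj))

    def test_linear_per_entry_variant(self, rng):
        X = rng.normal(size=(4, 5))
        S = rng.normal(size=(2, 5))
        r, per = reconstruction_error(X, S, per_entry="linear")
        assert per == pytest.approx(r / 20)


class TestOuterCV:
    def test_true_factorization_is_perfect_anchor(self, multiclass_dataset):
        # classifying with the generator's own (A_true, b_true) must be perfect
        ds = multiclass_dataset
        Yhat = predict_classes(ds.A_true.values, ds.b_true.b)
        tp, tn, fp, fn = confusion_counts(ds.Y.values, Yhat)
        s, t = sensitivity_specificity(tp, tn, fp, fn)
        assert np.allclose(s, 1.0) and np.allclose(t, 1.0)
        assert np.allclose(mcc(tp, tn, fp, fn), 1.0)

    def test_fold_partition_and_determinism(self, toy_dataset):
        ds = toy_dataset
        rep1 = outer_cv(ds.X.values, ds.labels, ds.class_names, folds=5, seed=3)
        rep2 = outer_cv(ds.X.values, ds.labels, ds.class_names, folds=5, seed=3)
        n = ds.X.n_samples
        assert sorted(np.unique(rep1.fold_ids)) == [0, 1, 2, 3, 4]
        assert rep1.fold_ids.size == n
        assert np.array_equal(rep1.fold_ids, rep2.fold_ids)
        assert np.array_equal(rep1.sensitivity, rep2.sensitivity)
        assert rep1.r == rep2.r

    def test_report_schema_and_ranges(self, toy_dataset):
        ds = toy_dataset
        rep = outer_cv(ds.X.values, ds.labels, ds.class_names, folds=5, seed=5)
        k, n = 2, ds.X.n_samples
        for arr in (rep.tp, rep.tn, rep.fp, rep.fn):
            assert arr.shape == (k,)
        # pooled counts cover every sample once per class
        assert np.all(rep.tp + rep.tn + rep.fp + rep.fn == n)
        assert np.all((rep.sensitivity >= 0) & (rep.sensitivity <= 1))
        assert np.all((rep.specificity >= 0) & (rep.specificity <= 1))
        assert np.all((rep.mcc >= -1) & (rep.mcc <= 1))
        assert rep.r >= 0
        assert rep.summary().shape[0] == k


class TestBenchmark:
    def test_row_accounting_and_sd_oracle(self):
        design = list(generate_design([0, 1], [50], [2], [50]))
        cfg = TrainerConfig(bfgs_max_iter=8, max_restarts=1)
        df = run_benchmark(design, methods=["brierscoremf", "linear-svm"], cfg=cfg, master_seed=3)
        assert len(df) == 4
        assert set(df["method"]) == {"brierscoremf", "linear-svm"}
        agg = aggregate_benchmark(df)
        assert len(agg) == 2  # one cell per method
        row = agg[agg["method"] == "brierscoremf"].iloc[0]
        vals = df[df["method"] == "brierscoremf"]["mean_sensitivity"].to_numpy()
        # two-pass SD oracle
        manual_sd = np.sqrt(((vals - vals.mean()) ** 2).sum() / (len(vals) - 1))
        assert row["sensitivity_sd"] == pytest.approx(manual_sd)
        assert row["n_seeds"] == 2

    def test_single_seed_cell_sd_is_undefined(self):
        design = list(generate_design([0], [50], [2], [50]))
        cfg = TrainerConfig(bfgs_max_iter=8, max_restarts=1)
        df = run_benchmark(design, methods=["brierscoremf"], cfg=cfg, master_seed=3)
        agg = aggregate_benchmark(df)
        assert np.isnan(agg["sensitivity_sd"].iloc[0])

    def test_unknown_method_rejected(self):
        design = generate_design([0], [50], [2], [50])
        with pytest.raises(ValueError, match="unknown method"):
            run_benchmark(design, methods=["perceptron"])


class TestHeldOutIsolation:
    def test_training_never_sees_held_out_rows(self, monkeypatch):
        """Each per-fold fit must receive exactly the complement of its test fold."""
        import brierscoremf.evaluate as ev

        ds = sample_dataset(SyntheticConfig(seed=5, n=40, k=2, m=20))
        seen = []
        real_fit = ev.fit

        def spy(X, Y, cfg):
            seen.append(np.asarray(X).copy())
            return real_fit(X, Y, cfg)

        monkeypatch.setattr(ev, "fit", spy)
        rep = ev.outer_cv(ds.X.values, ds.labels, ds.class_names, folds=5, seed=1)
        assert len(seen) == 5
        for f, Xtr in enumerate(seen):
            expected = ds.X.values[rep.fold_ids != f]
            assert np.array_equal(Xtr, expected)
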