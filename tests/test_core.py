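"""Unit tests for the closed-form factorization and its loss functions."""

import numpy as np
import pytest

from brierscoremf import (
    brier_score_loss,
    build_class_matrix,
    closed_form_signals,
    combined_loss,
    estimate_coefficients,
    frobenius_loss,
    predict_classes,
    pseudoinverse,
)


class TestBuildClassMatrix:
    @pytest.mark.parametrize(
        "labels, classes, expected",
        [
            (["c1", "c2", "c1"], ["c1", "c2"], [[1, -1], [-1, 1], [1, -1]]),
            (["c1"], ["c1"], [[1]]),
            (["b", "a"], ["a", "b"], [[-1, 1], [1, -1]]),
        ],
    )
    def test_encoding(self, labels, classes, expected):
        Y = build_class_matrix(labels, classes)
        assert np.array_equal(Y.values, np.array(expected, dtype=float))
        assert np.all((Y.values > 0).sum(axis=1) == 1)

    def test_unknown_label_names_offender(self):
        with pytest.raises(ValueError, match="c3"):
            build_class_matrix(["c3"], ["c1", "c2"])

    def test_empty_registry(self):
        with pytest.raises(ValueError):
            build_class_matrix([], [])


class TestPseudoinverse:
    def test_identity_and_scalar(self):
        assert np.allclose(pseudoinverse(np.eye(3)), np.eye(3))
        assert np.allclose(pseudoinverse([[2.0]]), [[0.5]])

    @pytest.mark.parametrize("shape, rank", [
        ((3, 5), None), ((5, 3), None), ((4, 4), None),
        ((6, 4), 2), ((4, 6), 2), ((5, 5), 3),
    ])
    def test_moore_penrose_identities(self, shape, rank, rng):
        p, q = shape
        if rank is None:
            M = rng.normal(size=shape)
        else:
            M = rng.normal(size=(p, rank)) @ rng.normal(size=(rank, q))
        Mp = pseudoinverse(M)
        assert np.linalg.norm(M @ Mp @ M - M) < 1e-10
        assert np.linalg.norm(Mp @ M @ Mp - Mp) < 1e-10
        assert np.linalg.norm((M @ Mp).T - M @ Mp) < 1e-10
        assert np.linalg.norm((Mp @ M).T - Mp @ M) < 1e-10

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pseudoinverse([[np.nan, 1.0]])

    def test_differential_identity(self, rng):
        # dS+ = -S+ (dS) S+ : the first-order term of the perturbed inverse.
        S = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        D = rng.normal(size=(4, 4))
        Sp = pseudoinverse(S)
        errs = {}
        for h in (1e-4, 1e-5):
            fd = pseudoinverse(S + h * D) - Sp
            errs[h] = np.linalg.norm(fd - (-Sp @ D @ Sp) * h)
        # remainder is O(h^2): shrinking h tenfold shrinks the error ~100x
        ratio = errs[1e-4] / errs[1e-5]
        assert 30 < ratio < 300


class TestFrobeniusLoss:
    def test_exact_reconstruction_is_zero(self, rng):
        A = rng.normal(size=(5, 2))
        S = rng.normal(size=(2, 7))
        assert frobenius_loss(A @ S, A, S) < 1e-12

    def test_identity_norm(self):
        X = np.eye(2)
        A = np.zeros((2, 1))
        S = np.ones((1, 2))
        assert frobenius_loss(X, A, S) == pytest.approx(np.sqrt(2.0))

    def test_matches_elementwise_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        A = rng.normal(size=(6, 3))
        S = rng.normal(size=(3, 4))
        Z = X - A @ S
        assert frobenius_loss(X, A, S) == pytest.approx(np.sqrt((Z**2).sum()))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            frobenius_loss(np.eye(2), np.zeros((3, 1)), np.ones((1, 2)))

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(size=(6, 4))
        A = rng.normal(size=(6, 3))
        S = rng.normal(size=(3, 4))
        perm = rng.permutation(6)
        assert frobenius_loss(X[perm], A[perm], S) == pytest.approx(
            frobenius_loss(X, A, S)
        )


class TestBrierScore:
    @pytest.mark.parametrize(
        "Y, V, expected",
        [
            ([[1.0, -1.0], [-1.0, 1.0]], [[1.0, -1.0], [-1.0, 1.0]], 0.0),
            ([[1.0]], [[0.0]], 1.0),
            ([[1.0, -1.0]], [[-1.0, 1.0]], 4.0),
        ],
    )
    def test_closed_form_cases(self, Y, V, expected):
        assert brier_score_loss(Y, V) == pytest.approx(expected)

    def test_row_permutation_invariance_and_bounds(self, rng):
        Y = np.where(rng.random((8, 3)) < 0.5, -1.0, 1.0)
        V = rng.normal(size=(8, 3))
        base = brier_score_loss(Y, V)
        perm = rng.permutation(8)
        assert brier_score_loss(Y[perm], V[perm]) == pytest.approx(base)
        assert base >= 0.0
        # zero iff Y o V == 1 everywhere
        assert brier_score_loss(Y, 1.0 / Y) == pytest.approx(0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            brier_score_loss(np.ones((2, 2)), np.ones((2, 3)))


class TestCombinedLoss:
    def test_exact_model_gives_zero(self, rng):
        # S with orthonormal rows; X built so that X S+ = Y + 1 b^T exactly.
        k, d, n = 2, 6, 5
        S, _ = np.linalg.qr(rng.normal(size=(d, k)))
        S = S.T  # k x d orthonormal rows
        Y = np.where(rng.random((n, k)) < 0.5, -1.0, 1.0)
        b = rng.uniform(size=k)
        W = Y + b
        X = W @ S
        loss = combined_loss(X, Y, S, b)
        assert loss.frobenius < 1e-12
        assert loss.brier < 1e-24
        assert loss.combined < 1e-24
        assert loss.kappa == pytest.approx(1.0 / (n * k))

    def test_composition_oracle_and_nonnegativity(self, rng):
        X = rng.normal(size=(7, 5))
        Y = np.where(rng.random((7, 3)) < 0.5, -1.0, 1.0)
        S = rng.normal(size=(3, 5))
        b = rng.uniform(size=3)
        loss = combined_loss(X, Y, S, b)
        Sp = np.linalg.pinv(S)
        A = X @ Sp
        frob = frobenius_loss(X, A, S)
        brier = brier_score_loss(Y, A - b)
        assert loss.frobenius == pytest.approx(frob)
        assert loss.brier == pytest.approx(brier)
        assert loss.combined == pytest.approx(frob**2 + brier)
        assert loss.combined >= 0.0


class TestClosedFormSignals:
    def test_hand_computed_example(self):
        # W = [[1], [-1]], W+ = [0.5, -0.5], X = 2*I  =>  S = [[1, -1]]
        S = closed_form_signals([[2.0, 0.0], [0.0, 2.0]], [[1.0], [-1.0]], [0.0])
        assert np.allclose(S.values, [[1.0, -1.0]])

    def test_consistent_system_residual(self, rng):
        n, k, d = 8, 3, 6
        Y = build_class_matrix([f"c{i % k + 1}" for i in range(n)],
                               [f"c{j + 1}" for j in range(k)]).values
        b = rng.uniform(size=k)
        W = Y + b
        S0 = rng.normal(size=(k, d))
        X = W @ S0
        S = closed_form_signals(X, Y, b).values
        assert np.linalg.norm(X - W @ S) < 1e-10

    def test_threshold_shift_matches_pinv_oracle(self, rng):
        n, k, d = 6, 2, 5
        X = rng.normal(size=(n, d))
        Y = np.where(rng.random((n, k)) < 0.5, -1.0, 1.0)
        b = rng.uniform(size=k)
        for c in (0.0, 0.3, -0.7):
            S = closed_form_signals(X, Y, b + c).values
            oracle = np.linalg.pinv(Y + (b + c)) @ X
            assert np.allclose(S, oracle, atol=1e-12)

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            closed_form_signals(np.eye(2), [[1.0], [-1.0]], [np.inf])


class TestEstimateCoefficients:
    def test_examples(self):
        assert np.allclose(estimate_coefficients([[2.0, 0.0]], [[1.0, 0.0]]), [[2.0]])
        assert np.allclose(
            estimate_coefficients(np.zeros((3, 4)), np.ones((2, 4))), np.zeros((3, 2))
        )

    def test_recovers_coefficients_on_full_row_rank(self, rng):
        A0 = rng.normal(size=(9, 3))
        S = rng.normal(size=(3, 7))  # full row rank a.s.
        A = estimate_coefficients(A0 @ S, S)
        assert np.max(np.abs(A - A0)) < 1e-10

    def test_channel_mismatch(self):
        with pytest.raises(ValueError):
            estimate_coefficients(np.ones((2, 3)), np.ones((2, 4)))


class TestPredictClasses:
    @pytest.mark.parametrize("a, b, expected", [(0.7, 0.5, 1.0), (0.3, 0.5, -1.0), (0.5, 0.5, 1.0)])
    def test_threshold_rule_with_tie_convention(self, a, b, expected):
        assert predict_classes([[a]], [b])[0, 0] == expected

    def test_multilabel_rows_allowed(self):
        pred = predict_classes([[0.9, 0.9], [0.1, 0.1]], [0.5, 0.5])
        assert np.array_equal(pred, [[1.0, 1.0], [-1.0, -1.0]])
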