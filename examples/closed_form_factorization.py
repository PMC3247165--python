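"""The closed-form signal matrix and the two loss terms on a tiny example.

Minimizing the joint loss  L = ||X - X S^+ S||_F^2 + B(Y, X S^+ - 1 b^T)
forces X S^+ = Y + 1 b^T = W at the stationary point, so S = W^+ X with
no iterative factorization at all.
"""

import numpy as np

from brierscoremf import (
    brier_score_loss,
    closed_form_signals,
    combined_loss,
    estimate_coefficients,
    pseudoinverse,
)

# two samples, one class: sample 1 is a member (+1), sample 2 is not (-1)
X = np.array([[2.0, 0.0], [0.0, 2.0]])
Y = np.array([[1.0], [-1.0]])
b = np.array([0.0])

S = closed_form_signals(X, Y, b).values
print("W  = Y + 1 b^T =", (Y + b).ravel())
print("S  = W^+ X     =", S)          # [[1, -1]]: the inferred class signal
A = estimate_coefficients(X, S)
print("A  = X S^+     =", A.ravel())  # coefficient of the signal per sample

loss = combined_loss(X, Y, S, b)
print(f"frobenius reconstruction F = {loss.frobenius:.4f}")
print(f"brier classification   B = {loss.brier:.4f}  (kappa = {loss.kappa})")
print(f"combined L = F^2 + B     = {loss.combined:.4f}")

# the pseudoinverse driving all of this satisfies the four defining identities
M = np.array([[1.0, 2.0, 0.0], [0.0, 1.0, 1.0]])
Mp = pseudoinverse(M)
print("||M M+ M - M|| =", np.linalg.norm(M @ Mp @ M - M))
print("Brier score of a perfect margin matrix:",
      brier_score_loss(Y, Y * 1.0))  # y*v = 1 everywhere -> 0
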