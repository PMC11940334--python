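"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths: the diffusion-map oracle
uses the non-symmetric eigensolver on the literal Markov operator, the FDR
oracle implements the step-up rule by explicit loop, and the AUC oracle
integrates the ROC curve trapezoidally.
"""

import numpy as np
import scipy.linalg


def dense_diffusion_oracle(W, alpha=0.5, n_components=5):
    """Literal step-by-step diffusion map on a dense affinity matrix.

    W_a = D^-a W D^-a; P = D_a^-1 W_a; right eigenvectors of P from the
    general (non-symmetric) eigensolver, sorted by descending eigenvalue,
    each scaled so its stationary-measure-weighted norm equals that of the
    all-ones trivial eigenvector; coordinates are psi_i * lambda_i/(1-lambda_i).
    """
    W = np.asarray(W, dtype=float)
    d = W.sum(axis=1)
    Da_inv = np.diag(d ** (-alpha))
    W_a = Da_inv @ W @ Da_inv
    d_a = W_a.sum(axis=1)
    P = np.diag(1.0 / d_a) @ W_a
    evals, evecs = scipy.linalg.eig(P)
    order = np.argsort(-evals.real)
    evals = evals.real[order]
    evecs = evecs.real[:, order]
    # normalize in the d_a-weighted norm; the trivial vector becomes all-ones
    total = d_a.sum()
    psi = np.empty_like(evecs)
    for j in range(evecs.shape[1]):
        v = evecs[:, j]
        w_norm = np.sqrt((d_a * v**2).sum())
        psi[:, j] = v * np.sqrt(total) / w_norm
    lam = evals[1:n_components + 1]
    coords = psi[:, 1:n_components + 1] * (lam / (1.0 - lam))
    return coords, lam


def match_columns_up_to_sign(A, B):
    """Max abs difference between matrices allowing per-column sign flips."""
    diff = 0.0
    for j in range(A.shape[1]):
        d = min(np.abs(A[:, j] - B[:, j]).max(), np.abs(A[:, j] + B[:, j]).max())
        diff = max(diff, d)
    return diff


def bh_stepup_oracle(pvals):
    """Benjamini-Hochberg adjusted values by the explicit step-up loop."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adjusted[i] = running_min
    return adjusted


def auc_trapezoid_oracle(y_true, scores):
    """AUC by explicit trapezoidal integration of the ROC curve."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    thresholds = np.unique(s)[::-1]
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    tpr = [0.0]
    fpr = [0.0]
    for th in thresholds:
        pred = s >= th
        tpr.append(((pred) & (y == 1)).sum() / n_pos)
        fpr.append(((pred) & (y == 0)).sum() / n_neg)
    return float(np.trapezoid(tpr, fpr))


def random_orthogonal(k, rng):
    """Haar-ish random orthogonal matrix via QR with sign fixing."""
    Q, R = np.linalg.qr(rng.standard_normal((k, k)))
    return Q * np.sign(np.diag(R))
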