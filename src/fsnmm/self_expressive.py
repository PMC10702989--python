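"""Diagnosis-restricted sparse self-expressive networks.

Each subject's feature vector is reconstructed as a sparse nonnegative
combination of the other subjects carrying the same diagnosis:

    min_{w >= 0}  1/2 ||x_i - D w||^2 + lambda ||w||_1

where the donor matrix D stacks the same-class subjects (excluding i).
Under the subspace assumption — each diagnosis class lies near a
low-dimensional subspace — the resulting subject-subject weight matrix
is block-supported on the classes and acts as a similarity network.

The nonnegativity constraint is part of the optimization (negative
combinations are excluded by the feasible set, not truncated after the
fact). The per-subject coefficient vectors are stacked and symmetrized,
W = W~ + W~^T, with the diagonal forced to zero.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import DiagnosisLabels, ModalityMatrix, SelfExpressiveNetwork

logger = logging.getLogger(__name__)

try:  # optional JIT of the coordinate-descent kernel
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

__all__ = [
    "nonneg_lasso",
    "sparse_code_one",
    "sparse_code_against",
    "build_sen",
    "lambda_max_sen",
    "reconstruct",
]

_TOL = 1e-8
_MAX_SWEEPS = 10_000


def _cd_sweeps(G, b, diag, lam, tol, max_sweeps):
    n = b.size
    w = np.zeros(n)
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(n):
            if diag[j] == 0.0:
                continue
            gj = b[j] - np.dot(G[j], w) + diag[j] * w[j]
            wj = (gj - lam) / diag[j]
            if wj < 0.0:
                wj = 0.0
            d = abs(wj - w[j])
            if d > delta:
                delta = d
            w[j] = wj
        if delta < tol:
            break
    return w


if njit is not None:
    _cd_sweeps = njit(cache=False)(_cd_sweeps)


def nonneg_lasso(
    D: np.ndarray,
    x: np.ndarray,
    lam: float,
    tol: float = _TOL,
    max_sweeps: int = _MAX_SWEEPS,
) -> np.ndarray:
    """Solve min_{w>=0} 1/2||x - D w||^2 + lam * sum(w).

    Cyclic coordinate descent with nonnegative soft-thresholding on the
    Gram matrix; coordinates are visited in column order, so ties among
    duplicated donors resolve deterministically. Stops when the largest
    coordinate update falls below ``tol`` (or after ``max_sweeps``).
    """
    D = np.asarray(D, dtype=float)
    x = np.asarray(x, dtype=float)
    n = D.shape[1]
    if n == 0:
        return np.zeros(0)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    G = np.ascontiguousarray(D.T @ D)
    b = D.T @ x
    diag = np.ascontiguousarray(np.diag(G))
    return _cd_sweeps(G, b, diag, float(lam), float(tol), max_sweeps)


def sparse_code_against(
    x: np.ndarray, donors: np.ndarray, lam: float
) -> np.ndarray:
    """Nonnegative sparse code of ``x`` against the rows of ``donors``.

    Label-free variant used to reconstruct held-out subjects against
    the training pool (diagnoses of new subjects are unknown).
    """
    return nonneg_lasso(np.asarray(donors, dtype=float).T, x, lam)


def sparse_code_one(
    i: int,
    X: ModalityMatrix | np.ndarray,
    labels: DiagnosisLabels,
    lambda_sparse: float,
) -> np.ndarray:
    """Sparse self-expression coefficients of subject ``i``.

    Returns a length-N vector; entries outside subject i's diagnosis
    class, and entry i itself, are exactly zero. A class of size one
    has no donors and yields the all-zero vector (with a warning).
    """
    vals = X.values if isinstance(X, ModalityMatrix) else np.asarray(X, dtype=float)
    n = vals.shape[0]
    if labels.n_subjects != n:
        raise ValueError("labels do not match the number of subjects")
    peers = labels.class_index_set(i)
    donors = peers[peers != i]
    w = np.zeros(n)
    if donors.size == 0:
        logger.warning(
            "subject %d is the only member of its class; zero coefficients", i
        )
        return w
    w[donors] = nonneg_lasso(vals[donors].T, vals[i], lambda_sparse)
    return w


def lambda_max_sen(X: ModalityMatrix | np.ndarray, labels: DiagnosisLabels) -> float:
    """Smallest lambda for which every subject's sparse code is zero.

    From the KKT conditions of the nonnegative lasso, the zero vector
    is optimal iff lambda >= <x_j, x_i> for every same-class donor j;
    the dataset-level threshold is the max over subjects.
    """
    vals = X.values if isinstance(X, ModalityMatrix) else np.asarray(X, dtype=float)
    lmax = 0.0
    for i in range(vals.shape[0]):
        peers = labels.class_index_set(i)
        donors = peers[peers != i]
        if donors.size:
            lmax = max(lmax, float((vals[donors] @ vals[i]).max()))
    return lmax


def build_sen(
    X: ModalityMatrix | np.ndarray,
    labels: DiagnosisLabels,
    lambda_sparse: float | None = None,
    lambda_frac: float = 0.1,
) -> SelfExpressiveNetwork:
    """Class-restricted sparse self-expressive network for one modality.

    When ``lambda_sparse`` is None it defaults to ``lambda_frac`` times
    the dataset's critical value ``lambda_max_sen`` (the smallest
    penalty that zeroes every code), giving a sparsity level comparable
    across datasets and modalities.
    """
    name = X.modality_name if isinstance(X, ModalityMatrix) else ""
    vals = X.values if isinstance(X, ModalityMatrix) else np.asarray(X, dtype=float)
    n = vals.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if lambda_sparse is None:
        lambda_sparse = lambda_frac * lambda_max_sen(vals, labels)
    coef = np.zeros((n, n))
    for i in range(n):
        coef[i] = sparse_code_one(i, vals, labels, lambda_sparse)
    w = coef + coef.T
    np.fill_diagonal(w, 0.0)
    return SelfExpressiveNetwork(
        weights=w, lambda_sparse=float(lambda_sparse), modality_name=name
    )


def reconstruct(W: np.ndarray, X: ModalityMatrix | np.ndarray):
    """Self-expressive reconstruction x~_i = sum_j W(i, j) x_j, i.e. W X."""
    w = np.asarray(W, dtype=float)
    if isinstance(X, ModalityMatrix):
        if w.shape[1] != X.n_subjects:
            raise ValueError(
                f"shape mismatch: W is {w.shape}, X has {X.n_subjects} subjects"
            )
        return ModalityMatrix(
            modality_name=X.modality_name,
            values=w @ X.values,
            subject_ids=list(X.subject_ids),
            feature_labels=list(X.feature_labels),
        )
    x = np.asarray(X, dtype=float)
    if w.shape[1] != x.shape[0]:
        raise ValueError(f"shape mismatch: W is {w.shape}, X is {x.shape}")
    return w @ x
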