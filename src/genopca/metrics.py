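"""Subspace-accuracy and population-differentiation metrics.

MEV (mean of explained variances) is the accuracy currency of the package:
for two sets of k orthonormal PCs it averages, over the reference vectors
v_i, the squared norm of their projection onto the span of the estimated
vectors u_j,

    MEV = (1/k) sum_i sum_j (v_i . u_j)^2 = ||U^T V||_F^2 / k,

which is 1 exactly when the two k-dimensional subspaces coincide and 0 when
they are orthogonal. It is symmetric in its arguments and invariant to
rotations within either subspace.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DimensionError, ParameterError

__all__ = ["mev", "principal_angles", "hudson_fst"]


def _check_orthonormal(basis: np.ndarray, name: str, tol: float = 1e-8) -> None:
    gram = basis.T @ basis
    if not np.allclose(gram, np.eye(basis.shape[1]), atol=tol):
        raise ParameterError(f"{name} does not have orthonormal columns (tol {tol})")


def mev(
    reference: np.ndarray, estimate: np.ndarray, *, orthonormalize: bool = False
) -> float:
    """Mean of explained variances between two orthonormal m x k bases.

    With orthonormalize=True, each input is replaced by an orthonormal basis
    of its column span (QR) instead of raising on a non-orthonormal input.
    """
    reference = np.asarray(reference, dtype=np.float64)
    estimate = np.asarray(estimate, dtype=np.float64)
    if reference.shape != estimate.shape:
        raise DimensionError(
            f"shape mismatch: reference {reference.shape} vs estimate {estimate.shape}"
        )
    if orthonormalize:
        reference = np.linalg.qr(reference)[0]
        estimate = np.linalg.qr(estimate)[0]
    else:
        _check_orthonormal(reference, "reference")
        _check_orthonormal(estimate, "estimate")
    k = reference.shape[1]
    overlap = estimate.T @ reference
    return float((overlap**2).sum() / k)


def principal_angles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Principal angles (radians) between the column spans of two bases."""
    qa = np.linalg.qr(np.asarray(a, dtype=np.float64))[0]
    qb = np.linalg.qr(np.asarray(b, dtype=np.float64))[0]
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.arccos(np.clip(s, -1.0, 1.0))


def hudson_fst(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> float:
    """Hudson-style Fst estimator between two populations (ratio of averages).

    p1, p2 are per-SNP allele frequencies; n1, n2 the allele counts they were
    estimated from (2 x sample counts for diploids).
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())
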