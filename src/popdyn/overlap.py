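"""Subspace overlap between condition-defined population subspaces.

The alignment index A = tr(D' C D) / sum(sigma) measures the fraction of
the total firing-rate variance of one conditioning (covariance C with
eigenvalues sigma) captured by the top principal subspace D of another
conditioning.  All covariances are computed on the same soft-normalized
stacked matrices that feed PCA, so both conditionings share preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PCSpace, TrajectorySet, project, soft_normalize_stack
from .rates import RateTensor

__all__ = ["AlignmentIndexResult", "alignment_index", "cross_project"]


@dataclass
class AlignmentIndexResult:
    A: float
    n_dims_numerator: int
    captured_variance: float  # tr(D' C D)
    total_variance: float  # sum of target eigenvalues


def alignment_index(
    cov_target: np.ndarray,
    basis_source: np.ndarray,
    eigs_target: np.ndarray,
) -> AlignmentIndexResult:
    """Fraction of target variance captured by a source subspace.

    ``basis_source`` is (units x d) with orthonormal columns (the top-d
    loadings of the source conditioning); ``eigs_target`` are *all*
    eigenvalues of the target conditioning, whose sum forms the denominator.
    """
    C = np.asarray(cov_target, dtype=float)
    D = np.asarray(basis_source, dtype=float)
    if D.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] != D.shape[0]:
        raise ValueError("shape mismatch between covariance and basis")
    if not np.allclose(D.T @ D, np.eye(D.shape[1]), atol=1e-8):
        raise ValueError("basis_source columns must be orthonormal")
    captured = float(np.trace(D.T @ C @ D))
    total = float(np.sum(eigs_target))
    return AlignmentIndexResult(
        A=captured / total if total > 0 else np.nan,
        n_dims_numerator=D.shape[1],
        captured_variance=captured,
        total_variance=total,
    )


def cross_project(
    tensor_a: RateTensor, pcspace_b: PCSpace, n_dims: int = 6
) -> tuple[TrajectorySet, float]:
    """Project conditioning A's rates into conditioning B's PC space.

    Applies B's centering, normalizers and top ``n_dims`` loadings to A's
    stacked rates; returns the trajectories and the fraction of A's
    (soft-normalized) variance they capture.
    """
    if tensor_a.values.shape[1] != pcspace_b.loadings.shape[0]:
        raise ValueError("unit count mismatch between tensor and PC space")
    trajset = project(tensor_a, pcspace_b, n_dims=n_dims)
    mat_a, _, _, _ = soft_normalize_stack(tensor_a)
    total = np.sum(mat_a**2)
    scores = mat_a @ pcspace_b.loadings[:, :n_dims]
    captured = np.sum(scores**2)
    return trajset, float(captured / total) if total > 0 else np.nan
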