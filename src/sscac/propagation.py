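"""Confidence-weighted harmonic-function label propagation.

Minimizes  tr(F^T L F) + tr((F - mu.Y)^T U (F - mu.Y))  over the prediction
matrix F, where L is the graph Laplacian of the affinity W, U is diagonal
with a large weight lambda_inf on labeled rows and 0 elsewhere, Y is the
binary label indicator and mu holds per-item label confidences in (0, 1].
With all confidences equal to 1 this is the classic Gaussian-fields /
harmonic-functions objective (soft-clamped by the finite lambda_inf).

The closed-form minimizer F = (L + U)^{-1} U (mu.Y) is computed by a
symmetric positive-definite factorization, never an explicit inverse.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

logger = logging.getLogger(__name__)


@dataclass
class LaplacianPair:
    Lap: np.ndarray   # (n, n) D - W, PSD
    Deg: np.ndarray   # (n, n) diagonal degree matrix


def build_laplacian(W: np.ndarray) -> LaplacianPair:
    """Combinatorial Laplacian L = D - W; the diagonal of W is treated as 0.

    Raises on asymmetry beyond 1e-10.
    """
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T, atol=1e-10, rtol=0):
        raise ValueError("affinity matrix is not symmetric")
    W0 = W.copy()
    np.fill_diagonal(W0, 0.0)
    deg = W0.sum(axis=1)
    Deg = np.diag(deg)
    return LaplacianPair(Lap=Deg - W0, Deg=Deg)


def _components_without_labels(Lap: np.ndarray, U_diag: np.ndarray):
    """Connected components (of the off-diagonal Laplacian structure) that
    contain no labeled item.  Returns (singletons, larger_components)."""
    n = Lap.shape[0]
    A = Lap.copy()
    np.fill_diagonal(A, 0.0)
    ncomp, memb = connected_components(csr_matrix(A != 0), directed=False)
    singles, larger = [], []
    for k in range(ncomp):
        nodes = np.flatnonzero(memb == k)
        if (U_diag[nodes] > 0).any():
            continue
        (singles if len(nodes) == 1 else larger).append(nodes)
    return singles, larger


def solve_F(Lap: np.ndarray, U_diag: np.ndarray, mu: np.ndarray,
            Y: np.ndarray) -> np.ndarray:
    """Solve (L + diag(U)) F = diag(U) (mu . Y) for the prediction matrix F.

    Isolated unlabeled items (their F rows do not enter the objective) get
    rows of zeros; a connected component of two or more items with no
    labeled member makes the system singular and raises, naming the
    component members.
    """
    Lap = np.asarray(Lap, dtype=float)
    U_diag = np.asarray(U_diag, dtype=float)
    n = Lap.shape[0]
    singles, larger = _components_without_labels(Lap, U_diag)
    if larger:
        raise ValueError(
            "graph component(s) with no labeled item: "
            + "; ".join(str(nodes.tolist()) for nodes in larger))
    rhs = U_diag[:, None] * (mu * Y)
    F = np.zeros((n, Y.shape[1]))
    drop = np.concatenate(singles).astype(int) if singles else np.array([], int)
    keep = np.setdiff1d(np.arange(n), drop)
    if keep.size:
        K = Lap[np.ix_(keep, keep)] + np.diag(U_diag[keep])
        c, low = cho_factor(K)
        F[keep] = cho_solve((c, low), rhs[keep])
    return F


def predict_labels(F: np.ndarray) -> np.ndarray:
    """Per-row argmax class (0-based); ties go to the lowest class index.

    All-zero rows get class 0 with a warning.
    """
    F = np.asarray(F, dtype=float)
    zero_rows = ~F.any(axis=1)
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} all-zero prediction row(s); "
                      f"assigned to the first class", RuntimeWarning,
                      stacklevel=2)
    return F.argmax(axis=1)


def objective_value(F: np.ndarray, Lap: np.ndarray, U_diag: np.ndarray,
                    mu: np.ndarray, Y: np.ndarray) -> float:
    """tr(F^T L F) + tr((F - mu.Y)^T U (F - mu.Y)); also the GSA fitness."""
    R = F - mu * Y
    return float(np.sum(F * (Lap @ F)) + np.sum(U_diag[:, None] * R * R))


def indicator_matrices(assigned: np.ndarray, confidences: np.ndarray,
                       labeled_mask: np.ndarray, n_classes: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Build (Y, mu) from 0-based assigned labels and per-item confidences.

    Unlabeled rows are all-zero in both matrices.
    """
    n = len(assigned)
    Y = np.zeros((n, n_classes))
    mu = np.zeros((n, n_classes))
    idx = np.flatnonzero(labeled_mask)
    Y[idx, assigned[idx]] = 1.0
    mu[idx, assigned[idx]] = confidences[idx]
    return Y, mu
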