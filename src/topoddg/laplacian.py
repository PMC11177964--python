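"""Combinatorial and persistent k-Laplacians and their spectra.

For a snapshot K of a filtration, the k-combinatorial Laplacian is

    L_k = B_{k+1} B_{k+1}^T + B_k^T B_k,        L_0 = B_1 B_1^T,

with B_k the signed boundary matrices. L_k is symmetric positive
semidefinite; by the combinatorial Hodge theorem the multiplicity of its
zero eigenvalue equals the Betti number β_k (components, loops, cavities for
k = 0, 1, 2). The non-zero part of the spectrum carries geometric
information that Betti numbers do not.

The p-persistent variant replaces the up-part with boundaries of those
(k+1)-chains of the later snapshot K(t+p) whose boundary already lies in the
k-chain space of K(t); its harmonic space recovers persistent homology of
the inclusion K(t) ⊆ K(t+p). The constrained chain subspace is computed by
an explicit orthonormal null-space basis, which is numerically robust at the
matrix sizes used here and directly testable against rank-based Betti
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .filtration import Snapshot, boundary_matrix

__all__ = [
    "LaplacianSpectrum",
    "combinatorial_laplacian",
    "persistent_laplacian",
    "spectrum",
    "betti_from_spectrum",
    "betti_by_rank",
    "persistent_betti_by_rank",
    "ZERO_TOL_SCALE",
    "DENSE_SIZE_LIMIT",
]

#: Relative harmonic threshold: zero_tol = ZERO_TOL_SCALE * max(1, λ_max).
ZERO_TOL_SCALE = 1e-8

#: Above this matrix size, only extremal eigenvalues would be reliable with
#: iterative solvers; the featurization keeps matrices below it by design.
DENSE_SIZE_LIMIT = 2000


@dataclass(frozen=True)
class LaplacianSpectrum:
    """Ascending eigenvalues of a (persistent) k-Laplacian at scale t."""

    k: int
    t: float
    p: float
    eigenvalues: np.ndarray
    zero_tol: float

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        object.__setattr__(self, "eigenvalues", ev)
        if ev.size and np.any(np.diff(ev) < -1e-12):
            raise ValueError("eigenvalues must be ascending")
        if ev.size and ev.min() < -self.zero_tol:
            raise ValueError(f"negative eigenvalue {ev.min()} below -zero_tol")

    @property
    def harmonic(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < self.zero_tol]

    @property
    def non_harmonic(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues >= self.zero_tol]


def combinatorial_laplacian(snap: Snapshot, k: int) -> np.ndarray:
    """L_k of a snapshot as a dense symmetric PSD matrix.

    With no k-simplices present the result is an empty (0, 0) matrix.
    """
    n = snap.n_simplices(k)
    if n == 0:
        return np.zeros((0, 0))
    b_up = boundary_matrix(snap, k + 1).entries.astype(float)
    lap = b_up @ b_up.T
    if k > 0:
        b_down = boundary_matrix(snap, k).entries.astype(float)
        lap = lap + b_down.T @ b_down
    return lap


def _restricted_up_boundary(
    snap_t: Snapshot, snap_tp: Snapshot, k: int
) -> np.ndarray:
    """Matrix of ∂_{k+1} restricted to (k+1)-chains of K(t+p) with boundary
    in C_k(K_t), expressed in an orthonormal basis of that subspace; rows are
    the k-simplices of K_t."""
    b_full = boundary_matrix(snap_tp, k + 1)
    inside_index = snap_t.index.get(k, {})
    inside_rows = [i for i, s in enumerate(b_full.rows) if s in inside_index]
    outside_rows = [i for i, s in enumerate(b_full.rows) if s not in inside_index]
    entries = b_full.entries.astype(float)
    n_cols = entries.shape[1]
    if n_cols == 0:
        return np.zeros((snap_t.n_simplices(k), 0))
    if outside_rows:
        z = scipy.linalg.null_space(entries[outside_rows, :])
    else:
        z = np.eye(n_cols)
    # reorder the inside rows to K_t's own simplex ordering
    order = sorted(inside_rows, key=lambda i: inside_index[b_full.rows[i]])
    return entries[order, :] @ z


def persistent_laplacian(snap_t: Snapshot, snap_tp: Snapshot, k: int) -> np.ndarray:
    """p-persistent k-Laplacian for the inclusion ``snap_t`` ⊆ ``snap_tp``.

    Reduces exactly (entrywise) to :func:`combinatorial_laplacian` of
    ``snap_t`` when the two snapshots coincide.
    """
    if not snap_tp.contains(snap_t):
        raise ValueError("snapshots are not nested (K_t must be inside K_{t+p})")
    n = snap_t.n_simplices(k)
    if n == 0:
        return np.zeros((0, 0))
    same = all(
        snap_t.n_simplices(d) == snap_tp.n_simplices(d) for d in (k, k + 1)
    )
    if same:
        return combinatorial_laplacian(snap_t, k)
    b_tilde = _restricted_up_boundary(snap_t, snap_tp, k)
    lap = b_tilde @ b_tilde.T
    if k > 0:
        b_down = boundary_matrix(snap_t, k).entries.astype(float)
        lap = lap + b_down.T @ b_down
    return lap


def spectrum(
    matrix: np.ndarray,
    k: int,
    t: float,
    p: float = 0.0,
    zero_tol: float | None = None,
) -> LaplacianSpectrum:
    """Ascending eigenvalues of a symmetric Laplacian matrix.

    Small negative round-off (within −zero_tol) is clamped to zero. The
    default tolerance is scale-relative so the harmonic classification is
    unit-independent.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size and not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("Laplacian must be symmetric")
    if matrix.shape[0] > DENSE_SIZE_LIMIT:
        raise ValueError(
            f"matrix of size {matrix.shape[0]} exceeds the dense-solver limit "
            f"({DENSE_SIZE_LIMIT}); reduce the subset or coarsen the grid"
        )
    ev = scipy.linalg.eigvalsh(matrix) if matrix.size else np.zeros(0)
    if zero_tol is None:
        lam_max = float(ev[-1]) if ev.size else 0.0
        zero_tol = ZERO_TOL_SCALE * max(1.0, lam_max)
    if ev.size and ev.min() < -zero_tol:
        raise ValueError(f"matrix is not PSD: min eigenvalue {ev.min()}")
    ev = np.clip(ev, 0.0, None)
    return LaplacianSpectrum(k=k, t=t, p=p, eigenvalues=ev, zero_tol=zero_tol)


def betti_from_spectrum(spec: LaplacianSpectrum) -> int:
    """Betti number as the harmonic (zero-eigenvalue) multiplicity."""
    return int(spec.harmonic.size)


def betti_by_rank(snap: Snapshot, k: int) -> int:
    """Independent Betti oracle: β_k = n_k − rank B_k − rank B_{k+1}."""
    n = snap.n_simplices(k)
    if n == 0:
        return 0
    rank_down = np.linalg.matrix_rank(boundary_matrix(snap, k).entries) if k > 0 else 0
    b_up = boundary_matrix(snap, k + 1).entries
    rank_up = np.linalg.matrix_rank(b_up) if b_up.size else 0
    return n - rank_down - rank_up


def persistent_betti_by_rank(snap_t: Snapshot, snap_tp: Snapshot, k: int) -> int:
    """Rank oracle for persistent homology of the inclusion.

    β_k^{t,p} = dim Z_k(K_t) − rank(∂_{k+1} restricted to chains of K(t+p)
    whose boundary lies in C_k(K_t)).
    """
    n = snap_t.n_simplices(k)
    if n == 0:
        return 0
    rank_down = np.linalg.matrix_rank(boundary_matrix(snap_t, k).entries) if k > 0 else 0
    b_tilde = _restricted_up_boundary(snap_t, snap_tp, k)
    rank_up = np.linalg.matrix_rank(b_tilde) if b_tilde.size else 0
    return n - rank_down - rank_up
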