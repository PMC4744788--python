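"""Sparse difference penalties on tensor-product spline coefficients.

The roughness penalty is λ‖Dα‖² where D stacks, for each of the three
covariate dimensions, the order-d difference operator applied along that
dimension of the coefficient array (Kronecker-expanded with identities on
the other dimensions).  A single global λ multiplies the whole stack.

D is rank deficient: order-1 differences leave constants unpenalized
(null dimension 1); order-2 differences leave the tensor products of
per-dimension {constant, linear-in-index} vectors unpenalized (null
dimension 2^3 = 8 in three dimensions).  The orthonormal null-space basis
is required downstream, where the improper prior implied by the penalty is
split into a flat part (null space) and a proper Gaussian part.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import sparse

from .basis import BasisSpec

__all__ = ["PenaltyMatrix", "build_difference_penalty", "null_space"]


def _diff_operator(m: int, order: int) -> sparse.csr_matrix:
    """(m - order, m) sparse matrix of order-th successive differences."""
    return sparse.csr_matrix(np.diff(np.eye(m), n=order, axis=0))


@dataclass
class PenaltyMatrix:
    """Stacked difference operator D with its cross-product and null space."""

    D: sparse.csr_matrix
    DtD: sparse.csr_matrix
    order: int
    sizes: tuple[int, int, int]
    null_basis: np.ndarray  # (m, q) orthonormal
    _split_cache: tuple | None = None

    @property
    def m(self) -> int:
        return self.D.shape[1]

    def whitened_split(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(Z, X, Linv): orthonormal null/complement split plus the whitener.

        Linv satisfies ``Linv' (X' D'D X) Linv = I``; it depends only on the
        penalty, so it is computed once and cached (fit contexts on data
        subsets — e.g. cross-validation folds — reuse it).
        """
        if self._split_cache is None:
            q = self.null_dim
            qz, _ = np.linalg.qr(self.null_basis, mode="complete")
            Z, X = qz[:, :q], qz[:, q:]
            S = X.T @ (self.DtD @ X)
            S = 0.5 * (S + S.T)
            w_s, V_s = np.linalg.eigh(S)
            if w_s.size and w_s.min() <= 1e-12 * max(w_s.max(), 1.0):
                raise np.linalg.LinAlgError(
                    "penalty not positive definite off its null space"
                )
            self._split_cache = (Z, X, V_s / np.sqrt(w_s))
        return self._split_cache

    @property
    def null_dim(self) -> int:
        return self.null_basis.shape[1]

    @property
    def rank(self) -> int:
        """rank(D'D) = m - dim null(D)."""
        return self.m - self.null_dim


def _null_basis(sizes: tuple[int, int, int], order: int) -> np.ndarray:
    """Orthonormal basis of null(D) for the stacked tensor difference penalty.

    null(D) is the tensor product of the per-dimension difference null
    spaces, i.e. products of per-dimension polynomials in the coefficient
    index of degree < order.
    """
    per_dim = []
    for m in sizes:
        idx = np.arange(m, dtype=float)
        per_dim.append([idx**p for p in range(order)])
    cols = []
    for p1, p2, p3 in product(*per_dim):
        cols.append(np.kron(np.kron(p1, p2), p3))
    v = np.column_stack(cols)
    q, _ = np.linalg.qr(v)
    return q


def build_difference_penalty(spec: BasisSpec, order: int = 1) -> PenaltyMatrix:
    """Assemble the stacked difference penalty for a tensor basis spec."""
    if order not in (1, 2):
        raise ValueError("penalty order must be 1 or 2")
    n1, n2, n3 = spec.sizes
    for m in spec.sizes:
        if order >= m:
            raise ValueError(f"order {order} >= marginal size {m}")
    d1 = _diff_operator(n1, order)
    d2 = _diff_operator(n2, order)
    d3 = _diff_operator(n3, order)
    i1 = sparse.eye(n1, format="csr")
    i2 = sparse.eye(n2, format="csr")
    i3 = sparse.eye(n3, format="csr")
    blocks = [
        sparse.kron(d1, sparse.kron(i2, i3), format="csr"),
        sparse.kron(i1, sparse.kron(d2, i3), format="csr"),
        sparse.kron(sparse.kron(i1, i2), d3, format="csr"),
    ]
    D = sparse.vstack(blocks, format="csr")
    DtD = (D.T @ D).tocsr()
    nb = _null_basis(spec.sizes, order)
    # the closed-form null space must be genuine: verify at build time
    resid = np.abs(D @ nb).max()
    if resid > 1e-8:
        raise AssertionError(f"null-space residual {resid:.2e} too large")
    return PenaltyMatrix(D=D, DtD=DtD, order=order, sizes=spec.sizes, null_basis=nb)


def null_space(pm: PenaltyMatrix) -> np.ndarray:
    """Orthonormal columns spanning null(D)."""
    return pm.null_basis
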