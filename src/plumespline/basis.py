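"""Marginal B-spline bases and the sparse spatiotemporal tensor design matrix.

The regression function is m(s1, s2, t) = Σ_jkl α_jkl φ_j(s1) φ_k(s2) φ_l(t)
with B-spline marginal bases on equally spaced knots.  Row i of the design
matrix is the Kronecker product of the three marginal basis rows evaluated at
observation i ("row-wise" Kronecker product), so the design stays sparse:
at most (degree+1)^3 non-zeros per row.

Column convention: coefficient (j, k, l) maps to column
``j * (n2 * n3) + k * n3 + l`` where (n1, n2, n3) are the marginal sizes.
Coordinates are affinely rescaled to [0, 1] per dimension before evaluation;
B-spline values are invariant under this map, it only aids conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.interpolate import BSpline

from .data import MonitoringDataset

__all__ = [
    "BasisSpec",
    "MarginalBasis",
    "TensorDesign",
    "build_marginal_basis",
    "build_tensor_design",
    "rowwise_kron",
]


class DomainError(ValueError):
    """A coordinate falls outside the basis domain and extrapolation is off."""


@dataclass(frozen=True)
class BasisSpec:
    """Sizes, degree and domains of the three marginal bases.

    ``n_basis_*`` counts basis functions per dimension; ``degree`` is the
    polynomial degree of the B-splines (2 by default, i.e. quadratic
    "second-order" pieces).  Domains are closed intervals in data units.
    """

    n_basis_s1: int
    n_basis_s2: int
    n_basis_t: int
    degree: int = 2
    domain_s1: tuple[float, float] = (0.0, 1.0)
    domain_s2: tuple[float, float] = (0.0, 1.0)
    domain_t: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        for n in self.sizes:
            if n < self.degree + 1:
                raise ValueError(
                    f"need n_basis >= degree + 1 = {self.degree + 1}, got {n}"
                )
        for lo, hi in self.domains:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid domain ({lo}, {hi})")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (self.n_basis_s1, self.n_basis_s2, self.n_basis_t)

    @property
    def domains(self) -> tuple[tuple[float, float], ...]:
        return (self.domain_s1, self.domain_s2, self.domain_t)

    @property
    def m(self) -> int:
        """Total number of tensor-product coefficients."""
        return self.n_basis_s1 * self.n_basis_s2 * self.n_basis_t

    @classmethod
    def from_data(
        cls,
        data: MonitoringDataset,
        n_basis: tuple[int, int, int],
        degree: int = 2,
    ) -> "BasisSpec":
        """Spec with domains equal to the data range in each dimension."""
        return cls(
            n_basis_s1=n_basis[0],
            n_basis_s2=n_basis[1],
            n_basis_t=n_basis[2],
            degree=degree,
            domain_s1=(float(data.s1.min()), float(data.s1.max())),
            domain_s2=(float(data.s2.min()), float(data.s2.max())),
            domain_t=(float(data.t.min()), float(data.t.max())),
        )


@dataclass(frozen=True)
class MarginalBasis:
    """One-dimensional B-spline basis on equally spaced knots.

    The knot vector extends ``degree`` uniform steps beyond each end of the
    domain so that exactly ``n_basis`` functions are supported on it and the
    basis sums to one everywhere inside the domain.
    """

    n_basis: int
    degree: int
    domain: tuple[float, float]
    knots: np.ndarray  # on the normalized [0, 1] scale

    def normalize(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.domain
        return (np.asarray(x, dtype=float) - lo) / (hi - lo)

    def evaluate(self, x, extrapolate: bool = False) -> sparse.csr_matrix:
        """(n_points, n_basis) sparse matrix of basis values at ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite coordinates")
        u = self.normalize(x)
        tol = 1e-10
        out = (u < -tol) | (u > 1 + tol)
        if out.any() and not extrapolate:
            bad = x[out]
            raise DomainError(
                f"{out.sum()} point(s) outside domain {self.domain} "
                f"(e.g. {bad[0]!r}); pass extrapolate=True to allow"
            )
        u = np.clip(u, 0.0, 1.0) if not extrapolate else u
        mat = BSpline.design_matrix(u, self.knots, self.degree, extrapolate=extrapolate)
        return sparse.csr_matrix(mat)


def build_marginal_basis(
    n_basis: int, degree: int, domain: tuple[float, float]
) -> MarginalBasis:
    """Construct a marginal basis of ``n_basis`` B-splines of given degree.

    Knots are equally spaced: the domain is divided into ``n_basis - degree``
    intervals and extended by ``degree`` steps of the same width on each side
    (uniform extension), yielding ``n_basis + degree + 1`` knots.
    """
    if n_basis < degree + 1:
        raise ValueError(f"need n_basis >= degree + 1, got {n_basis}")
    n_int = n_basis - degree
    h = 1.0 / n_int
    knots = np.arange(-degree, n_basis + 1, dtype=float) * h
    return MarginalBasis(n_basis=n_basis, degree=degree, domain=tuple(domain), knots=knots)


def rowwise_kron(a: sparse.spmatrix, b: sparse.spmatrix) -> sparse.csr_matrix:
    """Row-wise (face-splitting) Kronecker product of two sparse matrices.

    Row i of the result is ``kron(a[i], b[i])``; the column index of the
    pair (j, k) is ``j * b.shape[1] + k``.
    """
    a = sparse.csr_matrix(a)
    b = sparse.csr_matrix(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("row counts differ")
    n = a.shape[0]
    shape = (n, a.shape[1] * b.shape[1])
    if n == 0:
        return sparse.csr_matrix(shape)
    na = np.diff(a.indptr)
    nb = np.diff(b.indptr)
    # vectorized per-row outer products: A entries repeat over their row's
    # B entries; B row slices tile once per A entry of the same row
    per_a = np.repeat(nb, na)  # B-count for each A entry
    a_data = np.repeat(a.data, per_a)
    a_idx = np.repeat(a.indices, per_a)
    total = int(per_a.sum())
    block_ends = np.cumsum(per_a)
    offs = np.arange(total) - np.repeat(block_ends - per_a, per_a)
    bpos = np.repeat(np.repeat(b.indptr[:-1], na), per_a) + offs
    data = a_data * b.data[bpos]
    idx = a_idx * b.shape[1] + b.indices[bpos]
    indptr = np.concatenate([[0], np.cumsum(na * nb)])
    return sparse.csr_matrix((data, idx, indptr), shape=shape)


@dataclass
class TensorDesign:
    """Sparse spatiotemporal design matrix with its marginal bases."""

    B: sparse.csr_matrix
    spec: BasisSpec
    marginals: tuple[MarginalBasis, MarginalBasis, MarginalBasis]

    @property
    def n(self) -> int:
        return self.B.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]

    def column_index(self, j: int, k: int, l: int) -> int:
        n1, n2, n3 = self.spec.sizes
        return j * n2 * n3 + k * n3 + l

    def rows_at(self, s1, s2, t, extrapolate: bool = False) -> sparse.csr_matrix:
        """Design rows for arbitrary target points (for prediction)."""
        b1 = self.marginals[0].evaluate(s1, extrapolate=extrapolate)
        b2 = self.marginals[1].evaluate(s2, extrapolate=extrapolate)
        b3 = self.marginals[2].evaluate(t, extrapolate=extrapolate)
        return rowwise_kron(rowwise_kron(b1, b2), b3)


def build_tensor_design(
    data: MonitoringDataset, spec: BasisSpec, extrapolate: bool = False
) -> TensorDesign:
    """Assemble the sparse design matrix for a monitoring dataset."""
    if data.n == 0:
        raise ValueError("empty dataset")
    marginals = (
        build_marginal_basis(spec.n_basis_s1, spec.degree, spec.domain_s1),
        build_marginal_basis(spec.n_basis_s2, spec.degree, spec.domain_s2),
        build_marginal_basis(spec.n_basis_t, spec.degree, spec.domain_t),
    )
    b1 = marginals[0].evaluate(data.s1, extrapolate=extrapolate)
    b2 = marginals[1].evaluate(data.s2, extrapolate=extrapolate)
    b3 = marginals[2].evaluate(data.t, extrapolate=extrapolate)
    B = rowwise_kron(rowwise_kron(b1, b2), b3)
    return TensorDesign(B=B, spec=spec, marginals=marginals)
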