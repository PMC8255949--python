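"""Linear operator calculus: direct/adjoint contracts and algebra.

Every operator maps elements of ``domain`` to elements of ``range`` via
``direct`` and back via ``adjoint``; the central contract is the adjoint
identity  |<Av, z> - <v, A*z>| <= tol * ||Av|| * ||z||.

Operators combine through addition, scalar multiplication and composition;
``norm()`` estimates the largest singular value by power iteration on A*A.
"""

from __future__ import annotations

import numbers

import numpy as np

from ..datamodel import VectorGeometry, VectorData

__all__ = [
    "LinearOperator",
    "IdentityOperator",
    "ZeroOperator",
    "DiagonalOperator",
    "MaskOperator",
    "MatrixOperator",
    "ScaledOperator",
    "SumOperator",
    "CompositionOperator",
    "power_iteration",
]


class LinearOperator:
    def __init__(self, domain, range_):
        self.domain = domain
        self.range = range_
        self._norm = None

    # -- contracts -----------------------------------------------------
    def direct(self, x):
        raise NotImplementedError

    def adjoint(self, y):
        raise NotImplementedError

    def norm(self, iterations: int = 20, seed: int = 7):
        """Cached power-iteration estimate of the operator 2-norm."""
        if self._norm is None:
            self._norm = power_iteration(self, iterations=iterations, seed=seed)
        return self._norm

    # -- algebra -------------------------------------------------------
    def __mul__(self, other):
        if isinstance(other, numbers.Number):
            return ScaledOperator(other, self)
        return NotImplemented

    __rmul__ = __mul__

    def __add__(self, other):
        if isinstance(other, LinearOperator):
            return SumOperator(self, other)
        return NotImplemented

    def __neg__(self):
        return ScaledOperator(-1.0, self)

    def __sub__(self, other):
        if isinstance(other, LinearOperator):
            return SumOperator(self, ScaledOperator(-1.0, other))
        return NotImplemented

    def __matmul__(self, other):
        if isinstance(other, LinearOperator):
            return CompositionOperator(self, other)
        return NotImplemented


def power_iteration(A: LinearOperator, iterations: int = 20, seed: int = 7,
                    tol: float = 1e-10):
    """Estimate ||A|| via power iteration on A*A; deterministic given seed."""
    x = A.domain.allocate("random", seed=seed, dtype=np.float64)
    nx = x.norm()
    if nx == 0:
        return 0.0
    x = x * (1.0 / nx)
    estimate = 0.0
    for _ in range(int(iterations)):
        y = A.adjoint(A.direct(x))
        ny = y.norm()
        if ny == 0:
            return 0.0
        new_estimate = np.sqrt(ny)
        x = y * (1.0 / ny)
        if estimate > 0 and abs(new_estimate - estimate) <= tol * estimate:
            estimate = new_estimate
            break
        estimate = new_estimate
    return float(estimate)


class IdentityOperator(LinearOperator):
    def __init__(self, domain, range_=None):
        super().__init__(domain, range_ if range_ is not None else domain)

    def direct(self, x):
        return x.copy()

    def adjoint(self, y):
        return y.copy()

    def norm(self, iterations: int = 20, seed: int = 7):
        return 1.0


class ZeroOperator(LinearOperator):
    def __init__(self, domain, range_=None):
        super().__init__(domain, range_ if range_ is not None else domain)

    def direct(self, x):
        return self.range.allocate(0.0, dtype=np.float64)

    def adjoint(self, y):
        return self.domain.allocate(0.0, dtype=np.float64)

    def norm(self, iterations: int = 20, seed: int = 7):
        return 0.0


class DiagonalOperator(LinearOperator):
    """Elementwise multiplication by a data container (self-adjoint)."""

    def __init__(self, diagonal):
        super().__init__(diagonal.geometry, diagonal.geometry)
        self.diagonal = diagonal

    def direct(self, x):
        return x * self.diagonal

    def adjoint(self, y):
        return y * self.diagonal

    def norm(self, iterations: int = 20, seed: int = 7):
        return float(np.max(np.abs(self.diagonal.as_array())))


class MaskOperator(DiagonalOperator):
    """Keep entries where the boolean mask is True, zero the rest."""

    def __init__(self, mask):
        weights = mask.clone_with(mask.as_array().astype(np.float64))
        super().__init__(weights)
        self.mask = mask


class MatrixOperator(LinearOperator):
    """Dense matrix acting between vector geometries; adjoint = transpose."""

    def __init__(self, matrix):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2D")
        m, n = matrix.shape
        super().__init__(VectorGeometry(n), VectorGeometry(m))
        self.matrix = matrix

    def direct(self, x):
        return VectorData(self.matrix @ x.as_array().astype(np.float64),
                          geometry=self.range)

    def adjoint(self, y):
        return VectorData(self.matrix.T @ y.as_array().astype(np.float64),
                          geometry=self.domain)


class ScaledOperator(LinearOperator):
    """c*A; adjoint is c*A* (real scalars only)."""

    def __init__(self, scalar, operator):
        if not isinstance(scalar, numbers.Real):
            raise TypeError("scalar must be real")
        super().__init__(operator.domain, operator.range)
        self.scalar = float(scalar)
        self.operator = operator

    def direct(self, x):
        return self.operator.direct(x) * self.scalar

    def adjoint(self, y):
        return self.operator.adjoint(y) * self.scalar

    def norm(self, iterations: int = 20, seed: int = 7):
        return abs(self.scalar) * self.operator.norm(iterations, seed)


class SumOperator(LinearOperator):
    """(A+B)x = Ax + Bx; adjoint is A* + B*."""

    def __init__(self, A, B):
        _require_same_geometry(A.domain, B.domain, "sum: domains differ")
        _require_same_geometry(A.range, B.range, "sum: ranges differ")
        super().__init__(A.domain, A.range)
        self.A = A
        self.B = B

    def direct(self, x):
        return self.A.direct(x) + self.B.direct(x)

    def adjoint(self, y):
        return self.A.adjoint(y) + self.B.adjoint(y)


class CompositionOperator(LinearOperator):
    """(A o B)x = A(Bx); adjoint is B* o A*."""

    def __init__(self, A, B):
        _require_same_geometry(A.domain, B.range, "composition: range(B) != domain(A)")
        super().__init__(B.domain, A.range)
        self.A = A
        self.B = B

    def direct(self, x):
        return self.A.direct(self.B.direct(x))

    def adjoint(self, y):
        return self.B.adjoint(self.A.adjoint(y))


def _require_same_geometry(a, b, message):
    try:
        ok = (a == b)
    except Exception:
        ok = False
    if ok is False:
        raise ValueError(message)
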