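"""Finite-difference and gradient operators (Neumann boundary).

Forward difference along one axis: (Du)_i = u_{i+1} - u_i for i < n-1 and
(Du)_{n-1} = 0.  The adjoint is the exact transpose:
(D*v)_0 = -v_0, (D*v)_j = v_{j-1} - v_j, (D*v)_{n-1} = v_{n-2}.
"""

from __future__ import annotations

import numpy as np

from ..datamodel import BlockGeometry, BlockDataContainer
from .base import LinearOperator

__all__ = ["FiniteDifferenceOperator", "GradientOperator"]


def _axis_index(geometry, axis):
    labels = geometry.dimension_labels
    if isinstance(axis, str):
        if axis not in labels:
            raise ValueError(f"unknown axis {axis!r}; have {labels}")
        return labels.index(axis)
    axis = int(axis)
    if not (0 <= axis < len(labels)):
        raise ValueError(f"axis index {axis} out of range")
    return axis


def forward_difference(values: np.ndarray, axis: int) -> np.ndarray:
    out = np.zeros_like(values)
    src = np.diff(values, axis=axis)
    sl = [slice(None)] * values.ndim
    sl[axis] = slice(0, values.shape[axis] - 1)
    out[tuple(sl)] = src
    return out


def forward_difference_adjoint(values: np.ndarray, axis: int) -> np.ndarray:
    n = values.shape[axis]
    out = np.zeros_like(values)

    def sl(s):
        ix = [slice(None)] * values.ndim
        ix[axis] = s
        return tuple(ix)

    # interior: (D*v)_j = v_{j-1} - v_j
    out[sl(slice(1, n))] = values[sl(slice(0, n - 1))]
    out[sl(slice(0, n - 1))] -= values[sl(slice(0, n - 1))]
    return out


class FiniteDifferenceOperator(LinearOperator):
    def __init__(self, geometry, axis):
        super().__init__(geometry, geometry)
        self.axis = _axis_index(geometry, axis)
        if geometry.shape[self.axis] < 2:
            raise ValueError("finite differences require axis extent >= 2")

    def direct(self, x):
        return x.clone_with(forward_difference(x.as_array(), self.axis))

    def adjoint(self, y):
        return y.clone_with(forward_difference_adjoint(y.as_array(), self.axis))

    def norm(self, iterations: int = 20, seed: int = 7):
        # ||D|| <= 2; power iteration refines but the bound suffices rarely;
        # keep the estimate for step-size safety.
        return super().norm(iterations, seed)


class GradientOperator(LinearOperator):
    """Stack of per-axis forward differences; adjoint is minus divergence.

    The range is a BlockGeometry with one copy of the domain per spatial
    axis, in canonical axis order.
    """

    def __init__(self, geometry):
        n_axes = len(geometry.shape)
        if n_axes < 1:
            raise ValueError("image must have at least one axis")
        super().__init__(geometry, BlockGeometry(*[geometry.copy() for _ in range(n_axes)]))
        self.n_axes = n_axes

    def direct(self, x):
        arr = x.as_array()
        return BlockDataContainer(
            *[x.clone_with(forward_difference(arr, ax)) for ax in range(self.n_axes)]
        )

    def adjoint(self, y):
        out = None
        for ax, block in enumerate(y):
            term = forward_difference_adjoint(block.as_array(), ax)
            out = term if out is None else out + term
        return y[0].clone_with(out)

    def norm_bound(self):
        """Analytic bound sqrt(4*d) on the operator norm."""
        return float(np.sqrt(4.0 * self.n_axes))
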