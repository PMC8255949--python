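"""Convolutional blurring operator with reflect boundary.

Implemented as (valid convolution) o (reflect padding) so that the adjoint
can be written as the exact transpose: full correlation followed by folding
the padded borders back onto their source pixels.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve

from .base import LinearOperator

__all__ = ["BlurringOperator"]


class BlurringOperator(LinearOperator):
    def __init__(self, kernel, geometry):
        kernel = np.asarray(kernel, dtype=np.float64)
        if kernel.ndim != len(geometry.shape):
            raise ValueError("kernel dimensionality must match the data")
        if any(k % 2 == 0 for k in kernel.shape):
            raise ValueError("kernel sizes must be odd")
        if any(k > n for k, n in zip(kernel.shape, geometry.shape)):
            raise ValueError("kernel larger than data")
        super().__init__(geometry, geometry)
        self.kernel = kernel
        self._pads = tuple((k - 1) // 2 for k in kernel.shape)
        self._reflect_idx = tuple(
            np.pad(np.arange(n), p, mode="reflect")
            for n, p in zip(geometry.shape, self._pads)
        )

    def _pad(self, arr):
        return arr[np.ix_(*self._reflect_idx)]

    def _fold(self, arr):
        # transpose of reflect padding: scatter-add padded entries back
        for axis, idx in enumerate(self._reflect_idx):
            moved = np.moveaxis(arr, axis, 0)
            n = self.domain.shape[axis]
            out = np.zeros((n,) + moved.shape[1:], dtype=moved.dtype)
            np.add.at(out, idx, moved)
            arr = np.moveaxis(out, 0, axis)
        return arr

    def direct(self, x):
        padded = self._pad(x.as_array().astype(np.float64, copy=False))
        return x.clone_with(convolve(padded, self.kernel, mode="valid", method="direct"))

    def adjoint(self, y):
        flipped = self.kernel[tuple(slice(None, None, -1) for _ in self.kernel.shape)]
        full = convolve(y.as_array().astype(np.float64, copy=False), flipped,
                        mode="full", method="direct")
        return y.clone_with(self._fold(full))
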