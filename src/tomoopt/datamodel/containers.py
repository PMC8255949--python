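"""Labelled dense data containers and block containers.

:class:`DataContainer` wraps a dense real array with ordered string axis
labels and (optionally) an attached geometry.  Arithmetic is elementwise and
never touches the geometry; reductions (``dot``, ``norm``, ``sum``, ``mean``)
accumulate in float64 regardless of storage dtype so that oracle comparisons
are stable.

:class:`BlockDataContainer` holds an ordered list of containers (possibly
nested) and extends the same algebra blockwise; its inner product is the sum
of block inner products.
"""

from __future__ import annotations

import math
import numbers

import numpy as np

__all__ = [
    "DataContainer",
    "ImageData",
    "AcquisitionData",
    "VectorData",
    "BlockDataContainer",
]


class DataContainer:
    """Dense multidimensional array with named axes and optional geometry."""

    def __init__(self, array, labels=None, geometry=None):
        array = np.asarray(array)
        if geometry is not None:
            implied = geometry.shape
            if tuple(array.shape) != tuple(implied):
                raise ValueError(
                    f"array shape {array.shape} does not match geometry shape {implied}"
                )
            labels = geometry.dimension_labels
        if labels is None:
            labels = tuple(f"dim{i}" for i in range(array.ndim))
        labels = tuple(labels)
        if len(labels) != array.ndim:
            raise ValueError("one label per array axis is required")
        if len(set(labels)) != len(labels):
            raise ValueError("axis labels must be unique")
        self.array = array
        self.labels = labels
        self.geometry = geometry

    # -- basics --------------------------------------------------------
    @property
    def shape(self):
        return self.array.shape

    @property
    def ndim(self):
        return self.array.ndim

    @property
    def size(self):
        return self.array.size

    @property
    def dtype(self):
        return self.array.dtype

    def as_array(self):
        return self.array

    def copy(self):
        return type(self)(self.array.copy(), labels=self.labels, geometry=self.geometry)

    def clone_with(self, array):
        """New container of the same labels/geometry holding ``array``."""
        if self.geometry is not None:
            return type(self)(array, geometry=self.geometry)
        return type(self)(array, labels=self.labels)

    def fill(self, value):
        if isinstance(value, DataContainer):
            value = value.array
        self.array[...] = value
        return self

    def __repr__(self):
        return f"{type(self).__name__}(labels={self.labels}, shape={self.shape})"

    # -- algebra -------------------------------------------------------
    def _coerce(self, other):
        if isinstance(other, DataContainer):
            if other.labels != self.labels or other.shape != self.shape:
                raise ValueError(
                    f"label/shape mismatch: {self.labels}{self.shape} vs "
                    f"{other.labels}{other.shape}"
                )
            return other.array
        if isinstance(other, numbers.Number):
            return other
        return NotImplemented

    def _binary(self, other, op):
        arr = self._coerce(other)
        if arr is NotImplemented:
            return NotImplemented
        return self.clone_with(op(self.array, arr))

    def __add__(self, other):
        return self._binary(other, np.add)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract)

    def __rsub__(self, other):
        arr = self._coerce(other)
        if arr is NotImplemented:
            return NotImplemented
        return self.clone_with(np.subtract(arr, self.array))

    def __mul__(self, other):
        return self._binary(other, np.multiply)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, np.divide)

    def __rtruediv__(self, other):
        arr = self._coerce(other)
        if arr is NotImplemented:
            return NotImplemented
        return self.clone_with(np.divide(arr, self.array))

    def __neg__(self):
        return self.clone_with(-self.array)

    def __pow__(self, p):
        return self.clone_with(self.array ** p)

    # in-place variants: mutate values, never geometry
    def __iadd__(self, other):
        arr = self._coerce(other)
        if arr is NotImplemented:
            return NotImplemented
        self.array += arr
        return self

    def __isub__(self, other):
        arr = self._coerce(other)
        if arr is NotImplemented:
            return NotImplemented
        self.array -= arr
        return self

    def __imul__(self, other):
        arr = self._coerce(other)
        if arr is NotImplemented:
            return NotImplemented
        self.array *= arr
        return self

    def __itruediv__(self, other):
        arr = self._coerce(other)
        if arr is NotImplemented:
            return NotImplemented
        self.array /= arr
        return self

    # comparisons yield plain boolean containers (no geometry semantics lost)
    def __gt__(self, other):
        return self._binary(other, np.greater)

    def __ge__(self, other):
        return self._binary(other, np.greater_equal)

    def __lt__(self, other):
        return self._binary(other, np.less)

    def __le__(self, other):
        return self._binary(other, np.less_equal)

    # -- math functions ------------------------------------------------
    def exp(self):
        return self.clone_with(np.exp(self.array))

    def log(self):
        if np.any(self.array <= 0):
            raise ValueError("log of non-positive entry")
        return self.clone_with(np.log(self.array))

    def abs(self):
        return self.clone_with(np.abs(self.array))

    def sqrt(self):
        return self.clone_with(np.sqrt(self.array))

    def maximum(self, other):
        return self._binary(other, np.maximum)

    def minimum(self, other):
        return self._binary(other, np.minimum)

    def clip(self, lower=None, upper=None):
        return self.clone_with(np.clip(self.array, lower, upper))

    def sign(self):
        return self.clone_with(np.sign(self.array))

    # -- reductions (float64 accumulation) -----------------------------
    def sum(self):
        return float(np.sum(self.array, dtype=np.float64))

    def mean(self):
        return float(np.mean(self.array, dtype=np.float64))

    def max(self):
        return float(np.max(self.array))

    def min(self):
        return float(np.min(self.array))

    def dot(self, other):
        arr = self._coerce(other)
        if arr is NotImplemented:
            raise TypeError("dot requires a congruent container")
        if isinstance(arr, numbers.Number):
            raise TypeError("dot requires a container, not a scalar")
        return float(
            np.dot(
                self.array.ravel().astype(np.float64, copy=False),
                np.asarray(arr).ravel().astype(np.float64, copy=False),
            )
        )

    def norm(self):
        return math.sqrt(self.dot(self))

    def squared_norm(self):
        return self.dot(self)

    # -- structure -----------------------------------------------------
    def get_slice(self, **kwargs):
        """Extract the hyperplane at ``label=index``, dropping that axis.

        The attached geometry is reduced where the reduction is expressible
        (e.g. a vertical slice of a 3D parallel-beam acquisition is a 2D
        one); otherwise the result carries labels but no geometry.
        """
        if len(kwargs) != 1:
            raise ValueError("get_slice takes exactly one label=index pair")
        (label, index), = kwargs.items()
        if label not in self.labels:
            raise ValueError(f"unknown label {label!r}; have {self.labels}")
        axis = self.labels.index(label)
        n = self.shape[axis]
        if not (-n <= index < n):
            raise IndexError(f"index {index} out of range for axis {label!r} of extent {n}")
        values = np.take(self.array, index, axis=axis)
        new_labels = tuple(l for l in self.labels if l != label)
        geometry = None
        if self.geometry is not None:
            geometry = self.geometry.get_slice_geometry(label)
        if geometry is not None:
            return type(self)(values, geometry=geometry)
        return DataContainer(values, labels=new_labels)

    def reorder(self, order):
        """Permute axes to the given label order (pure transposition)."""
        order = tuple(order)
        if sorted(order) != sorted(self.labels):
            raise ValueError(f"order {order} is not a permutation of {self.labels}")
        perm = tuple(self.labels.index(l) for l in order)
        return DataContainer(np.transpose(self.array, perm), labels=order)


class ImageData(DataContainer):
    """Reconstructed / simulated volume data with an :class:`ImageGeometry`."""


class AcquisitionData(DataContainer):
    """Measured (sinogram) data with an :class:`AcquisitionGeometry`."""


class VectorData(DataContainer):
    """Flat dense vector with a :class:`VectorGeometry`."""


class BlockDataContainer:
    """Ordered list of containers supporting joint (blockwise) algebra."""

    def __init__(self, *blocks):
        if len(blocks) == 1 and isinstance(blocks[0], (list, tuple)):
            blocks = tuple(blocks[0])
        if not blocks:
            raise ValueError("BlockDataContainer needs at least one block")
        self.blocks = list(blocks)

    def __len__(self):
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def __getitem__(self, i):
        return self.blocks[i]

    def __repr__(self):
        return f"BlockDataContainer({self.blocks!r})"

    @property
    def shape(self):
        return (len(self.blocks),)

    def copy(self):
        return BlockDataContainer(*[b.copy() for b in self.blocks])

    def fill(self, other):
        if isinstance(other, BlockDataContainer):
            for b, o in zip(self.blocks, other.blocks):
                b.fill(o)
        else:
            for b in self.blocks:
                b.fill(other)
        return self

    def _check(self, other):
        if isinstance(other, BlockDataContainer):
            if len(other) != len(self):
                raise ValueError("block structure mismatch")
            return other.blocks
        if isinstance(other, numbers.Number):
            return [other] * len(self)
        raise TypeError(f"cannot combine BlockDataContainer with {type(other)}")

    def _binary(self, other, op):
        others = self._check(other)
        return BlockDataContainer(*[op(a, b) for a, b in zip(self.blocks, others)])

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b)

    def __rsub__(self, other):
        return self._binary(other, lambda a, b: b - a)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b)

    def __neg__(self):
        return BlockDataContainer(*[-b for b in self.blocks])

    def __iadd__(self, other):
        others = self._check(other)
        for a, b in zip(self.blocks, others):
            a += b
        return self

    def __isub__(self, other):
        others = self._check(other)
        for a, b in zip(self.blocks, others):
            a -= b
        return self

    def __imul__(self, other):
        others = self._check(other)
        for a, b in zip(self.blocks, others):
            a *= b
        return self

    def dot(self, other):
        others = self._check(other)
        return float(sum(a.dot(b) for a, b in zip(self.blocks, others)))

    def squared_norm(self):
        return self.dot(self)

    def norm(self):
        return math.sqrt(self.dot(self))

    def sum(self):
        return float(sum(b.sum() for b in self.blocks))

    def max(self):
        return max(b.max() for b in self.blocks)

    def sqrt(self):
        return BlockDataContainer(*[b.sqrt() for b in self.blocks])

    def abs(self):
        return BlockDataContainer(*[b.abs() for b in self.blocks])

    def maximum(self, other):
        return self._binary(other, lambda a, b: a.maximum(b) if isinstance(b, DataContainer) else a.maximum(b))
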