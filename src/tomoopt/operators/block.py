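"""Block (grid) operators.

A BlockOperator is a rows-by-cols grid of linear operators.  Entries in a
column share a domain and entries in a row share a range; ``None`` entries
act as zero operators.  ``direct`` computes row-wise sums of entry
applications; ``adjoint`` column-wise sums of entry adjoints.  Nesting a
BlockOperator inside another is supported because a block's domain/range may
itself be a BlockGeometry.
"""

from __future__ import annotations

from ..datamodel import BlockGeometry, BlockDataContainer
from .base import LinearOperator, _require_same_geometry

__all__ = ["BlockOperator"]


class BlockOperator(LinearOperator):
    def __init__(self, rows):
        """``rows`` is a list of lists of operators (or None for zero)."""
        if not rows or not all(isinstance(r, (list, tuple)) for r in rows):
            raise ValueError("BlockOperator takes a non-empty list of rows of operators")
        ncols = len(rows[0])
        if ncols == 0 or any(len(r) != ncols for r in rows):
            raise ValueError("all rows must have the same non-zero number of columns")
        self.grid = [list(r) for r in rows]
        self.nrows = len(rows)
        self.ncols = ncols

        col_domains = [None] * ncols
        row_ranges = [None] * self.nrows
        for i, row in enumerate(self.grid):
            for j, op in enumerate(row):
                if op is None:
                    continue
                if col_domains[j] is None:
                    col_domains[j] = op.domain
                else:
                    _require_same_geometry(
                        col_domains[j], op.domain,
                        f"block entry ({i},{j}): domain differs within column")
                if row_ranges[i] is None:
                    row_ranges[i] = op.range
                else:
                    _require_same_geometry(
                        row_ranges[i], op.range,
                        f"block entry ({i},{j}): range differs within row")
        if any(d is None for d in col_domains) or any(r is None for r in row_ranges):
            raise ValueError("every row and column needs at least one non-zero entry")

        domain = col_domains[0] if ncols == 1 else BlockGeometry(*col_domains)
        range_ = row_ranges[0] if self.nrows == 1 else BlockGeometry(*row_ranges)
        super().__init__(domain, range_)
        self._col_domains = col_domains
        self._row_ranges = row_ranges

    def _split_domain(self, x):
        if self.ncols == 1:
            return [x]
        if not isinstance(x, BlockDataContainer) or len(x) != self.ncols:
            raise ValueError("input block structure does not match operator columns")
        return list(x)

    def _split_range(self, y):
        if self.nrows == 1:
            return [y]
        if not isinstance(y, BlockDataContainer) or len(y) != self.nrows:
            raise ValueError("input block structure does not match operator rows")
        return list(y)

    def direct(self, x):
        xs = self._split_domain(x)
        outs = []
        for i, row in enumerate(self.grid):
            acc = None
            for j, op in enumerate(row):
                if op is None:
                    continue
                term = op.direct(xs[j])
                acc = term if acc is None else acc + term
            outs.append(acc)
        return outs[0] if self.nrows == 1 else BlockDataContainer(*outs)

    def adjoint(self, y):
        ys = self._split_range(y)
        outs = []
        for j in range(self.ncols):
            acc = None
            for i, row in enumerate(self.grid):
                op = row[j]
                if op is None:
                    continue
                term = op.adjoint(ys[i])
                acc = term if acc is None else acc + term
            outs.append(acc)
        return outs[0] if self.ncols == 1 else BlockDataContainer(*outs)

    def __getitem__(self, ij):
        i, j = ij
        return self.grid[i][j]
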