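"""Native parallel-beam projector (ray-driven, Joseph-style).

The forward map samples the image along each ray at a step equal to the
smallest voxel size, bilinearly interpolating between voxel centres and
weighting each sample by the step length, so each sinogram entry
approximates the line integral of the image along the ray

    p(t) = (s + rotation_axis_offset) * n_hat + t * d_hat,
    n_hat = (-sin(theta), cos(theta)),   d_hat = (cos(theta), sin(theta)).

Angles are counterclockwise; at theta = 0 the detector coordinate s grows
with +y and rays run along +x.  The whole discretization is assembled once
into a sparse matrix, so the adjoint (back-projection) is its exact
transpose — a matched pair, which is what the convergence theory of the
iterative solvers relies on.

3D parallel geometry is handled slice-by-slice with the same 2D matrix.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ..datamodel import AcquisitionGeometry, ImageGeometry
from .base import LinearOperator

__all__ = ["ProjectionOperator"]

# small process-wide cache: geometries recur across FBP/solver pipelines
_MATRIX_CACHE: dict[tuple, sp.csr_matrix] = {}
_MATRIX_CACHE_MAX = 8


def _matrix_key(ig: ImageGeometry, ag: AcquisitionGeometry):
    return (
        ig.voxel_num_x, ig.voxel_num_y,
        ig.voxel_size_x, ig.voxel_size_y,
        ig.center_x, ig.center_y,
        ag.pixel_num_h, ag.pixel_size_h, ag.rotation_axis_offset,
        tuple(np.round(ag.angles_radian(), 12)),
    )


def build_system_matrix(ig: ImageGeometry, ag: AcquisitionGeometry) -> sp.csr_matrix:
    """Sparse (n_angles*n_det) x (ny*nx) parallel-beam system matrix."""
    nx, ny = ig.voxel_num_x, ig.voxel_num_y
    vx, vy = ig.voxel_size_x, ig.voxel_size_y
    cx, cy = ig.center_x, ig.center_y
    nh = ag.pixel_num_h
    ps = ag.pixel_size_h
    off = ag.rotation_axis_offset
    angles = ag.angles_radian()

    step = min(vx, vy)
    half_diag = 0.5 * np.hypot(nx * vx, ny * vy)
    nt = int(np.ceil(2.0 * half_diag / step)) + 1
    t = (np.arange(nt) - (nt - 1) / 2.0) * step
    s = (np.arange(nh) - (nh - 1) / 2.0) * ps + off

    blocks = []
    for theta in angles:
        nhat = np.array([-np.sin(theta), np.cos(theta)])
        dhat = np.array([np.cos(theta), np.sin(theta)])
        # sample coordinates, shape (nh, nt)
        X = s[:, None] * nhat[0] + t[None, :] * dhat[0]
        Y = s[:, None] * nhat[1] + t[None, :] * dhat[1]
        fx = (X - cx) / vx + (nx - 1) / 2.0
        fy = (Y - cy) / vy + (ny - 1) / 2.0
        ix0 = np.floor(fx).astype(np.int64)
        iy0 = np.floor(fy).astype(np.int64)
        wx = fx - ix0
        wy = fy - iy0
        rows_base = np.repeat(np.arange(nh, dtype=np.int64), nt)

        data_parts, row_parts, col_parts = [], [], []
        for dx, dy, w in (
            (0, 0, (1 - wx) * (1 - wy)),
            (1, 0, wx * (1 - wy)),
            (0, 1, (1 - wx) * wy),
            (1, 1, wx * wy),
        ):
            ix = ix0 + dx
            iy = iy0 + dy
            valid = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            vmask = valid.ravel()
            weights = (w * step).ravel()[vmask]
            if weights.size == 0:
                continue
            data_parts.append(weights)
            row_parts.append(rows_base[vmask])
            col_parts.append((iy.ravel()[vmask] * nx + ix.ravel()[vmask]))
        if data_parts:
            block = sp.csr_matrix(
                (np.concatenate(data_parts),
                 (np.concatenate(row_parts), np.concatenate(col_parts))),
                shape=(nh, ny * nx),
            )
        else:
            block = sp.csr_matrix((nh, ny * nx))
        blocks.append(block)
    return sp.vstack(blocks, format="csr")


class ProjectionOperator(LinearOperator):
    """Discretized Radon transform for parallel 2D/3D geometries."""

    def __init__(self, image_geometry: ImageGeometry, acquisition_geometry: AcquisitionGeometry):
        ag = acquisition_geometry
        ig = image_geometry
        if not ag.is_parallel:
            raise ValueError("only parallel-beam geometries are supported by the native projector")
        if ag.is_3d != ig.is_3d:
            raise ValueError("image and acquisition geometries must both be 2D or both 3D")
        if ag.is_3d:
            if ig.voxel_num_z != ag.pixel_num_v:
                raise ValueError(
                    f"vertical extents differ: {ig.voxel_num_z} voxels vs "
                    f"{ag.pixel_num_v} detector rows")
            if abs(ig.voxel_size_z - ag.pixel_size_v) > 1e-9:
                raise ValueError("vertical voxel size must match the detector pixel size")
        super().__init__(ig, ag)
        self._matrix = None

    @property
    def matrix(self) -> sp.csr_matrix:
        if self._matrix is None:
            key = _matrix_key(self.domain, self.range)
            if key not in _MATRIX_CACHE:
                if len(_MATRIX_CACHE) >= _MATRIX_CACHE_MAX:
                    _MATRIX_CACHE.pop(next(iter(_MATRIX_CACHE)))
                _MATRIX_CACHE[key] = build_system_matrix(self.domain, self.range)
            self._matrix = _MATRIX_CACHE[key]
        return self._matrix

    def direct(self, x):
        ag = self.range
        M = self.matrix
        u = x.as_array().astype(np.float64, copy=False)
        if ag.is_3d:
            nz = self.domain.voxel_num_z
            u2 = u.reshape(nz, -1)                       # (nz, ny*nx)
            sino = (M @ u2.T)                            # (na*nh, nz)
            na, nh = ag.num_angles, ag.pixel_num_h
            out = sino.reshape(na, nh, nz).transpose(0, 2, 1)
        else:
            out = (M @ u.ravel()).reshape(ag.num_angles, ag.pixel_num_h)
        return ag.allocate(dtype=np.float64).fill(out)

    def adjoint(self, y):
        ig = self.domain
        M = self.matrix
        b = y.as_array().astype(np.float64, copy=False)
        if self.range.is_3d:
            na, nv, nh = b.shape
            b2 = b.transpose(0, 2, 1).reshape(na * nh, nv)
            vol = (M.T @ b2).T.reshape(nv, ig.voxel_num_y, ig.voxel_num_x)
        else:
            vol = (M.T @ b.ravel()).reshape(ig.voxel_num_y, ig.voxel_num_x)
        return ig.allocate(dtype=np.float64).fill(vol)
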