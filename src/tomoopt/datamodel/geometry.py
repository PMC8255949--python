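"""Scan and volume geometry descriptions.

Two concrete geometry classes describe the measurement side
(:class:`AcquisitionGeometry`) and the reconstruction side
(:class:`ImageGeometry`).  A lightweight :class:`VectorGeometry` backs plain
dense-vector problems (small dense oracles, matrix operators) and
:class:`BlockGeometry` groups several geometries for block-structured
operators.

Conventions
-----------
* Canonical axis order: acquisition data ``(angle, vertical, horizontal)``
  (2D drops ``vertical``); image data ``(vertical, horizontal_y,
  horizontal_x)`` (2D drops ``vertical``).
* Angles are stored with an explicit unit flag, degrees by default, and are
  measured counterclockwise.
* Physical coordinates place voxel/pixel centres on the grid; the volume is
  centred at the origin plus the ``center_*`` offsets.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "ImageGeometry",
    "VectorGeometry",
    "BlockGeometry",
    "create_acquisition_geometry",
    "default_image_geometry",
    "BEAM_TYPES",
    "ANGLE_UNITS",
]

BEAM_TYPES = ("parallel2D", "parallel3D", "cone2D", "cone3D")
ANGLE_UNITS = ("degree", "radian")

#: tolerance used for float comparisons in geometry equality
GEOMETRY_TOL = 1e-9


def _float_eq(a, b, tol=GEOMETRY_TOL):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        return False
    return bool(np.all(np.abs(a - b) <= tol))


class AcquisitionGeometry:
    """Scan configuration keyed to sinogram data.

    Parameters
    ----------
    beam_type:
        One of ``parallel2D``, ``parallel3D``, ``cone2D``, ``cone3D``.
        Cone geometries are *represented* (stored, serialized) but are not
        supported by the native projector.
    angles:
        Ordered sequence of rotation angles, at least one.
    angle_unit:
        ``"degree"`` (default) or ``"radian"``.
    pixel_num_h, pixel_num_v:
        Detector pixel counts.  ``pixel_num_v`` is ignored for 2D beams.
    pixel_size_h, pixel_size_v:
        Physical detector pixel sizes (> 0).
    rotation_axis_offset:
        Horizontal displacement (physical length) of the rotation-axis image
        on the detector.
    rotation_axis_direction:
        3-vector, default ``(0, 0, 1)``; a tilt is representable for cone3D
        (laminography) but no projector consumes it.
    source_position, detector_position:
        3-vectors, required for cone beams.
    """

    def __init__(
        self,
        beam_type: str,
        angles: Sequence[float],
        pixel_num_h: int,
        pixel_num_v: int | None = None,
        pixel_size_h: float = 1.0,
        pixel_size_v: float = 1.0,
        angle_unit: str = "degree",
        rotation_axis_offset: float = 0.0,
        rotation_axis_direction: Sequence[float] = (0.0, 0.0, 1.0),
        source_position: Sequence[float] | None = None,
        detector_position: Sequence[float] | None = None,
    ):
        if beam_type not in BEAM_TYPES:
            raise ValueError(f"unknown beam_type {beam_type!r}; expected one of {BEAM_TYPES}")
        if angle_unit not in ANGLE_UNITS:
            raise ValueError(f"unknown angle_unit {angle_unit!r}; expected one of {ANGLE_UNITS}")
        angles = np.atleast_1d(np.asarray(angles, dtype=float))
        if angles.size == 0:
            raise ValueError("at least one projection angle is required")
        if angles.ndim != 1:
            raise ValueError("angles must be a 1D sequence")
        if int(pixel_num_h) < 1:
            raise ValueError("pixel_num_h must be >= 1")
        if pixel_size_h <= 0 or pixel_size_v <= 0:
            raise ValueError("pixel sizes must be > 0")
        self.beam_type = beam_type
        self.angles = angles
        self.angle_unit = angle_unit
        self.pixel_num_h = int(pixel_num_h)
        self.pixel_size_h = float(pixel_size_h)
        self.pixel_size_v = float(pixel_size_v)
        if self.is_3d:
            if pixel_num_v is None or int(pixel_num_v) < 1:
                raise ValueError("pixel_num_v must be >= 1 for a 3D beam")
            self.pixel_num_v = int(pixel_num_v)
        else:
            self.pixel_num_v = None
        self.rotation_axis_offset = float(rotation_axis_offset)
        self.rotation_axis_direction = np.asarray(rotation_axis_direction, dtype=float)
        if self.rotation_axis_direction.shape != (3,):
            raise ValueError("rotation_axis_direction must be a 3-vector")
        if beam_type.startswith("cone"):
            if source_position is None or detector_position is None:
                raise ValueError(f"{beam_type} requires source_position and detector_position")
            self.source_position = np.asarray(source_position, dtype=float)
            self.detector_position = np.asarray(detector_position, dtype=float)
            if self.source_position.shape != (3,) or self.detector_position.shape != (3,):
                raise ValueError("source/detector positions must be 3-vectors")
        else:
            self.source_position = None
            self.detector_position = None

    # ------------------------------------------------------------------
    @property
    def is_parallel(self) -> bool:
        return self.beam_type.startswith("parallel")

    @property
    def is_3d(self) -> bool:
        return self.beam_type.endswith("3D")

    @property
    def num_angles(self) -> int:
        return int(self.angles.size)

    @property
    def dimension_labels(self) -> tuple[str, ...]:
        if self.is_3d:
            return ("angle", "vertical", "horizontal")
        return ("angle", "horizontal")

    @property
    def shape(self) -> tuple[int, ...]:
        if self.is_3d:
            return (self.num_angles, self.pixel_num_v, self.pixel_num_h)
        return (self.num_angles, self.pixel_num_h)

    def angles_radian(self) -> np.ndarray:
        if self.angle_unit == "radian":
            return self.angles.copy()
        return np.deg2rad(self.angles)

    # ------------------------------------------------------------------
    def allocate(self, fill=0.0, seed: int | None = None, dtype=np.float32):
        from .containers import AcquisitionData

        return AcquisitionData(_alloc(self.shape, fill, seed, dtype), geometry=self)

    def copy(self) -> "AcquisitionGeometry":
        return AcquisitionGeometry(
            self.beam_type,
            self.angles.copy(),
            self.pixel_num_h,
            self.pixel_num_v,
            self.pixel_size_h,
            self.pixel_size_v,
            self.angle_unit,
            self.rotation_axis_offset,
            self.rotation_axis_direction.copy(),
            None if self.source_position is None else self.source_position.copy(),
            None if self.detector_position is None else self.detector_position.copy(),
        )

    def get_slice_geometry(self, label: str) -> "AcquisitionGeometry | None":
        """Geometry left after removing ``label``; None if not representable."""
        if label == "vertical" and self.is_3d:
            g = self.copy()
            g.beam_type = "parallel2D" if self.is_parallel else "cone2D"
            g.pixel_num_v = None
            return g
        return None

    def __eq__(self, other) -> bool:
        if not isinstance(other, AcquisitionGeometry):
            return NotImplemented
        if self.beam_type != other.beam_type or self.angle_unit != other.angle_unit:
            return False
        if self.pixel_num_h != other.pixel_num_h or self.pixel_num_v != other.pixel_num_v:
            return False
        if not _float_eq(self.angles, other.angles):
            return False
        for a, b in (
            (self.pixel_size_h, other.pixel_size_h),
            (self.pixel_size_v, other.pixel_size_v),
            (self.rotation_axis_offset, other.rotation_axis_offset),
        ):
            if not _float_eq(a, b):
                return False
        if not _float_eq(self.rotation_axis_direction, other.rotation_axis_direction):
            return False
        for a, b in ((self.source_position, other.source_position),
                     (self.detector_position, other.detector_position)):
            if (a is None) != (b is None):
                return False
            if a is not None and not _float_eq(a, b):
                return False
        return True

    __hash__ = None

    def __repr__(self) -> str:
        return (
            f"AcquisitionGeometry({self.beam_type}, {self.num_angles} angles "
            f"[{self.angle_unit}], shape={self.shape})"
        )


class ImageGeometry:
    """Voxel-grid specification of a reconstruction volume.

    A 2D geometry is expressed with ``voxel_num_z=None``; its canonical labels
    are ``(horizontal_y, horizontal_x)``.
    """

    def __init__(
        self,
        voxel_num_x: int,
        voxel_num_y: int,
        voxel_num_z: int | None = None,
        voxel_size_x: float = 1.0,
        voxel_size_y: float = 1.0,
        voxel_size_z: float = 1.0,
        center_x: float = 0.0,
        center_y: float = 0.0,
        center_z: float = 0.0,
    ):
        if int(voxel_num_x) < 1 or int(voxel_num_y) < 1:
            raise ValueError("voxel counts must be >= 1")
        if voxel_num_z is not None and int(voxel_num_z) < 1:
            raise ValueError("voxel_num_z must be >= 1 (or None for 2D)")
        if voxel_size_x <= 0 or voxel_size_y <= 0 or voxel_size_z <= 0:
            raise ValueError("voxel sizes must be > 0")
        self.voxel_num_x = int(voxel_num_x)
        self.voxel_num_y = int(voxel_num_y)
        self.voxel_num_z = None if voxel_num_z is None else int(voxel_num_z)
        self.voxel_size_x = float(voxel_size_x)
        self.voxel_size_y = float(voxel_size_y)
        self.voxel_size_z = float(voxel_size_z)
        self.center_x = float(center_x)
        self.center_y = float(center_y)
        self.center_z = float(center_z)

    @property
    def is_3d(self) -> bool:
        return self.voxel_num_z is not None

    @property
    def dimension_labels(self) -> tuple[str, ...]:
        if self.is_3d:
            return ("vertical", "horizontal_y", "horizontal_x")
        return ("horizontal_y", "horizontal_x")

    @property
    def shape(self) -> tuple[int, ...]:
        if self.is_3d:
            return (self.voxel_num_z, self.voxel_num_y, self.voxel_num_x)
        return (self.voxel_num_y, self.voxel_num_x)

    def allocate(self, fill=0.0, seed: int | None = None, dtype=np.float32):
        from .containers import ImageData

        return ImageData(_alloc(self.shape, fill, seed, dtype), geometry=self)

    def copy(self) -> "ImageGeometry":
        return ImageGeometry(
            self.voxel_num_x, self.voxel_num_y, self.voxel_num_z,
            self.voxel_size_x, self.voxel_size_y, self.voxel_size_z,
            self.center_x, self.center_y, self.center_z,
        )

    def get_slice_geometry(self, label: str) -> "ImageGeometry | None":
        if label == "vertical" and self.is_3d:
            g = self.copy()
            g.voxel_num_z = None
            return g
        return None

    def __eq__(self, other) -> bool:
        if not isinstance(other, ImageGeometry):
            return NotImplemented
        if (self.voxel_num_x, self.voxel_num_y, self.voxel_num_z) != (
            other.voxel_num_x, other.voxel_num_y, other.voxel_num_z,
        ):
            return False
        return all(
            _float_eq(a, b)
            for a, b in (
                (self.voxel_size_x, other.voxel_size_x),
                (self.voxel_size_y, other.voxel_size_y),
                (self.voxel_size_z, other.voxel_size_z),
                (self.center_x, other.center_x),
                (self.center_y, other.center_y),
                (self.center_z, other.center_z),
            )
        )

    __hash__ = None

    def __repr__(self) -> str:
        return f"ImageGeometry(shape={self.shape})"


class VectorGeometry:
    """Geometry of a flat dense vector of given length."""

    dimension_labels = ("index",)

    def __init__(self, length: int):
        if int(length) < 1:
            raise ValueError("length must be >= 1")
        self.length = int(length)

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.length,)

    def allocate(self, fill=0.0, seed: int | None = None, dtype=np.float32):
        from .containers import VectorData

        return VectorData(_alloc(self.shape, fill, seed, dtype), geometry=self)

    def copy(self) -> "VectorGeometry":
        return VectorGeometry(self.length)

    def __eq__(self, other):
        if not isinstance(other, VectorGeometry):
            return NotImplemented
        return self.length == other.length

    __hash__ = None

    def __repr__(self):
        return f"VectorGeometry({self.length})"


class BlockGeometry:
    """Ordered list of geometries, the domain/range of block operators."""

    def __init__(self, *geometries):
        if len(geometries) == 1 and isinstance(geometries[0], (list, tuple)):
            geometries = tuple(geometries[0])
        if not geometries:
            raise ValueError("BlockGeometry needs at least one geometry")
        self.geometries = tuple(geometries)

    def __len__(self):
        return len(self.geometries)

    def __iter__(self):
        return iter(self.geometries)

    def __getitem__(self, i):
        return self.geometries[i]

    def allocate(self, fill=0.0, seed: int | None = None, dtype=np.float32):
        from .containers import BlockDataContainer

        blocks = []
        for k, g in enumerate(self.geometries):
            s = None if seed is None else seed + 1000003 * k
            blocks.append(g.allocate(fill, seed=s, dtype=dtype))
        return BlockDataContainer(*blocks)

    def copy(self):
        return BlockGeometry(*[g.copy() for g in self.geometries])

    def __eq__(self, other):
        if not isinstance(other, BlockGeometry):
            return NotImplemented
        return len(self) == len(other) and all(
            a == b for a, b in zip(self.geometries, other.geometries)
        )

    __hash__ = None

    def __repr__(self):
        return f"BlockGeometry({list(self.geometries)!r})"


# ----------------------------------------------------------------------
def _alloc(shape, fill, seed, dtype):
    if isinstance(fill, str):
        if fill != "random":
            raise ValueError(f"unknown fill {fill!r}")
        rng = np.random.default_rng(seed)
        return rng.random(shape).astype(dtype)
    return np.full(shape, fill, dtype=dtype)


def create_acquisition_geometry(**config) -> AcquisitionGeometry:
    """Build a validated :class:`AcquisitionGeometry` from key/value config.

    Required keys: ``beam_type``, ``angles``, ``pixel_num_h`` (plus
    ``pixel_num_v`` for 3D beams; cone beams additionally require
    ``source_position`` and ``detector_position``).  Everything else defaults:
    degrees, unit pixel sizes, zero axis offset, axis along +z.
    """
    return AcquisitionGeometry(**config)


def default_image_geometry(ag: AcquisitionGeometry) -> ImageGeometry:
    """Default reconstruction grid for a parallel-beam acquisition.

    The in-plane grid is square with ``pixel_num_h`` voxels per side; the
    vertical extent copies the detector.  Voxel sizes equal pixel sizes and
    the volume is centred at the origin.
    """
    if not ag.is_parallel:
        raise ValueError("default image geometry is only defined for parallel beams "
                         "(cone magnification rule out of scope)")
    if ag.is_3d:
        return ImageGeometry(
            voxel_num_x=ag.pixel_num_h,
            voxel_num_y=ag.pixel_num_h,
            voxel_num_z=ag.pixel_num_v,
            voxel_size_x=ag.pixel_size_h,
            voxel_size_y=ag.pixel_size_h,
            voxel_size_z=ag.pixel_size_v,
        )
    return ImageGeometry(
        voxel_num_x=ag.pixel_num_h,
        voxel_num_y=ag.pixel_num_h,
        voxel_size_x=ag.pixel_size_h,
        voxel_size_y=ag.pixel_size_h,
    )
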