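"""File I/O: TIFF stacks (with a YAML geometry sidecar) and a fixed
NeXus-style HDF5 dialect.

HDF5 layout::

    /entry1/tomo_entry/data/data          float32 values
    /entry1/tomo_entry/config/<field>     geometry fields, labels, angle unit

Data is stored as 32-bit floats on disk; roundtrips are bit-exact at that
precision and geometry survives to equality-with-tolerance.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from ..datamodel import (
    AcquisitionData,
    AcquisitionGeometry,
    DataContainer,
    ImageData,
    ImageGeometry,
)

__all__ = [
    "geometry_to_dict",
    "geometry_from_dict",
    "write_tiff_stack",
    "read_tiff_stack",
    "write_hdf5",
    "read_hdf5",
]

_DATA_PATH = "entry1/tomo_entry/data/data"
_CONFIG_PATH = "entry1/tomo_entry/config"


def geometry_to_dict(geometry) -> dict:
    if isinstance(geometry, AcquisitionGeometry):
        d = {
            "type": "acquisition",
            "beam_type": geometry.beam_type,
            "angles": [float(a) for a in geometry.angles],
            "angle_unit": geometry.angle_unit,
            "pixel_num_h": geometry.pixel_num_h,
            "pixel_size_h": geometry.pixel_size_h,
            "pixel_size_v": geometry.pixel_size_v,
            "rotation_axis_offset": geometry.rotation_axis_offset,
            "rotation_axis_direction": [float(v) for v in geometry.rotation_axis_direction],
        }
        if geometry.pixel_num_v is not None:
            d["pixel_num_v"] = geometry.pixel_num_v
        if geometry.source_position is not None:
            d["source_position"] = [float(v) for v in geometry.source_position]
            d["detector_position"] = [float(v) for v in geometry.detector_position]
        return d
    if isinstance(geometry, ImageGeometry):
        return {
            "type": "image",
            "voxel_num_x": geometry.voxel_num_x,
            "voxel_num_y": geometry.voxel_num_y,
            "voxel_num_z": geometry.voxel_num_z,
            "voxel_size_x": geometry.voxel_size_x,
            "voxel_size_y": geometry.voxel_size_y,
            "voxel_size_z": geometry.voxel_size_z,
            "center_x": geometry.center_x,
            "center_y": geometry.center_y,
            "center_z": geometry.center_z,
        }
    raise TypeError(f"cannot serialize geometry of type {type(geometry)}")


def geometry_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("type")
    if kind == "acquisition":
        return AcquisitionGeometry(**d)
    if kind == "image":
        return ImageGeometry(**d)
    raise ValueError(f"unknown geometry type {kind!r}")


def _wrap(values: np.ndarray, geometry):
    if isinstance(geometry, AcquisitionGeometry):
        return AcquisitionData(values, geometry=geometry)
    if isinstance(geometry, ImageGeometry):
        return ImageData(values, geometry=geometry)
    return DataContainer(values)


# ----------------------------------------------------------------------
def write_tiff_stack(data, directory, prefix: str = "slice") -> list[str]:
    """One float32 TIFF per leading-axis index, 5-digit zero-padded suffix.

    A ``<prefix>_geometry.yaml`` sidecar stores the geometry when present.
    Returns the list of file paths written.
    """
    if data.ndim not in (2, 3):
        raise ValueError("TIFF stacks support 2D and 3D data only")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arr = data.as_array().astype(np.float32)
    paths = []
    for i in range(arr.shape[0]):
        frame = arr[i]
        if frame.ndim == 1:
            frame = frame[None, :]
        path = directory / f"{prefix}_{i:05d}.tiff"
        tifffile.imwrite(path, frame)
        paths.append(str(path))
    if data.geometry is not None:
        with open(directory / f"{prefix}_geometry.yaml", "w") as fh:
            yaml.safe_dump(geometry_to_dict(data.geometry), fh)
    return paths


def read_tiff_stack(directory, prefix: str = "slice", geometry=None):
    """Read a stack written by :func:`write_tiff_stack`."""
    directory = Path(directory)
    files = sorted(directory.glob(f"{prefix}_[0-9][0-9][0-9][0-9][0-9].tiff"))
    if not files:
        raise FileNotFoundError(f"no files matching {prefix}_*.tiff in {directory}")
    if geometry is None:
        sidecar = directory / f"{prefix}_geometry.yaml"
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no geometry given and no sidecar {sidecar.name}; pass geometry explicitly")
        with open(sidecar) as fh:
            geometry = geometry_from_dict(yaml.safe_load(fh))
    frames = [tifffile.imread(f) for f in files]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in stack: {sorted(shapes)}")
    arr = np.stack(frames, axis=0)
    expected = tuple(geometry.shape)
    if arr.shape != expected:
        squeezed = arr.squeeze(axis=1) if arr.ndim == 3 and arr.shape[1] == 1 else arr
        if squeezed.shape != expected:
            raise ValueError(f"stack shape {arr.shape} does not match geometry shape {expected}")
        arr = squeezed
    return _wrap(arr, geometry)


# ----------------------------------------------------------------------
def write_hdf5(data, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        dset = f.create_dataset(_DATA_PATH, data=data.as_array().astype(np.float32))
        dset.attrs["dimension_labels"] = [str(l) for l in data.labels]
        cfg = f.require_group(_CONFIG_PATH)
        if data.geometry is not None:
            for key, value in geometry_to_dict(data.geometry).items():
                if value is None:
                    continue
                cfg.attrs[key] = value


def read_hdf5(path):
    with h5py.File(path, "r") as f:
        if _DATA_PATH not in f:
            raise ValueError(f"malformed file: missing dataset /{_DATA_PATH}")
        values = f[_DATA_PATH][...]
        cfg = f.get(_CONFIG_PATH)
        geometry = None
        if cfg is not None and len(cfg.attrs):
            d = {}
            for key, value in cfg.attrs.items():
                if isinstance(value, bytes):
                    value = value.decode()
                elif isinstance(value, np.ndarray):
                    value = value.tolist()
                elif isinstance(value, np.generic):
                    value = value.item()
                d[key] = value
            geometry = geometry_from_dict(d)
    return _wrap(values, geometry)
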