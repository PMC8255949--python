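"""Preprocessing transforms on acquisition/image data.

Each processor validates its parameters at construction, before any data is
seen, and is a callable mapping a data container to a new data container
whose geometry is updated consistently (counts, sizes, angle lists, and the
rotation-axis offset when the horizontal detector axis is cropped, binned
or padded).

Indexing is 0-based with half-open ``(start, stop, step)`` ranges.  The
centre-of-rotation corrector writes its estimate into the geometry rather
than resampling data; the projector and FBP consume the offset from there.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import AcquisitionGeometry, DataContainer, ImageGeometry

__all__ = [
    "normalise",
    "negative_log",
    "slice_axes",
    "bin_axes",
    "pad_axes",
    "find_centre_of_rotation",
    "make_mask",
    "apply_mask",
    "Normaliser",
    "NegativeLog",
    "Slicer",
    "Binner",
    "Padder",
    "CentreOfRotationCorrector",
    "MaskGenerator",
    "Masker",
    "ProcessorSpec",
    "PROCESSOR_NAMES",
]


# ----------------------------------------------------------------------
# geometry axis bookkeeping
#
# Spatial axes follow the coordinate model coord(i) = (i - (n-1)/2)*size +
# centre; for the acquisition "horizontal" axis the rotation-axis offset
# plays the role of the centre (the projector adds it to the detector
# coordinate), so cropping or binning the detector keeps rays in place.

_ACQ_AXES = {
    "vertical": ("pixel_num_v", "pixel_size_v", None),
    "horizontal": ("pixel_num_h", "pixel_size_h", "rotation_axis_offset"),
}
_IMG_AXES = {
    "vertical": ("voxel_num_z", "voxel_size_z", "center_z"),
    "horizontal_y": ("voxel_num_y", "voxel_size_y", "center_y"),
    "horizontal_x": ("voxel_num_x", "voxel_size_x", "center_x"),
}


def _axis_attrs(geometry, label):
    table = _ACQ_AXES if isinstance(geometry, AcquisitionGeometry) else _IMG_AXES
    return table.get(label)


def _update_geometry_slice(geometry, label, start, stop, step):
    if geometry is None:
        return None
    g = geometry.copy()
    if label == "angle":
        g.angles = g.angles[start:stop:step]
        return g
    attrs = _axis_attrs(geometry, label)
    if attrs is None:
        return None
    num_attr, size_attr, centre_attr = attrs
    n_old = getattr(g, num_attr)
    n_new = len(range(start, stop, step))
    size = getattr(g, size_attr)
    c_old = (n_old - 1) / 2.0
    c_new = (n_new - 1) / 2.0
    setattr(g, num_attr, n_new)
    if centre_attr is not None:
        shift = (start + c_new * step - c_old) * size
        setattr(g, centre_attr, getattr(g, centre_attr) + shift)
    return g


def _update_geometry_bin(geometry, label, factor):
    if geometry is None:
        return None
    g = geometry.copy()
    if label == "angle":
        n = (g.angles.size // factor) * factor
        g.angles = g.angles[:n].reshape(-1, factor).mean(axis=1)
        return g
    attrs = _axis_attrs(geometry, label)
    if attrs is None:
        return None
    num_attr, size_attr, centre_attr = attrs
    n_old = getattr(g, num_attr)
    n_new = n_old // factor
    size = getattr(g, size_attr)
    c_old = (n_old - 1) / 2.0
    c_new = (n_new - 1) / 2.0
    setattr(g, num_attr, n_new)
    setattr(g, size_attr, size * factor)
    if centre_attr is not None:
        shift = ((factor - 1) / 2.0 - c_old + c_new * factor) * size
        setattr(g, centre_attr, getattr(g, centre_attr) + shift)
    return g


def _update_geometry_pad(geometry, label, before, after):
    if geometry is None:
        return None
    if label == "angle":
        raise ValueError("padding the angle axis is not supported")
    g = geometry.copy()
    attrs = _axis_attrs(geometry, label)
    if attrs is None:
        return None
    num_attr, size_attr, centre_attr = attrs
    n_old = getattr(g, num_attr)
    n_new = n_old + before + after
    size = getattr(g, size_attr)
    c_old = (n_old - 1) / 2.0
    c_new = (n_new - 1) / 2.0
    setattr(g, num_attr, n_new)
    if centre_attr is not None:
        shift = (c_new - before - c_old) * size
        setattr(g, centre_attr, getattr(g, centre_attr) + shift)
    return g


def _rebuild(x, values, geometry):
    if geometry is not None:
        return type(x)(values, geometry=geometry)
    return DataContainer(values, labels=x.labels)


# ----------------------------------------------------------------------
def normalise(raw, flat, dark, epsilon: float = 1e-6):
    """Flat/dark-field correction (raw - dark) / (flat - dark).

    ``flat``/``dark`` may be plain arrays or containers broadcastable to the
    detector shape.  Where |flat - dark| < epsilon the output is set to 1.0
    and a warning reports the count.
    """
    flat_arr = np.asarray(flat.as_array() if isinstance(flat, DataContainer) else flat,
                          dtype=np.float64)
    dark_arr = np.asarray(dark.as_array() if isinstance(dark, DataContainer) else dark,
                          dtype=np.float64)
    raw_arr = raw.as_array().astype(np.float64, copy=False)
    denom = flat_arr - dark_arr
    try:
        np.broadcast_shapes(raw_arr.shape, denom.shape)
    except ValueError as exc:
        raise ValueError(f"flat/dark not broadcastable to data shape: {exc}") from exc
    degenerate = np.abs(denom) < epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (raw_arr - dark_arr) / denom
    out = np.where(np.broadcast_to(degenerate, out.shape), 1.0, out)
    n_bad = int(np.count_nonzero(degenerate))
    if n_bad:
        warnings.warn(f"normalise: {n_bad} detector elements with |flat - dark| < "
                      f"{epsilon}; output set to 1.0 there")
    return _rebuild(raw, out, raw.geometry)


def negative_log(x, clip_floor: float = 1e-6):
    """Lambert-Beer conversion -log(max(x, clip_floor))."""
    if clip_floor <= 0:
        raise ValueError("clip_floor must be positive")
    arr = x.as_array().astype(np.float64, copy=False)
    n_floored = int(np.count_nonzero(arr < clip_floor))
    if n_floored:
        warnings.warn(f"negative_log: {n_floored} entries below {clip_floor} were floored")
    return _rebuild(x, -np.log(np.maximum(arr, clip_floor)), x.geometry)


def _validate_roi(x, roi):
    for label in roi:
        if label not in x.labels:
            raise ValueError(f"unknown label {label!r}; data has {x.labels}")


def slice_axes(x, roi: dict):
    """Subsample/crop axes by per-label half-open (start, stop, step) ranges."""
    _validate_roi(x, roi)
    slicers = [slice(None)] * x.ndim
    geometry = x.geometry
    for label, (start, stop, step) in roi.items():
        axis = x.labels.index(label)
        n = x.shape[axis]
        start, stop, step = int(start), int(stop), int(step)
        if step < 1:
            raise ValueError("step must be >= 1")
        start = max(start, 0)
        stop = min(stop, n)
        if len(range(start, stop, step)) == 0:
            raise ValueError(f"slicing leaves axis {label!r} empty")
        slicers[axis] = slice(start, stop, step)
        geometry = _update_geometry_slice(geometry, label, start, stop, step)
    return _rebuild(x, x.as_array()[tuple(slicers)].copy(), geometry)


def bin_axes(x, factors: dict):
    """Non-overlapping block means; trailing remainder elements are dropped."""
    _validate_roi(x, factors)
    arr = x.as_array().astype(np.float64, copy=False)
    geometry = x.geometry
    for label, factor in factors.items():
        factor = int(factor)
        if factor < 1:
            raise ValueError("binning factor must be >= 1")
        axis = x.labels.index(label)
        n = arr.shape[axis]
        if factor > n:
            raise ValueError(f"binning factor {factor} exceeds axis {label!r} extent {n}")
        if factor == 1:
            continue
        n_keep = (n // factor) * factor
        sl = [slice(None)] * arr.ndim
        sl[axis] = slice(0, n_keep)
        trimmed = arr[tuple(sl)]
        new_shape = list(trimmed.shape)
        new_shape[axis] = n // factor
        new_shape.insert(axis + 1, factor)
        arr = trimmed.reshape(new_shape).mean(axis=axis + 1)
        geometry = _update_geometry_bin(geometry, label, factor)
    return _rebuild(x, arr, geometry)


def pad_axes(x, widths: dict, mode: str = "constant", value: float = 0.0):
    """Extend axes by (before, after) elements; constant (default 0) or edge."""
    if mode not in ("constant", "edge"):
        raise ValueError("mode must be 'constant' or 'edge'")
    _validate_roi(x, widths)
    pad_spec = [(0, 0)] * x.ndim
    geometry = x.geometry
    for label, (before, after) in widths.items():
        before, after = int(before), int(after)
        if before < 0 or after < 0:
            raise ValueError("pad widths must be >= 0")
        axis = x.labels.index(label)
        pad_spec[axis] = (before, after)
        if before or after:
            geometry = _update_geometry_pad(geometry, label, before, after)
    if mode == "constant":
        arr = np.pad(x.as_array(), pad_spec, mode="constant", constant_values=value)
    else:
        arr = np.pad(x.as_array(), pad_spec, mode="edge")
    return _rebuild(x, arr, geometry)


# ----------------------------------------------------------------------
def find_centre_of_rotation(data, angle_tolerance: float = 0.1):
    """Estimate the rotation-axis offset, in detector pixels (signed).

    Works on parallel-beam data containing an opposing angle pair
    (theta, theta + 180 deg) within ``angle_tolerance`` degrees.  The
    central-row profile at theta is cross-correlated (after mean removal
    and variance normalization) against the horizontally flipped profile at
    theta + 180 deg; half the argmax lag, refined by 3-point parabolic
    interpolation, is the offset estimate.  The data is untouched: apply
    :class:`CentreOfRotationCorrector` to write the estimate into the
    geometry.
    """
    ag = data.geometry
    if ag is None or not ag.is_parallel:
        raise ValueError("centre-of-rotation estimation requires parallel-beam data")
    if ag.num_angles < 2:
        raise ValueError("need at least two projections to find an opposing pair")
    sino = data
    if ag.is_3d:
        sino = data.get_slice(vertical=ag.pixel_num_v // 2)
    arr = sino.as_array().astype(np.float64, copy=False)  # (angle, horizontal)

    angles_deg = ag.angles if ag.angle_unit == "degree" else np.rad2deg(ag.angles)
    pair = None
    for i in range(ag.num_angles):
        diffs = np.mod(angles_deg - angles_deg[i], 360.0)
        js = np.where(np.abs(diffs - 180.0) <= angle_tolerance)[0]
        if js.size:
            pair = (i, int(js[0]))
            break
    if pair is None:
        raise ValueError(
            f"no opposing projection pair (180 deg within {angle_tolerance} deg) found")

    p1 = arr[pair[0]]
    p2 = arr[pair[1]][::-1]
    if p1.std() == 0 or p2.std() == 0:
        raise ValueError("flat (zero-variance) profiles; cannot correlate")

    # per-lag normalized cross-correlation (Pearson r over the overlap);
    # global-mean NCC is biased towards zero lag by the zero padding
    n = p1.size
    max_lag = max(n // 3, 4)
    lags = np.arange(-max_lag, max_lag + 1)
    scores = np.full(lags.size, -np.inf)
    for k, lag in enumerate(lags):
        if lag >= 0:
            a_seg, b_seg = p1[lag:], p2[: n - lag]
        else:
            a_seg, b_seg = p1[: n + lag], p2[-lag:]
        if a_seg.size < 8:
            continue
        sa, sb = a_seg.std(), b_seg.std()
        if sa == 0 or sb == 0:
            continue
        scores[k] = np.mean((a_seg - a_seg.mean()) * (b_seg - b_seg.mean())) / (sa * sb)
    m = int(np.argmax(scores))
    lag = float(lags[m])
    if 0 < m < scores.size - 1 and np.all(np.isfinite(scores[m - 1: m + 2])):
        denom = scores[m - 1] - 2.0 * scores[m] + scores[m + 1]
        if denom != 0:
            lag += 0.5 * (scores[m - 1] - scores[m + 1]) / denom
    return -0.5 * lag


def make_mask(x, method: str = "threshold", lo=-np.inf, hi=np.inf, quantile: float = 0.99):
    """Boolean keep-mask: True where data is retained.

    ``threshold`` keeps entries inside [lo, hi]; ``quantile`` keeps the
    central ``quantile`` fraction (entries outside the symmetric quantile
    range are masked out).
    """
    arr = x.as_array()
    if method == "threshold":
        mask = (arr >= lo) & (arr <= hi)
    elif method == "quantile":
        if not (0 < quantile <= 1):
            raise ValueError("quantile must lie in (0, 1]")
        lo_q = np.quantile(arr, (1.0 - quantile) / 2.0)
        hi_q = np.quantile(arr, (1.0 + quantile) / 2.0)
        mask = (arr >= lo_q) & (arr <= hi_q)
    else:
        raise ValueError("method must be 'threshold' or 'quantile'")
    return DataContainer(mask, labels=x.labels)


def apply_mask(x, mask, fill: str = "value", value: float = 0.0):
    """Replace masked-out (False) entries per the fill rule.

    ``value`` writes a constant; ``neighbour-mean`` iteratively replaces
    each masked entry by the mean of its valid orthogonal neighbours.
    """
    marr = np.asarray(mask.as_array() if isinstance(mask, DataContainer) else mask, dtype=bool)
    if marr.shape != x.shape:
        raise ValueError(f"mask shape {marr.shape} does not match data shape {x.shape}")
    arr = x.as_array().astype(np.float64).copy()
    if fill == "value":
        arr[~marr] = value
    elif fill == "neighbour-mean":
        if not marr.any():
            raise ValueError("all-false mask cannot be filled from neighbours")
        valid = marr.copy()
        while not valid.all():
            acc = np.zeros_like(arr)
            cnt = np.zeros_like(arr)
            for axis in range(arr.ndim):
                for shift in (1, -1):
                    v = np.roll(np.where(valid, arr, 0.0), shift, axis=axis)
                    c = np.roll(valid.astype(np.float64), shift, axis=axis)
                    # rolled-in wrap entries are invalid
                    sl = [slice(None)] * arr.ndim
                    sl[axis] = 0 if shift == 1 else -1
                    v[tuple(sl)] = 0.0
                    c[tuple(sl)] = 0.0
                    acc += v
                    cnt += c
            frontier = (~valid) & (cnt > 0)
            if not frontier.any():
                raise ValueError("isolated masked region cannot be filled")
            arr[frontier] = acc[frontier] / cnt[frontier]
            valid |= frontier
    else:
        raise ValueError("fill must be 'value' or 'neighbour-mean'")
    return _rebuild(x, arr, x.geometry)


# ----------------------------------------------------------------------
# processor objects (parameters validated up front, then applied to data)

class _Processor:
    def __call__(self, data):
        raise NotImplementedError


class Normaliser(_Processor):
    def __init__(self, flat, dark, epsilon: float = 1e-6):
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.flat = flat
        self.dark = dark
        self.epsilon = epsilon

    def __call__(self, data):
        return normalise(data, self.flat, self.dark, self.epsilon)


class NegativeLog(_Processor):
    def __init__(self, clip_floor: float = 1e-6):
        if clip_floor <= 0:
            raise ValueError("clip_floor must be positive")
        self.clip_floor = clip_floor

    def __call__(self, data):
        return negative_log(data, self.clip_floor)


class Slicer(_Processor):
    def __init__(self, roi: dict):
        for label, rng in roi.items():
            if len(rng) != 3 or int(rng[2]) < 1:
                raise ValueError(f"roi for {label!r} must be (start, stop, step>=1)")
        self.roi = {k: tuple(int(v) for v in rng) for k, rng in roi.items()}

    def __call__(self, data):
        return slice_axes(data, self.roi)


class Binner(_Processor):
    def __init__(self, factors: dict):
        for label, f in factors.items():
            if int(f) < 1:
                raise ValueError(f"binning factor for {label!r} must be >= 1")
        self.factors = {k: int(v) for k, v in factors.items()}

    def __call__(self, data):
        return bin_axes(data, self.factors)


class Padder(_Processor):
    def __init__(self, widths: dict, mode: str = "constant", value: float = 0.0):
        if mode not in ("constant", "edge"):
            raise ValueError("mode must be 'constant' or 'edge'")
        self.widths = {k: (int(b), int(a)) for k, (b, a) in widths.items()}
        self.mode = mode
        self.value = value

    def __call__(self, data):
        return pad_axes(data, self.widths, self.mode, self.value)


class CentreOfRotationCorrector(_Processor):
    """Estimate the axis offset and store it in the output's geometry."""

    def __init__(self, angle_tolerance: float = 0.1):
        self.angle_tolerance = angle_tolerance

    def __call__(self, data):
        offset_px = find_centre_of_rotation(data, self.angle_tolerance)
        geometry = data.geometry.copy()
        geometry.rotation_axis_offset = offset_px * geometry.pixel_size_h
        return type(data)(data.as_array().copy(), geometry=geometry)


class MaskGenerator(_Processor):
    def __init__(self, method: str = "threshold", lo=-np.inf, hi=np.inf, quantile: float = 0.99):
        if method not in ("threshold", "quantile"):
            raise ValueError("method must be 'threshold' or 'quantile'")
        if method == "quantile" and not (0 < quantile <= 1):
            raise ValueError("quantile must lie in (0, 1]")
        self.method = method
        self.lo = lo
        self.hi = hi
        self.quantile = quantile

    def __call__(self, data):
        return make_mask(data, self.method, self.lo, self.hi, self.quantile)


class Masker(_Processor):
    def __init__(self, mask, fill: str = "value", value: float = 0.0):
        if fill not in ("value", "neighbour-mean"):
            raise ValueError("fill must be 'value' or 'neighbour-mean'")
        self.mask = mask
        self.fill = fill
        self.value = value

    def __call__(self, data):
        return apply_mask(data, self.mask, self.fill, self.value)


PROCESSOR_NAMES = {
    "normaliser": Normaliser,
    "negative_log": NegativeLog,
    "slicer": Slicer,
    "binner": Binner,
    "padder": Padder,
    "cor_corrector": CentreOfRotationCorrector,
    "mask_generator": MaskGenerator,
    "masker": Masker,
}


class ProcessorSpec:
    """Named processor + parameters; validates eagerly, serializes to dicts."""

    def __init__(self, name: str, parameters: dict | None = None):
        if name not in PROCESSOR_NAMES:
            raise ValueError(f"unknown processor {name!r}; expected one of "
                             f"{sorted(PROCESSOR_NAMES)}")
        self.name = name
        self.parameters = dict(parameters or {})
        self._processor = PROCESSOR_NAMES[name](**self.parameters)

    def build(self):
        return self._processor

    def __call__(self, data):
        return self._processor(data)

    def to_dict(self):
        return {"name": self.name, "parameters": self.parameters}

    @classmethod
    def from_dict(cls, d):
        return cls(d["name"], d.get("parameters"))
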