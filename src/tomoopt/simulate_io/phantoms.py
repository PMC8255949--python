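"""Synthetic phantoms with ground-truth records.

Three families:

``disc``
    Centred (or offset) uniform disc indicator.
``steel_wire_like``
    Low-value cylinder with a high-value eccentric wire and a few zero-value
    bubbles.
``rods``
    Cylinder carrying exactly 10 circular inserts — five materials in two
    sizes — of distinct values.

All values are dimensionless attenuation per unit length in [0, v_max]
(v_max defaults to 1) and every randomized choice is a pure function of the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datamodel import ImageData, ImageGeometry

__all__ = ["PhantomSpec", "make_phantom", "disc_phantom", "steel_wire_phantom", "rods_phantom"]

PHANTOM_KINDS = ("disc", "steel_wire_like", "rods")


@dataclass
class PhantomSpec:
    kind: str
    size: int = 128
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    v_max: float = 1.0

    def __post_init__(self):
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; expected {PHANTOM_KINDS}")
        if self.size < 4:
            raise ValueError("phantom size must be >= 4")
        if self.v_max <= 0:
            raise ValueError("v_max must be > 0")


def _grid(ig: ImageGeometry):
    ny, nx = ig.voxel_num_y, ig.voxel_num_x
    y = (np.arange(ny) - (ny - 1) / 2.0) * ig.voxel_size_y + ig.center_y
    x = (np.arange(nx) - (nx - 1) / 2.0) * ig.voxel_size_x + ig.center_x
    return np.meshgrid(y, x, indexing="ij")


def _disc_mask(Y, X, cy, cx, r):
    return (X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2


def disc_phantom(ig: ImageGeometry, radius: float | None = None, value: float = 1.0,
                 center=(0.0, 0.0), supersample: int = 4) -> tuple[ImageData, dict]:
    """Uniform disc; default radius 0.25 of the field of view.

    Boundary voxels hold the subpixel coverage fraction (``supersample``^2
    subsamples per voxel) so line integrals approximate the analytic disc.
    """
    fov = ig.voxel_num_x * ig.voxel_size_x
    if radius is None:
        radius = 0.25 * fov
    Y, X = _grid(ig)
    m = max(int(supersample), 1)
    offsets = (np.arange(m) + 0.5) / m - 0.5
    cover = np.zeros(Y.shape)
    for oy in offsets * ig.voxel_size_y:
        for ox in offsets * ig.voxel_size_x:
            cover += _disc_mask(Y + oy, X + ox, center[0], center[1], radius)
    arr = value * cover / (m * m)
    record = {"kind": "disc", "radius": radius, "value": value, "center": tuple(center)}
    return ImageData(arr.astype(np.float32), geometry=ig), record


def steel_wire_phantom(ig: ImageGeometry, seed: int = 0, cylinder_value: float = 0.045,
                       wire_value: float = 0.09, n_bubbles: int = 3) -> tuple[ImageData, dict]:
    """Low-attenuation cylinder + eccentric high-value wire + zero bubbles."""
    rng = np.random.default_rng(seed)
    fov = ig.voxel_num_x * ig.voxel_size_x
    r_cyl = 0.38 * fov
    Y, X = _grid(ig)
    arr = np.where(_disc_mask(Y, X, 0.0, 0.0, r_cyl), cylinder_value, 0.0)

    wire_r = 0.04 * fov
    wire_pos = 0.18 * fov
    wire_angle = rng.uniform(0, 2 * np.pi)
    wc = (wire_pos * np.sin(wire_angle), wire_pos * np.cos(wire_angle))
    arr[_disc_mask(Y, X, wc[0], wc[1], wire_r)] = wire_value

    bubbles = []
    for _ in range(n_bubbles):
        br = rng.uniform(0.02, 0.05) * fov
        rho = rng.uniform(0, r_cyl - br)
        phi = rng.uniform(0, 2 * np.pi)
        bc = (rho * np.sin(phi), rho * np.cos(phi))
        mask = _disc_mask(Y, X, bc[0], bc[1], br) & ~_disc_mask(Y, X, wc[0], wc[1], wire_r)
        arr[mask] = 0.0
        bubbles.append({"center": bc, "radius": br})
    record = {
        "kind": "steel_wire_like",
        "cylinder": {"radius": r_cyl, "value": cylinder_value},
        "wire": {"center": wc, "radius": wire_r, "value": wire_value},
        "bubbles": bubbles,
        "seed": seed,
    }
    return ImageData(arr.astype(np.float32), geometry=ig), record


def rods_phantom(ig: ImageGeometry, seed: int = 0, cylinder_value: float = 0.2,
                 v_max: float = 1.0) -> tuple[ImageData, dict]:
    """Cylinder with 10 circular inserts (5 materials x 2 sizes)."""
    rng = np.random.default_rng(seed)
    fov = ig.voxel_num_x * ig.voxel_size_x
    r_cyl = 0.42 * fov
    Y, X = _grid(ig)
    arr = np.where(_disc_mask(Y, X, 0.0, 0.0, r_cyl), cylinder_value, 0.0)

    values = np.linspace(0.35, 0.95, 5) * v_max
    big_r = 0.065 * fov
    small_r = 0.028 * fov
    inserts = []
    phase = rng.uniform(0, 2 * np.pi)
    for ring_radius, insert_r, offset in ((0.26 * fov, big_r, 0.0),
                                          (0.13 * fov, small_r, np.pi / 5)):
        for k in range(5):
            phi = phase + offset + 2 * np.pi * k / 5
            c = (ring_radius * np.sin(phi), ring_radius * np.cos(phi))
            if np.hypot(*c) + insert_r > r_cyl:
                raise ValueError("insert exceeds the cylinder")
            # slight value offset distinguishes the two sizes of one material
            value = float(values[k] * (1.0 if insert_r == big_r else 0.92))
            arr[_disc_mask(Y, X, c[0], c[1], insert_r)] = value
            inserts.append({"center": c, "radius": insert_r, "value": value})
    record = {
        "kind": "rods",
        "cylinder": {"radius": r_cyl, "value": cylinder_value},
        "inserts": inserts,
        "seed": seed,
    }
    return ImageData(arr.astype(np.float32), geometry=ig), record


def make_phantom(spec: PhantomSpec) -> tuple[ImageData, dict]:
    ig = ImageGeometry(voxel_num_x=spec.size, voxel_num_y=spec.size)
    params = dict(spec.parameters)
    if spec.kind == "disc":
        return disc_phantom(ig, **params)
    if spec.kind == "steel_wire_like":
        return steel_wire_phantom(ig, seed=spec.seed, **params)
    return rods_phantom(ig, seed=spec.seed, v_max=spec.v_max, **params)
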