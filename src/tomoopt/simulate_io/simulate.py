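"""Acquisition simulation (forward projection + noise) and golden angles."""

from __future__ import annotations

import numpy as np

from ..datamodel import AcquisitionData, AcquisitionGeometry, ImageData
from ..operators import ProjectionOperator

__all__ = ["simulate_acquisition", "generate_golden_angles", "GOLDEN_ANGLE_DEG"]

#: golden-ratio angular increment, (sqrt(5) - 1)/2 * 180 degrees
GOLDEN_ANGLE_DEG = (np.sqrt(5.0) - 1.0) / 2.0 * 180.0


def generate_golden_angles(n: int, start: float = 0.0) -> np.ndarray:
    """theta_k = (start + k * g) mod 360 with g = (sqrt(5)-1)/2 * 180 deg."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.mod(start + GOLDEN_ANGLE_DEG * np.arange(n), 360.0)


def simulate_acquisition(
    phantom: ImageData,
    acquisition_geometry: AcquisitionGeometry,
    noise: str = "none",
    sigma: float = 0.0,
    i0: float = 1e5,
    seed: int | None = None,
    zero_count_floor: float = 0.5,
) -> AcquisitionData:
    """Forward-project a phantom and corrupt the sinogram.

    ``noise``:

    * ``"none"`` — the exact forward projection;
    * ``"gaussian"`` — adds N(0, sigma) per bin;
    * ``"poisson"`` — draws counts ~ Pois(i0 * exp(-sinogram)) and converts
      back through -log(counts / i0), flooring zero counts at
      ``zero_count_floor`` counts before the log.

    A seed is mandatory for the noisy modes so runs are reproducible.
    """
    projector = ProjectionOperator(phantom.geometry, acquisition_geometry)
    sino = projector.direct(phantom)
    if noise == "none":
        return sino
    if seed is None:
        raise ValueError("a seed is required for noisy simulation")
    rng = np.random.default_rng(seed)
    arr = sino.as_array()
    if noise == "gaussian":
        noisy = arr + rng.normal(0.0, sigma, size=arr.shape)
    elif noise == "poisson":
        if i0 <= 0:
            raise ValueError("i0 must be > 0")
        counts = rng.poisson(i0 * np.exp(-arr)).astype(np.float64)
        counts = np.maximum(counts, zero_count_floor)
        noisy = -np.log(counts / i0)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return sino.clone_with(noisy)
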