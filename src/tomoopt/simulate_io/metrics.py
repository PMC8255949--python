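"""Image quality metrics against a ground truth."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["mse", "psnr", "quality_report", "QualityReport"]


def _arrays(a, b):
    aa = np.asarray(a.as_array() if hasattr(a, "as_array") else a, dtype=np.float64)
    bb = np.asarray(b.as_array() if hasattr(b, "as_array") else b, dtype=np.float64)
    if aa.shape != bb.shape:
        raise ValueError(f"shape mismatch: {aa.shape} vs {bb.shape}")
    return aa, bb


def mse(a, b) -> float:
    aa, bb = _arrays(a, b)
    return float(np.mean((aa - bb) ** 2))


def psnr(a, ground_truth, data_range: float | None = None) -> float:
    """20 log10(range) - 10 log10(mse); +inf for identical inputs.

    ``data_range`` defaults to the maximum of the ground truth.
    """
    aa, bb = _arrays(a, ground_truth)
    if data_range is None:
        data_range = float(np.max(bb))
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    err = float(np.mean((aa - bb) ** 2))
    if err == 0:
        return math.inf
    return 20.0 * math.log10(data_range) - 10.0 * math.log10(err)


@dataclass
class QualityReport:
    mse: float
    psnr: float


def quality_report(a, ground_truth, data_range: float | None = None) -> QualityReport:
    return QualityReport(mse=mse(a, ground_truth),
                         psnr=psnr(a, ground_truth, data_range))
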