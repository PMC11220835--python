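"""Agreement scores between an algorithmic TFR and the ground truth.

Three root-mean-square-error formulations (per-row "spectral", per-column
"temporal", and element-wise "total") plus the structural similarity index
computed on the TFR matrices treated as greyscale images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from ._errors import InputError, ParameterError
from .tfr_engines import TFRMatrix

__all__ = [
    "ScoreTable",
    "spectral_rmse",
    "temporal_rmse",
    "total_rmse",
    "ssi",
    "percent_difference",
]


@dataclass(frozen=True)
class ScoreTable:
    """Per-method record of the four agreement scores."""

    method: str
    spectral_rmse: float
    temporal_rmse: float
    total_rmse: float
    ssi: float


def _aligned(a: TFRMatrix, g: TFRMatrix) -> tuple[np.ndarray, np.ndarray]:
    if a.values.shape != g.values.shape:
        raise InputError(
            f"shape mismatch: {a.values.shape} vs {g.values.shape}"
        )
    return np.asarray(a.values, float), np.asarray(g.values, float)


def spectral_rmse(a: TFRMatrix, g: TFRMatrix) -> float:
    """Mean over frequency rows of the per-row RMSE."""
    av, gv = _aligned(a, g)
    return float(np.mean(np.sqrt(np.mean((av - gv) ** 2, axis=1))))


def temporal_rmse(a: TFRMatrix, g: TFRMatrix) -> float:
    """Mean over time columns of the per-column RMSE."""
    av, gv = _aligned(a, g)
    return float(np.mean(np.sqrt(np.mean((av - gv) ** 2, axis=0))))


def total_rmse(a: TFRMatrix, g: TFRMatrix) -> float:
    """RMSE over all matrix elements."""
    av, gv = _aligned(a, g)
    return float(np.sqrt(np.mean((av - gv) ** 2)))


def ssi(
    a: TFRMatrix,
    g: TFRMatrix,
    win_size: int = 11,
    sigma: float = 1.5,
    data_range: float = 1.0,
) -> float:
    """Mean structural similarity of the two TFRs as greyscale images.

    Uses the canonical Gaussian-weighted window (11x11, sigma 1.5) and
    stabilisers C1 = (0.01 L)^2, C2 = (0.03 L)^2 with dynamic range L = 1,
    matching the Wang et al. reference formulation.
    """
    av, gv = _aligned(a, g)
    return float(
        structural_similarity(
            av,
            gv,
            win_size=win_size,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


def percent_difference(a: float, b: float) -> float:
    """Symmetric percentage difference: 100 |a-b| / mean(a, b)."""
    if a <= 0 or b <= 0:
        raise ParameterError("percent_difference needs positive inputs")
    return 100.0 * abs(a - b) / ((a + b) / 2.0)
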