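"""Imaging quantification arithmetic for the validation experiments.

Percent-positive-area of a fluorescence channel after rolling-ball background
subtraction, volume fractions of boolean label masks (the vessel- and
Gfap-occupancy computations), and the adaptive two-stage FDR used with
families of t tests.
"""

from __future__ import annotations

import numpy as np
from skimage.restoration import rolling_ball

from .matrix import ValidationError
from .stats import MultiTestResult, bky_two_stage, multiple_t_tests  # noqa: F401

__all__ = [
    "percent_positive_area",
    "volume_fraction",
    "bky_two_stage",
    "multiple_t_tests",
    "MultiTestResult",
]


def percent_positive_area(
    img: np.ndarray,
    threshold: float,
    rolling_ball_radius: float = 25.0,
    roi: np.ndarray | None = None,
) -> float:
    """Percent of ROI pixels above threshold after background subtraction.

    Background is estimated with a rolling-ball (grayscale opening with a ball
    structuring element) of the given radius and subtracted, clipping at 0;
    a radius <= 0 (or None) skips the background step. The ROI defaults to the
    full frame.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValidationError("expected a 2D image plane")
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if not np.isfinite(img).all():
        raise ValidationError("image intensities must be finite")
    if rolling_ball_radius is not None and rolling_ball_radius > 0:
        background = rolling_ball(img, radius=rolling_ball_radius)
        img = np.clip(img - background, 0.0, None)
    if roi is None:
        roi = np.ones(img.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != img.shape:
        raise ValidationError("ROI shape mismatch")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValidationError("empty ROI")
    return 100.0 * float((img[roi] > threshold).sum()) / n_roi


def volume_fraction(
    mask: np.ndarray,
    roi: np.ndarray | None = None,
    voxel_size=None,
) -> float:
    """Percent of ROI volume occupied by the boolean mask.

    ``100 * (true voxels * voxel volume) / (ROI voxels * voxel volume)``; the
    voxel volume cancels, so anisotropic voxel dimensions are accepted but do
    not change the result.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValidationError("empty mask")
    if roi is None:
        roi = np.ones(mask.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != mask.shape:
        raise ValidationError("ROI shape mismatch")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValidationError("zero ROI volume")
    return 100.0 * float((mask & roi).sum()) / n_roi
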