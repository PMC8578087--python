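"""Vessel segmentation and OCT angiography.

Segmentation follows the semi-automated scheme used across modalities:
per-modality intensity thresholding (Otsu or a fixed value) followed by
binary morphological cleanup.  Manual correction is replaced by an
accept-external-mask pathway — any :class:`~vasculink.io_formats.BinaryMask`
file can be substituted at any stage of the pipeline.

OCT angiograms (OCTA) separate moving blood from static tissue by
differencing consecutive B-scans acquired at the same position: static
structures (DC) cancel, decorrelating flow (AC) survives.  The statistic is
the pixel-wise mean absolute difference over consecutive frame pairs,
followed by Gaussian smoothing and thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .io_formats import BinaryMask, ImageVolume

__all__ = [
    "BScanSeries",
    "threshold_segment",
    "morphological_cleanup",
    "octa_angiogram",
    "dice_coefficient",
]


@dataclass
class BScanSeries:
    """Repeated 2D B-scans acquired at the same position."""

    frames: np.ndarray                       # (n_frames, H, W)
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if len(self.frames) < 2:
            raise ValueError("a B-scan series needs at least 2 frames")


def threshold_segment(
    vol: ImageVolume,
    method: str = "otsu",
    threshold: float | None = None,
) -> BinaryMask:
    """Binary vessel mask by intensity thresholding.

    Foreground = voxels strictly above the threshold.  ``method='otsu'``
    computes the threshold from the full-volume 256-bin histogram;
    ``method='fixed'`` requires ``threshold``.
    """
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        t = float(threshold)
    elif method == "otsu":
        data = vol.voxels
        if float(data.min()) == float(data.max()):
            raise ValueError("constant volume: Otsu threshold is undefined (degenerate histogram)")
        t = float(threshold_otsu(data, nbins=256))
    else:
        raise ValueError(f"unknown method {method!r}; use 'otsu' or 'fixed'")
    return BinaryMask((vol.voxels > t).astype(np.uint8), vol.spacing, vol.origin)


def morphological_cleanup(
    mask: BinaryMask,
    min_component_voxels: int = 0,
    closing_radius_voxels: int = 0,
) -> BinaryMask:
    """Binary closing then small-component removal (26-connectivity).

    Closing with a ball of the given radius bridges gaps smaller than the
    structuring element; components below ``min_component_voxels`` are then
    dropped.  Radius/min-size of 0 are no-ops.
    """
    if min_component_voxels < 0 or closing_radius_voxels < 0:
        raise ValueError("cleanup parameters must be >= 0")
    data = mask.voxels.astype(bool)
    if closing_radius_voxels > 0:
        data = ndimage.binary_closing(data, structure=ball(closing_radius_voxels))
    if min_component_voxels > 0:
        labels = measure.label(data, connectivity=3)
        counts = np.bincount(labels.ravel())
        keep = counts >= min_component_voxels
        keep[0] = False
        data = keep[labels]
    return mask.like(data.astype(np.uint8))


def octa_angiogram(
    series: BScanSeries | np.ndarray,
    gaussian_sigma: float = 0.0,
    threshold: float = 0.0,
    statistic: str = "mean_abs",
) -> np.ndarray:
    """2D angiogram from repeated B-scans by consecutive-frame differencing.

    ``statistic`` selects the temporal contrast: ``mean_abs`` (default) is
    the mean absolute consecutive difference; ``signed`` the mean signed
    difference; ``squared`` the mean squared difference.  The result is
    Gaussian-smoothed (``gaussian_sigma`` pixels) and values at or below
    ``threshold`` are zeroed to suppress residual static tissue.
    """
    frames = series.frames if isinstance(series, BScanSeries) else np.asarray(series, dtype=float)
    if frames.ndim != 3 or len(frames) < 2:
        raise ValueError("need a (n_frames >= 2, H, W) series")
    diffs = np.diff(frames, axis=0)
    if statistic == "mean_abs":
        ang = np.abs(diffs).mean(axis=0)
    elif statistic == "signed":
        ang = diffs.mean(axis=0)
    elif statistic == "squared":
        ang = (diffs**2).mean(axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if gaussian_sigma > 0:
        ang = ndimage.gaussian_filter(ang, sigma=gaussian_sigma)
    ang = np.where(ang > threshold, ang, 0.0)
    return ang


def dice_coefficient(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    va = (a.voxels if isinstance(a, ImageVolume) else np.asarray(a)).astype(bool)
    vb = (b.voxels if isinstance(b, ImageVolume) else np.asarray(b)).astype(bool)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    denom = va.sum() + vb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(va, vb).sum() / denom)
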