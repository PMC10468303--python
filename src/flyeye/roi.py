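"""Micrograph preprocessing and region-of-interest selection.

The eye sits in a roughly elliptical region of the micrograph; only
ommatidia near the focal plane reflect light as tight bright facets.  The
ROI procedure exploits this: a white top-hat transform flattens the
illumination background, bright pixels are detected, pixels far from the
bright-pixel centroid (beyond the 0.8 distance quantile) are discarded, and
a confidence ellipse fitted to the surviving pixels becomes the ROI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import morphology
from skimage.filters import threshold_otsu

__all__ = [
    "PixelSet",
    "ROIEllipse",
    "preprocess",
    "detect_bright_pixels",
    "prune_by_centroid_distance",
    "fit_confidence_ellipse",
    "mask_to_roi",
]

# ITU-R BT.709 luminance weights for colour input
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class PixelSet:
    """Integer pixel coordinates selected from an image."""

    coordinates: np.ndarray  # (n, 2) int (row, col)
    source_image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass
class ROIEllipse:
    """Confidence ellipse over pixel coordinates.

    ``semi_axes`` are (a, b) with a >= b, in pixels; ``orientation`` is the
    major-axis angle in radians within [0, pi), measured from the row axis
    toward the column axis.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float
    confidence_level: float = 0.95

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for (n, 2) (row, col) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        u = pts[:, 0] * c + pts[:, 1] * s
        v = -pts[:, 0] * s + pts[:, 1] * c
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def to_dict(self) -> dict:
        return {
            "center": [float(self.center[0]), float(self.center[1])],
            "semi_axes": [float(self.semi_axes[0]), float(self.semi_axes[1])],
            "orientation": float(self.orientation),
            "confidence_level": float(self.confidence_level),
        }


def preprocess(raw_image: np.ndarray, structuring_radius: int = 10) -> np.ndarray:
    """Grayscale conversion followed by a white top-hat transform.

    Colour images are collapsed with standard luminance weights.  The white
    top-hat (image minus its morphological opening with a disk of the given
    radius) suppresses any background structure wider than the element while
    preserving bright blobs smaller than it.  Output is float in [0, 1]; a
    flat image maps to all zeros.
    """
    img = np.asarray(raw_image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        if img.shape[2] != 3:
            raise ValueError("colour input must have 3 channels")
        img = img @ _LUMA
    elif img.ndim != 2:
        raise ValueError("image must be 2-D grayscale or 3-channel colour")
    if structuring_radius < 1:
        raise ValueError("structuring_radius must be >= 1")

    # normalise integer inputs to [0, 1]
    if img.max() > 1.0:
        img = img / img.max()
    out = morphology.white_tophat(img, morphology.disk(int(structuring_radius)))
    return np.clip(out, 0.0, 1.0)


def detect_bright_pixels(
    img: np.ndarray, threshold_rule: str | float = "otsu"
) -> PixelSet:
    """Pixels whose intensity exceeds the configured threshold.

    ``threshold_rule`` is ``"otsu"`` (default) or a float in (0, 1)
    interpreted as an intensity quantile.  A flat image yields an empty set
    with a warning.
    """
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        warnings.warn("flat image: no bright pixels detected", stacklevel=2)
        return PixelSet(np.empty((0, 2), dtype=int), img.shape)
    if threshold_rule == "otsu":
        thr = threshold_otsu(img)
    else:
        q = float(threshold_rule)
        if not 0.0 < q < 1.0:
            raise ValueError("quantile threshold must lie in (0, 1)")
        thr = np.quantile(img, q)
    coords = np.argwhere(img > thr)
    return PixelSet(coords, img.shape)


def prune_by_centroid_distance(pixels: PixelSet, q: float = 0.8) -> PixelSet:
    """Discard pixels farther from the set centroid than the q-quantile.

    The quantile uses linear interpolation between order statistics, and
    ties at the quantile are retained (distance <= quantile survives).
    """
    if len(pixels) == 0:
        raise ValueError("cannot prune an empty pixel set")
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    coords = pixels.coordinates.astype(float)
    centroid = coords.mean(axis=0)
    dist = np.linalg.norm(coords - centroid, axis=1)
    cutoff = np.quantile(dist, q)  # linear interpolation (default)
    keep = dist <= cutoff
    return PixelSet(pixels.coordinates[keep], pixels.source_image_shape)


def fit_confidence_ellipse(pixels: PixelSet, level: float = 0.95) -> ROIEllipse:
    """Confidence ellipse from the mean and covariance of pixel coordinates.

    Semi-axes are the covariance eigenvalue square roots scaled by the
    chi-square(2) quantile at ``level``.  Degenerate (collinear) pixel sets
    raise a rank-deficiency error.
    """
    if len(pixels) < 3:
        raise ValueError("need at least 3 pixels to fit an ellipse")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    coords = pixels.coordinates.astype(float)
    center = coords.mean(axis=0)
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise ValueError("rank-deficient pixel covariance (collinear pixels)")
    scale = stats.chi2.ppf(level, df=2)
    a = math.sqrt(evals[1] * scale)
    b = math.sqrt(evals[0] * scale)
    major = evecs[:, 1]
    theta = math.atan2(major[1], major[0]) % math.pi
    return ROIEllipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(a, b),
        orientation=theta,
        confidence_level=level,
    )


def mask_to_roi(img: np.ndarray, roi: ROIEllipse) -> np.ndarray:
    """Zero out pixels outside the ROI ellipse; inside is unchanged."""
    img = np.asarray(img, dtype=float)
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    inside = roi.contains(pts).reshape(img.shape)
    out = img.copy()
    out[~inside] = 0.0
    return out
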