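"""Focus criterion functions and focus-curve diagnostics.

A focus criterion function maps an image to a scalar sharpness score that
peaks when the specimen is in focus.  Three candidates suited to bright-field
micrographs of roughly spherical embryos on a clean background are provided:

* the Brenner gradient — squared intensity differences between pixels two
  columns apart (horizontal direction only);
* the Tenengrad — squared magnitude of the horizontal and vertical Sobel
  responses;
* the normalized variance — squared deviations from the mean intensity,
  divided by the mean.

All three are computed over the pixels whose operands lie entirely inside the
image (no padding), accumulate in float64, and are invariant to adding a
constant intensity (Brenner/Tenengrad) or to the image's DC level only through
the mean (normalized variance).  ``compute_focus_curve`` evaluates a measure
across a z-stack and ``curve_fwhm`` quantifies peak narrowness as the full
width at half maximum of a normalized curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "FocusCurve",
    "FocusStack",
    "brenner_score",
    "tenengrad_score",
    "normalized_variance_score",
    "FOCUS_MEASURES",
    "compute_focus_curve",
    "curve_fwhm",
    "OpenWidthError",
]

# standard 3x3 Sobel stencils; S_x responds to horizontal intensity change
_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


class OpenWidthError(ValueError):
    """Raised when a focus curve never drops below half maximum on one side."""


def _as_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        # convenience path: collapse color to 8-bit luminance (ITU-R 601)
        img = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    return img.astype(np.float64, copy=False)


def brenner_score(img: np.ndarray) -> float:
    """Brenner gradient: sum over pixels of ``[I(x+2, y) - I(x, y)]**2``.

    ``x`` indexes columns; only the horizontal direction is used.  The sum
    runs over pixels for which column ``x + 2`` exists, so the last two
    columns contribute only as right-hand operands.

    Parameters
    ----------
    img : ndarray
        2-D intensity raster with at least 3 columns.
    """
    a = _as_float(img)
    if a.shape[1] < 3:
        raise ValueError("Brenner gradient needs an image at least 3 columns wide")
    d = a[:, 2:] - a[:, :-2]
    return float(np.sum(d * d))


def tenengrad_score(img: np.ndarray) -> float:
    """Tenengrad: sum of squared Sobel gradient magnitudes ``Sx**2 + Sy**2``.

    Summation covers only pixels where the full 3x3 Sobel window fits inside
    the image, so a constant border never contributes.
    """
    a = _as_float(img)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("Tenengrad needs an image of at least 3x3 pixels")
    sx = convolve2d(a, _SOBEL_X, mode="valid")
    sy = convolve2d(a, _SOBEL_Y, mode="valid")
    return float(np.sum(sx * sx + sy * sy))


def normalized_variance_score(img: np.ndarray) -> float:
    """Normalized variance: ``(1/mu) * sum((I - mu)**2)`` with ``mu`` the mean.

    The sum of squared deviations is divided by the mean intensity only — not
    by the pixel count — so the score scales with image area.  Only relative
    values along a stack matter for focusing, where the area is constant.
    """
    a = _as_float(img)
    mu = float(a.mean())
    if mu <= 0:
        raise ValueError("normalized variance is undefined for an all-zero image")
    d = a - mu
    return float(np.sum(d * d) / mu)


FOCUS_MEASURES: dict[str, Callable[[np.ndarray], float]] = {
    "brenner": brenner_score,
    "tenengrad": tenengrad_score,
    "normalized_variance": normalized_variance_score,
}


@dataclass(frozen=True)
class FocusCurve:
    """Sharpness scores sampled along the optical axis.

    Attributes
    ----------
    z_positions : tuple of float
        Strictly increasing stage positions, micrometres.
    scores : tuple of float
        Non-negative sharpness scores, one per position.
    normalized : bool
        True if the scores have been divided by their maximum.
    """

    z_positions: tuple[float, ...]
    scores: tuple[float, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.z_positions) != len(self.scores):
            raise ValueError("z_positions and scores must have equal length")
        if len(self.z_positions) == 0:
            raise ValueError("focus curve cannot be empty")
        z = np.asarray(self.z_positions)
        if len(z) > 1 and not np.all(np.diff(z) > 0):
            raise ValueError("z_positions must be strictly increasing")

    @property
    def peak_z(self) -> float:
        """Stage position of the global score maximum (first on ties)."""
        return self.z_positions[int(np.argmax(self.scores))]


@dataclass(frozen=True)
class FocusStack:
    """An ordered list of ``(z_position, image)`` frames of equal shape."""

    z_positions: tuple[float, ...]
    images: tuple[np.ndarray, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.z_positions) != len(self.images):
            raise ValueError("one image per z position required")
        if len(self.images) == 0:
            raise ValueError("a focus stack needs at least one frame")
        z = np.asarray(self.z_positions)
        if len(z) > 1 and not np.all(np.diff(z) > 0):
            raise ValueError("z_positions must be strictly increasing")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError(f"all frames must share dimensions, got {shapes}")

    def __len__(self) -> int:
        return len(self.images)


def compute_focus_curve(
    stack: FocusStack,
    measure: str = "brenner",
    normalize: bool = False,
) -> FocusCurve:
    """Score every frame of a z-stack with the selected focus measure.

    Parameters
    ----------
    stack : FocusStack
        Non-empty z-stack.
    measure : {"brenner", "tenengrad", "normalized_variance"}
    normalize : bool
        If True, divide all scores by the curve maximum so the peak is 1.
    """
    if measure not in FOCUS_MEASURES:
        raise ValueError(f"unknown focus measure {measure!r}")
    if len(stack) == 0:
        raise ValueError("cannot score an empty stack")
    fn = FOCUS_MEASURES[measure]
    scores = np.array([fn(im) for im in stack.images], dtype=np.float64)
    if normalize:
        peak = scores.max()
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero focus curve")
        scores = scores / peak
    return FocusCurve(tuple(stack.z_positions), tuple(scores), normalized=normalize)


def curve_fwhm(curve: FocusCurve) -> float:
    """Full width at half maximum of a normalized, unimodal focus curve.

    Walks outward from the global maximum to the first samples falling below
    0.5 on each side and linearly interpolates the two half-maximum crossings.
    A narrow FWHM indicates a sharply peaked criterion function, which makes
    the focal plane easier to pinpoint.

    Raises
    ------
    OpenWidthError
        If the curve never drops below half maximum on either side, so the
        width is not bracketed by the sampled range.
    """
    if not curve.normalized:
        raise ValueError("curve must be normalized before measuring FWHM")
    z = np.asarray(curve.z_positions, dtype=np.float64)
    s = np.asarray(curve.scores, dtype=np.float64)
    k = int(np.argmax(s))
    half = 0.5 * s[k]

    def _cross(idx_from: int, step: int) -> float:
        i = idx_from
        while 0 <= i + step < len(s):
            j = i + step
            if s[j] < half:
                # linear interpolation between samples i (>= half) and j (< half)
                t = (half - s[i]) / (s[j] - s[i])
                return float(z[i] + t * (z[j] - z[i]))
            i = j
        raise OpenWidthError(
            "focus curve does not fall below half maximum within the sampled range"
        )

    left = _cross(k, -1)
    right = _cross(k, +1)
    return right - left
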