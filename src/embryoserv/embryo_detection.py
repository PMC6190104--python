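"""Embryo localization under uneven illumination.

A global threshold (Otsu) separates a bright-field embryo from its background
only when the illumination is even; a shadowed or tilted light field shifts
local intensity enough that any single threshold breaks the membrane contour
or merges it with the background.  The adaptive threshold used here compares
each pixel against the weighted mean of its own ``b x b`` neighbourhood minus
an offset ``param1``:

    T(i, j) = A(i, j) - param1,    output = 255 if S(i, j) > T(i, j) else 0

which cancels smooth illumination gradients by construction.  The block size
``b`` and offset ``param1`` are not known a priori — they depend on how
uneven the field is — so :func:`detect_embryo` circulates over candidate
``(b, param1)`` pairs, extracting the largest closed dark contour and fitting
a least-squares ellipse for each, until the fitted major axis ``L`` lands in
a plausibility band for an embryo at the working magnification.

Coordinates are 0-based with ``x`` = column and ``y`` = row; centres are
sub-pixel reals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import EllipseModel

__all__ = [
    "AdaptiveThresholdParams",
    "EllipseFit",
    "DetectionConfig",
    "EmbryoDetection",
    "ContourNotFound",
    "local_weighted_mean",
    "adaptive_threshold",
    "otsu_global_threshold",
    "largest_closed_contour",
    "fit_ellipse_lsq",
    "detect_embryo",
    "detect_embryo_global_otsu",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class ContourNotFound(ValueError):
    """No closed dark contour with enough points exists in the mask."""


@dataclass(frozen=True)
class AdaptiveThresholdParams:
    """Block size ``b`` (odd, >= 3), offset ``param1`` (>= 0), and weighting."""

    b: int
    param1: float
    weighting: str = "gaussian"

    def __post_init__(self) -> None:
        if self.b < 3 or self.b % 2 == 0:
            raise ValueError("block size b must be odd and >= 3")
        if self.param1 < 0:
            raise ValueError("param1 must be non-negative")
        if self.weighting not in ("gaussian", "uniform"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class EllipseFit:
    """Fitted ellipse: centre (x, y), full axis lengths, orientation."""

    center: tuple[float, float]
    major_axis_length: float
    minor_axis_length: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not self.major_axis_length >= self.minor_axis_length > 0:
            raise ValueError("need major >= minor > 0")


@dataclass(frozen=True)
class DetectionConfig:
    """Search space and acceptance band for the parameter circulation.

    ``b_range`` is tried outer and ascending, ``param1_range`` inner and
    ascending; the first combination whose fitted major axis lies in
    ``[L_min, L_max]`` wins.  When the band is left at None it defaults to
    [0.45, 0.95] x the shorter image dimension — an embryo fills a large
    fraction of the field at injection magnification.
    """

    b_range: tuple[int, ...] = (9, 13, 19, 25, 31, 39)
    param1_range: tuple[float, ...] = (5.0, 7.0)
    L_min: float | None = None
    L_max: float | None = None
    min_contour_points: int = 40
    weighting: str = "gaussian"

    def band(self, shape: tuple[int, int]) -> tuple[float, float]:
        short = min(shape)
        lo = 0.45 * short if self.L_min is None else self.L_min
        hi = 0.95 * short if self.L_max is None else self.L_max
        if not lo < hi:
            raise ValueError("need L_min < L_max")
        return lo, hi


@dataclass(frozen=True)
class EmbryoDetection:
    """Outcome of the circulation: ellipse, winning (b, param1), acceptance."""

    ellipse: EllipseFit | None
    params_used: tuple[int, float] | None
    accepted: bool
    n_combinations_tried: int


def _check_b(img_shape: tuple[int, int], b: int) -> None:
    if b % 2 == 0 or b < 3:
        raise ValueError("block size b must be odd and >= 3")
    if b > min(img_shape):
        raise ValueError(f"block size {b} exceeds image extent {img_shape}")


def local_weighted_mean(img: np.ndarray, b: int, weighting: str = "gaussian") -> np.ndarray:
    """Weighted mean of each pixel's b x b neighbourhood, replicate borders.

    ``uniform`` weighting is the plain box mean.  ``gaussian`` weights the
    neighbourhood with a Gaussian whose sigma follows the usual block-size
    convention ``sigma = 0.3 * ((b - 1) / 2 - 1) + 0.8``, truncated to the
    block.  Returns a float64 raster the same shape as the input.
    """
    a = np.asarray(img, dtype=np.float64)
    _check_b(a.shape, b)
    if weighting == "uniform":
        return ndimage.uniform_filter(a, size=b, mode="nearest")
    if weighting == "gaussian":
        sigma = 0.3 * ((b - 1) * 0.5 - 1.0) + 0.8
        radius = (b - 1) // 2
        return ndimage.gaussian_filter(a, sigma=sigma, mode="nearest", radius=radius)
    raise ValueError(f"unknown weighting {weighting!r}")


def adaptive_threshold(img: np.ndarray, params: AdaptiveThresholdParams) -> np.ndarray:
    """Binarize against the local mean: 255 where S > A - param1, else 0."""
    a = np.asarray(img, dtype=np.float64)
    A = local_weighted_mean(a, params.b, params.weighting)
    out = np.where(a > A - params.param1, 255, 0).astype(np.uint8)
    return out


def otsu_global_threshold(img: np.ndarray) -> np.ndarray:
    """Single global threshold maximizing between-class variance.

    Same 0/255 encoding as :func:`adaptive_threshold`: pixels above the
    threshold map to 255.  Serves as the non-adaptive baseline that fails
    under uneven illumination.
    """
    a = np.asarray(img)
    if a.min() == a.max():
        raise ValueError("Otsu threshold is undefined for a constant image")
    t = threshold_otsu(a.astype(np.uint8))
    return np.where(a > t, 255, 0).astype(np.uint8)


def largest_closed_contour(binmask: np.ndarray, min_points: int = 40) -> np.ndarray:
    """Boundary points of the largest closed dark region, as (x, y) pairs.

    Dark (0-valued) pixels are first closed morphologically (3x3, one
    iteration) so single-pixel noise breaks cannot sever a thin boundary,
    then grouped into 8-connected components.  A component touching the
    image border cannot form a closed contour (the
    pipette shaft and shadowed corners always run off the frame, the embryo
    never does) and is excluded.  Each remaining component is hole-filled so
    its boundary is the outer contour only; the component with the most
    boundary pixels wins, provided it has at least ``min_points`` of them.

    Returns an ``(N, 2)`` float array of (x, y) boundary pixel coordinates.

    Raises
    ------
    ContourNotFound
        If no interior dark component has ``min_points`` boundary pixels.
    """
    mask = np.asarray(binmask) == 0
    # edge-replicated padding keeps border-touching regions attached to the
    # border through the closing (the dilation step would otherwise erode them)
    padded = ndimage.binary_closing(np.pad(mask, 1, mode="edge"),
                                    structure=_EIGHT_CONNECTED)
    mask = padded[1:-1, 1:-1]
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    if n == 0:
        raise ContourNotFound("mask contains no dark pixels")
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border])) - {0}

    best_pts: np.ndarray | None = None
    # examine components from largest area down; a component's boundary can
    # never have more pixels than its area, so stop once the best boundary
    # found already beats every remaining component's area
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    objects = ndimage.find_objects(labels)
    for lab in (np.argsort(areas)[::-1] + 1):
        area = areas[lab - 1]
        if area < min_points or (best_pts is not None and area <= len(best_pts)):
            break
        if lab in border_labels:
            continue
        sl = objects[lab - 1]
        comp = ndimage.binary_fill_holes(labels[sl] == lab)
        boundary = comp & ~ndimage.binary_erosion(comp, structure=_EIGHT_CONNECTED)
        ys, xs = np.nonzero(boundary)
        if len(xs) >= min_points and (best_pts is None or len(xs) > len(best_pts)):
            best_pts = np.column_stack(
                [xs + sl[1].start, ys + sl[0].start]
            ).astype(np.float64)
    if best_pts is None:
        raise ContourNotFound(f"no closed dark contour with >= {min_points} points")
    return best_pts


def fit_ellipse_lsq(points: np.ndarray) -> EllipseFit:
    """Direct algebraic least-squares ellipse fit to (x, y) points.

    Minimizes the algebraic distance of the points to a conic constrained to
    be an ellipse, then converts to geometric parameters.  Requires at least
    5 points in a non-degenerate configuration.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("ellipse fitting needs >= 5 (x, y) points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("degenerate point configuration: points are collinear")
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model or not np.all(np.isfinite([*model.center, *model.axis_lengths])):
            raise ValueError("degenerate point configuration: ellipse fit failed")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(pts) or not np.all(np.isfinite(model.params)):
            raise ValueError("degenerate point configuration: ellipse fit failed")
        xc, yc, a, b, theta = model.params
    if a <= 0 or b <= 0:
        raise ValueError("degenerate ellipse fit (non-positive axis)")
    major, minor = (a, b) if a >= b else (b, a)
    angle = np.rad2deg(theta if a >= b else theta + np.pi / 2.0)
    angle = float(angle % 180.0)
    return EllipseFit(
        center=(float(xc), float(yc)),
        major_axis_length=2.0 * major,
        minor_axis_length=2.0 * minor,
        angle_deg=angle,
    )


def detect_embryo(img: np.ndarray, config: DetectionConfig = DetectionConfig()) -> EmbryoDetection:
    """Locate the embryo by circulating over adaptive-threshold parameters.

    For each ``b`` (ascending) and ``param1`` (ascending, inner loop):
    adaptive threshold -> largest closed dark contour -> least-squares
    ellipse.  The first combination whose major axis ``L`` lies in the
    acceptance band is returned with ``accepted=True``.  If no combination
    qualifies, ``accepted=False`` is returned with the fit whose ``L`` came
    closest to the band (when any fit succeeded at all), for diagnostics.
    Deterministic: a fixed image and config always select the same pair.
    """
    a = np.asarray(img)
    lo, hi = config.band(a.shape)
    tried = 0
    best: tuple[float, EllipseFit, tuple[int, float]] | None = None
    for b in config.b_range:
        if b > min(a.shape):
            continue
        for p1 in config.param1_range:
            tried += 1
            try:
                mask = adaptive_threshold(a, AdaptiveThresholdParams(b, p1, config.weighting))
                pts = largest_closed_contour(mask, config.min_contour_points)
                fit = fit_ellipse_lsq(pts)
            except (ContourNotFound, ValueError):
                continue
            L = fit.major_axis_length
            if lo <= L <= hi:
                return EmbryoDetection(fit, (b, p1), accepted=True, n_combinations_tried=tried)
            dist = max(lo - L, L - hi, 0.0)
            if best is None or dist < best[0]:
                best = (dist, fit, (b, p1))
    if best is None:
        return EmbryoDetection(None, None, accepted=False, n_combinations_tried=tried)
    return EmbryoDetection(best[1], best[2], accepted=False, n_combinations_tried=tried)


def detect_embryo_global_otsu(
    img: np.ndarray, config: DetectionConfig = DetectionConfig()
) -> EmbryoDetection:
    """Baseline detector: global Otsu binarization instead of the adaptive map.

    Shares the contour/ellipse stages and acceptance band with
    :func:`detect_embryo`, isolating the thresholding step as the only
    difference.  Under even illumination it agrees with the adaptive route;
    under a strong gradient the single global threshold merges the embryo
    with shadowed background or shatters its contour, and detection fails.
    """
    a = np.asarray(img)
    lo, hi = config.band(a.shape)
    try:
        mask = otsu_global_threshold(a)
        pts = largest_closed_contour(mask, config.min_contour_points)
        fit = fit_ellipse_lsq(pts)
    except (ContourNotFound, ValueError):
        return EmbryoDetection(None, None, accepted=False, n_combinations_tried=1)
    ok = lo <= fit.major_axis_length <= hi
    return EmbryoDetection(fit, None, accepted=ok, n_combinations_tried=1)
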