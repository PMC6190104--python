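"""Pipette-tip localization by template matching.

The injection pipette is rigid and its orientation under the camera is fixed,
so a single template of the tip region suffices.  Matching minimizes the
sum-of-squared-deviations (SSD) between the template and each image window;
expanding the square shows that for a fixed template the cross-correlation
term carries all the position information, and normalizing it by the window
energy,

    M(i, j) = sum(g * f) / sqrt(sum(f ** 2)),

makes the argmax invariant to multiplicative illumination changes.  The
template is stored together with the pixel offsets ``(L, H)`` from its origin
(top-left corner) to the needle tip, so a match at origin ``(i, j)`` (row,
column) yields the tip directly: ``tip_x = j + L``, ``tip_y = i + H``.

The search scans every valid origin in row-major order and keeps the first
origin attaining the maximum, i.e. ties break toward the earliest window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate2d

__all__ = [
    "TipTemplate",
    "MatchResult",
    "make_template",
    "ssd_score",
    "normalized_match",
    "locate_template",
    "locate_tip",
]


@dataclass(frozen=True)
class TipTemplate:
    """A template patch plus the offsets from its origin to the needle tip.

    ``offset_L`` is the horizontal (column) displacement and ``offset_H`` the
    vertical (row) displacement from the patch's top-left corner to the tip.
    """

    patch: np.ndarray = field(repr=False)
    offset_L: float
    offset_H: float

    def __post_init__(self) -> None:
        p = np.asarray(self.patch)
        if p.ndim != 2 or p.size == 0:
            raise ValueError("template patch must be a non-empty 2-D raster")
        m, n = p.shape
        if not (0 <= self.offset_L <= n and 0 <= self.offset_H <= m):
            raise ValueError("tip offsets must fall within the template extent")

    @property
    def shape(self) -> tuple[int, int]:
        return self.patch.shape


@dataclass(frozen=True)
class MatchResult:
    """Best match: window origin (row i, column j), score, derived tip pixel."""

    match_origin: tuple[int, int]
    score: float
    tip_xy: tuple[float, float]


def make_template(
    reference: np.ndarray,
    top_left: tuple[int, int],
    size: tuple[int, int],
    tip_xy: tuple[float, float],
) -> TipTemplate:
    """Cut a template from a reference image around a user-chosen rectangle.

    Parameters
    ----------
    reference : ndarray
        Image to crop from.
    top_left : (row, col)
        Top-left corner of the rectangle.
    size : (rows, cols)
        Rectangle extent.
    tip_xy : (x, y)
        Needle-tip pixel in *reference* coordinates; stored as offsets
        relative to the rectangle origin.
    """
    r0, c0 = top_left
    m, n = size
    ref = np.asarray(reference)
    if r0 < 0 or c0 < 0 or r0 + m > ref.shape[0] or c0 + n > ref.shape[1]:
        raise ValueError("template rectangle overhangs the reference image")
    patch = ref[r0 : r0 + m, c0 : c0 + n].copy()
    return TipTemplate(patch=patch, offset_L=tip_xy[0] - c0, offset_H=tip_xy[1] - r0)


def _window(img: np.ndarray, tpl: TipTemplate, origin: tuple[int, int]) -> np.ndarray:
    i, j = origin
    m, n = tpl.shape
    a = np.asarray(img, dtype=np.float64)
    if i < 0 or j < 0 or i + m > a.shape[0] or j + n > a.shape[1]:
        raise ValueError(f"window at origin {origin} overhangs image of shape {a.shape}")
    return a[i : i + m, j : j + n]


def ssd_score(img: np.ndarray, tpl: TipTemplate, origin: tuple[int, int]) -> float:
    """Sum of squared deviations between the template and the window at origin."""
    f = _window(img, tpl, origin)
    g = np.asarray(tpl.patch, dtype=np.float64)
    d = f - g
    return float(np.sum(d * d))


def normalized_match(img: np.ndarray, tpl: TipTemplate, origin: tuple[int, int]) -> float:
    """Energy-normalized correlation ``sum(g*f) / sqrt(sum(f**2))`` at origin.

    An identically zero window scores 0 by convention, so flat black regions
    never win the search.
    """
    f = _window(img, tpl, origin)
    g = np.asarray(tpl.patch, dtype=np.float64)
    denom = np.sqrt(np.sum(f * f))
    if denom == 0.0:
        return 0.0
    return float(np.sum(g * f) / denom)


def locate_template(
    img: np.ndarray,
    tpl: TipTemplate,
    measure: str = "eq10_normalized",
) -> MatchResult:
    """Exhaustive search for the template over every valid window origin.

    ``measure`` selects the score that is maximized:

    * ``"eq9_unnormalized"`` — raw cross-correlation ``sum(g * f)``;
    * ``"eq10_normalized"`` — cross-correlation over the window energy,
      robust to illumination gain changes.

    The scan is row-major and the first origin attaining the maximum wins.
    Correlations are evaluated with exact direct convolution so tie-breaking
    is reproducible.
    """
    a = np.asarray(img, dtype=np.float64)
    g = np.asarray(tpl.patch, dtype=np.float64)
    m, n = g.shape
    if m > a.shape[0] or n > a.shape[1]:
        raise ValueError("template larger than the searched image")
    # direct (non-FFT) correlation keeps sums exact for 8-bit data
    num = correlate2d(a, g, mode="valid")
    if measure == "eq9_unnormalized":
        scores = num
    elif measure == "eq10_normalized":
        energy = correlate2d(a * a, np.ones((m, n)), mode="valid")
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(energy > 0.0, num / np.sqrt(energy), 0.0)
    else:
        raise ValueError(f"unknown match measure {measure!r}")
    flat = int(np.argmax(scores))  # first maximum in row-major order
    i, j = np.unravel_index(flat, scores.shape)
    return MatchResult(
        match_origin=(int(i), int(j)),
        score=float(scores[i, j]),
        tip_xy=(j + tpl.offset_L, i + tpl.offset_H),
    )


def locate_tip(img: np.ndarray, tpl: TipTemplate) -> tuple[float, float]:
    """Needle-tip pixel: normalized-match origin plus the stored tip offsets."""
    return locate_template(img, tpl, measure="eq10_normalized").tip_xy
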