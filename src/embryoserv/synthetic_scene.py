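"""Ground-truthed synthetic bright-field micrographs.

Renders the imaging conditions of a zebrafish-embryo microinjection station
without any hardware: an elliptical embryo (dark chorion-like membrane
annulus enclosing a slightly darker yolk disc on a bright background), a dark
tapered pipette entering from an image edge, defocus blur that grows with
distance from a true focal plane, multiplicative/additive uneven-illumination
fields, and additive sensor noise.  Every rendered scene carries a
:class:`SceneTruth` record so detection and servoing stages can be scored
against known ground truth.

Rendering order is: geometry -> defocus blur -> illumination -> sensor noise
-> clamp to 8-bit.  Illumination is applied after rendering and before noise
so a gradient dims both the object and the background, as a real shadowed
field would, while the sensor noise floor stays constant.  All randomness is
driven by the scene seed, so identical parameters produce byte-identical
rasters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .focus_measures import FocusStack

__all__ = [
    "SceneParams",
    "IlluminationField",
    "DefocusModel",
    "SceneTruth",
    "Scene",
    "render_scene",
    "apply_uneven_illumination",
    "generate_defocus_stack",
    "generate_fixture_suite",
]

_ENTRY_EDGES = ("left", "right", "top", "bottom")
# unit vector pointing from the tip toward the entry edge, (dx, dy)
_ENTRY_DIR = {
    "left": (-1.0, 0.0),
    "right": (1.0, 0.0),
    "top": (0.0, -1.0),
    "bottom": (0.0, 1.0),
}

# amplitude of the seeded interior texture; bright-field embryo granularity
# shows local contrast of tens of gray levels, well above the sensor noise
# floor, and it is this fine texture that gives focus measures their peak
_TEXTURE_AMPLITUDE = 15.0


@dataclass(frozen=True)
class SceneParams:
    """Geometry and photometry of one synthetic scene.

    ``embryo_axes`` are the *outer* semi-axes of the membrane annulus in
    pixels; the membrane extends inward by ``membrane_thickness`` and the
    yolk disc fills the remainder.  Intensities are 8-bit levels; the
    membrane renders dark on a bright field, so ``membrane_intensity`` must
    be below ``background_intensity``.
    """

    image_height: int = 256
    image_width: int = 256
    embryo_center: tuple[float, float] = (128.0, 128.0)  # (x, y)
    embryo_axes: tuple[float, float] = (88.0, 74.0)  # (semi-major, semi-minor)
    embryo_angle: float = 0.0  # degrees, counter-clockwise
    membrane_thickness: float = 10.0
    membrane_intensity: float = 80.0
    yolk_intensity: float = 150.0
    background_intensity: float = 200.0
    pipette_present: bool = True
    pipette_tip: tuple[float, float] = (232.0, 64.0)  # (x, y)
    pipette_entry_edge: str = "right"
    pipette_tip_width: float = 4.0
    pipette_base_width: float = 18.0
    pipette_intensity: float = 60.0
    noise_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        a, b = self.embryo_axes
        if not (a >= b > 0):
            raise ValueError("embryo semi-major axis must be >= semi-minor > 0")
        th = np.deg2rad(self.embryo_angle)
        # half-extent of the rotated ellipse along each image axis
        ext_x = np.hypot(a * np.cos(th), b * np.sin(th))
        ext_y = np.hypot(a * np.sin(th), b * np.cos(th))
        cx, cy = self.embryo_center
        if not (
            cx - ext_x >= 0
            and cx + ext_x <= self.image_width - 1
            and cy - ext_y >= 0
            and cy + ext_y <= self.image_height - 1
        ):
            raise ValueError("embryo ellipse must lie fully inside the image")
        if not self.membrane_intensity < self.background_intensity:
            raise ValueError("membrane must render darker than the background")
        if self.pipette_present:
            tx, ty = self.pipette_tip
            if not (0 <= tx <= self.image_width - 1 and 0 <= ty <= self.image_height - 1):
                raise ValueError("pipette tip must lie inside the image")
            if self.pipette_entry_edge not in _ENTRY_EDGES:
                raise ValueError(f"unknown entry edge {self.pipette_entry_edge!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class IlluminationField:
    """Smooth multiplicative illumination nonuniformity plus a DC offset.

    ``linear`` mode interpolates the four corner gains bilinearly over the
    frame (order: top-left, top-right, bottom-left, bottom-right); ``radial``
    mode falls off quadratically from unit gain at the frame centre to the
    mean corner gain at the corners, emulating a decentred lamp or vignette.
    ``none`` is the identity field.
    """

    mode: str = "none"
    gain_at_corners: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    additive_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "linear", "radial"):
            raise ValueError(f"unknown illumination mode {self.mode!r}")
        if any(g <= 0 for g in self.gain_at_corners):
            raise ValueError("all illumination gains must be positive")

    def gain_field(self, height: int, width: int) -> np.ndarray:
        """Evaluate the per-pixel gain raster."""
        if self.mode == "none":
            return np.ones((height, width), dtype=np.float64)
        yy = np.linspace(0.0, 1.0, height)[:, None]
        xx = np.linspace(0.0, 1.0, width)[None, :]
        tl, tr, bl, br = self.gain_at_corners
        if self.mode == "linear":
            top = tl + (tr - tl) * xx
            bottom = bl + (br - bl) * xx
            return top + (bottom - top) * yy
        # radial: unit gain at centre, mean corner gain at corner radius
        g_corner = float(np.mean(self.gain_at_corners))
        r2 = (yy - 0.5) ** 2 + (xx - 0.5) ** 2
        return 1.0 + (g_corner - 1.0) * (r2 / 0.5)

    @property
    def severity(self) -> float:
        """1 minus the minimum gain: 0 for even light, larger = more uneven."""
        if self.mode == "none":
            return 0.0
        return 1.0 - min(self.gain_at_corners)


@dataclass(frozen=True)
class DefocusModel:
    """Isotropic Gaussian defocus: sigma grows linearly away from focus.

    ``sigma(z) = sigma_at_focus + blur_slope * |z - focal_z|`` pixels, which
    is minimal exactly at ``focal_z`` and strictly increasing on either side,
    producing the unimodal focus curves a real through-focus series shows.
    """

    focal_z: float = 3000.0  # micrometres
    sigma_at_focus: float = 0.8  # pixels
    blur_slope: float = 0.004  # pixels per micrometre of |z - focal_z|

    def __post_init__(self) -> None:
        if self.sigma_at_focus < 0 or self.blur_slope < 0:
            raise ValueError("sigma_at_focus and blur_slope must be non-negative")

    def sigma(self, z: float) -> float:
        return self.sigma_at_focus + self.blur_slope * abs(z - self.focal_z)


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth emitted with every rendered scene."""

    embryo_center: tuple[float, float]
    embryo_axes: tuple[float, float]
    embryo_angle: float
    focal_z: float | None
    tip_xy: tuple[float, float] | None
    illumination_mode: str
    seed: int

    def to_json(self) -> str:
        d = {
            "center_x": self.embryo_center[0],
            "center_y": self.embryo_center[1],
            "semi_major": self.embryo_axes[0],
            "semi_minor": self.embryo_axes[1],
            "angle_deg": self.embryo_angle,
            "focal_z": self.focal_z,
            "tip_x": None if self.tip_xy is None else self.tip_xy[0],
            "tip_y": None if self.tip_xy is None else self.tip_xy[1],
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class Scene:
    """A rendered scene bundled with everything needed to re-render it."""

    image: np.ndarray
    truth: SceneTruth
    params: SceneParams
    illumination: IlluminationField


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle_deg: float,
) -> np.ndarray:
    """Boolean mask of the filled, rotated ellipse (sub-pixel parameters)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = center
    th = np.deg2rad(angle_deg)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _pipette_mask(params: SceneParams) -> np.ndarray:
    """Filled dark taper from the entry edge to the tip."""
    h, w = params.image_height, params.image_width
    tx, ty = params.pipette_tip
    ux, uy = _ENTRY_DIR[params.pipette_entry_edge]
    # perpendicular to the pipette axis
    px, py = -uy, ux
    # base far beyond the frame so translating the tip keeps the shaft attached
    reach = 2.0 * max(h, w)
    bx, by = tx + ux * reach, ty + uy * reach
    half_tip = params.pipette_tip_width / 2.0
    half_base = params.pipette_base_width / 2.0
    xs = [tx + px * half_tip, tx - px * half_tip, bx - px * half_base, bx + px * half_base]
    ys = [ty + py * half_tip, ty - py * half_tip, by - py * half_base, by + py * half_base]
    rr, cc = draw_polygon(np.asarray(ys), np.asarray(xs), shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return mask


def _render_clean(params: SceneParams) -> np.ndarray:
    """Noise-free, evenly lit, unblurred float render of the scene."""
    params.validate()
    h, w = params.image_height, params.image_width
    img = np.full((h, w), float(params.background_intensity), dtype=np.float64)

    outer = _ellipse_mask((h, w), params.embryo_center, params.embryo_axes, params.embryo_angle)
    a, b = params.embryo_axes
    t = params.membrane_thickness
    inner_axes = (max(a - t, 1.0), max(b - t, 1.0))
    inner = _ellipse_mask((h, w), params.embryo_center, inner_axes, params.embryo_angle)
    img[outer] = params.membrane_intensity
    img[inner] = params.yolk_intensity

    # seeded granular texture in the yolk (the chorion envelope is smooth);
    # this fine-scale detail is what defocus blur attenuates
    rng = np.random.default_rng(params.seed)
    texture = rng.normal(0.0, _TEXTURE_AMPLITUDE, size=(h, w))
    img[inner] += texture[inner]

    if params.pipette_present:
        img[_pipette_mask(params)] = params.pipette_intensity
    return img


def _finish(
    img: np.ndarray,
    illum: IlluminationField | None,
    noise_sigma: float,
    noise_seed: int,
) -> np.ndarray:
    """Apply illumination and sensor noise, clamp to 8-bit."""
    out = img
    if illum is not None and illum.mode != "none":
        out = out * illum.gain_field(*out.shape) + illum.additive_offset
    if noise_sigma > 0:
        rng = np.random.default_rng(noise_seed)
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def render_scene(
    params: SceneParams,
    illum: IlluminationField | None = None,
) -> tuple[np.ndarray, SceneTruth]:
    """Render one in-focus scene and its ground-truth record.

    Deterministic for a fixed ``(params, illum)``: the interior texture and
    the sensor noise both derive from ``params.seed``.
    """
    clean = _render_clean(params)
    # noise stream decorrelated from the texture stream
    img = _finish(clean, illum, params.noise_sigma, params.seed + 1)
    truth = SceneTruth(
        embryo_center=params.embryo_center,
        embryo_axes=params.embryo_axes,
        embryo_angle=params.embryo_angle,
        focal_z=None,
        tip_xy=params.pipette_tip if params.pipette_present else None,
        illumination_mode="none" if illum is None else illum.mode,
        seed=params.seed,
    )
    return img, truth


def apply_uneven_illumination(img: np.ndarray, illum: IlluminationField) -> np.ndarray:
    """Per-pixel multiply by the gain field, add the offset, clamp to 8-bit.

    With ``mode="none"`` the output equals the input.
    """
    arr = np.asarray(img)
    if illum.mode == "none":
        return arr.astype(np.uint8, copy=True)
    out = arr.astype(np.float64) * illum.gain_field(*arr.shape) + illum.additive_offset
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def generate_defocus_stack(
    params: SceneParams,
    model: DefocusModel,
    z_positions: Sequence[float],
) -> tuple[FocusStack, SceneTruth]:
    """Render the scene once per stage position, blurred by ``model.sigma(z)``.

    Emulates a through-focus acquisition: the underlying scene (texture
    included) is identical in every frame; only the defocus blur and the
    per-frame sensor noise differ.  Sensor noise is applied after blurring,
    as a camera would add it.
    """
    z = np.asarray(z_positions, dtype=np.float64)
    if len(z) < 3:
        raise ValueError("a defocus stack needs at least 3 positions")
    if not np.all(np.diff(z) > 0):
        raise ValueError("z_positions must be strictly increasing")
    clean = _render_clean(params)
    frames = []
    for i, zi in enumerate(z):
        s = model.sigma(zi)
        blurred = gaussian_filter(clean, sigma=s, mode="nearest") if s > 0 else clean
        frames.append(_finish(blurred, None, params.noise_sigma, params.seed + 1 + i))
    truth = SceneTruth(
        embryo_center=params.embryo_center,
        embryo_axes=params.embryo_axes,
        embryo_angle=params.embryo_angle,
        focal_z=model.focal_z,
        tip_xy=params.pipette_tip if params.pipette_present else None,
        illumination_mode="none",
        seed=params.seed,
    )
    return FocusStack(tuple(z), tuple(frames)), truth


def _random_scene_params(rng: np.random.Generator, size: int, seed: int) -> SceneParams:
    """Randomized embryo geometry and pipette pose inside a size x size frame."""
    a = rng.uniform(0.30, 0.37) * size
    b = a * rng.uniform(0.82, 0.95)
    angle = rng.uniform(0.0, 180.0)
    margin = a + 4
    cx = rng.uniform(margin, size - 1 - margin)
    cy = rng.uniform(margin, size - 1 - margin)
    edge = _ENTRY_EDGES[rng.integers(0, 4)]
    # tip placed in the outer band near its entry edge, clear of the embryo
    for _ in range(64):
        if edge == "left":
            tx, ty = rng.uniform(8, 0.25 * size), rng.uniform(8, size - 9)
        elif edge == "right":
            tx, ty = rng.uniform(0.75 * size, size - 9), rng.uniform(8, size - 9)
        elif edge == "top":
            tx, ty = rng.uniform(8, size - 9), rng.uniform(8, 0.25 * size)
        else:
            tx, ty = rng.uniform(8, size - 9), rng.uniform(0.75 * size, size - 9)
        if np.hypot(tx - cx, ty - cy) > a + 12:
            break
    return SceneParams(
        image_height=size,
        image_width=size,
        embryo_center=(round(cx, 1), round(cy, 1)),
        embryo_axes=(round(a, 1), round(b, 1)),
        embryo_angle=round(angle, 1),
        pipette_tip=(round(tx, 1), round(ty, 1)),
        pipette_entry_edge=edge,
        seed=seed,
    )


def generate_fixture_suite(
    seed: int,
    n_scenes: int,
    image_size: int = 256,
    min_gain: float = 0.4,
) -> list[Scene]:
    """Seeded suite of scenes spanning even to strongly uneven illumination.

    Scene 0 is evenly lit (``mode="none"``); subsequent scenes use a linear
    gain field whose darkest corner ramps from 1.0 down to ``min_gain``, so
    the last scene is the most strongly shadowed.  Embryo geometry and
    pipette pose are randomized per scene from ``seed``.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    rng = np.random.default_rng(seed)
    scenes: list[Scene] = []
    for i in range(n_scenes):
        params = _random_scene_params(rng, image_size, seed=int(seed * 10_000 + i) % (2**31))
        if i == 0:
            illum = IlluminationField(mode="none")
        else:
            frac = i / max(n_scenes - 1, 1)
            g = 1.0 - frac * (1.0 - min_gain)
            # darken the bottom-right corner hardest, with a gentle top tilt
            illum = IlluminationField(
                mode="linear",
                gain_at_corners=(1.0, 1.0 - 0.5 * (1.0 - g), 1.0 - 0.5 * (1.0 - g), g),
            )
        img, truth = render_scene(params, illum)
        scenes.append(Scene(image=img, truth=truth, params=params, illumination=illum))
    return scenes
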