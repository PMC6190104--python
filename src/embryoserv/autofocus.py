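"""Two-phase (coarse/fine) microscope autofocus.

The controller drives an abstract focusable stage: a coarse scan with a large
step brackets the focal plane by watching the sharpness score rise and then
fall, after which a fine scan with a small step pinpoints the peak.  The fine
step must stay below the optical depth of field, otherwise the specimen can
jump straight through the in-focus range between consecutive frames;
:func:`depth_of_field` computes that bound from the numerical aperture, total
magnification and illumination wavelength.

The stage abstraction is synchronous and positions are absolute micrometres;
hardware latency, backlash and hysteresis are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .focus_measures import FOCUS_MEASURES

__all__ = [
    "OpticsParams",
    "AutofocusConfig",
    "FocusableStage",
    "SimulatedStage",
    "AutofocusResult",
    "depth_of_field",
    "trend_of_triplet",
    "run_two_phase_autofocus",
]


@dataclass(frozen=True)
class OpticsParams:
    """Optical parameters entering the depth-of-field formula.

    numerical_aperture : dimensionless, > 0
    total_magnification : eyepiece x objective (x any adapter), > 0
    wavelength_mm : illumination wavelength in millimetres (550 nm = 5.5e-4)
    """

    numerical_aperture: float
    total_magnification: float
    wavelength_mm: float = 5.5e-4

    def __post_init__(self) -> None:
        if self.numerical_aperture <= 0 or self.total_magnification <= 0:
            raise ValueError("numerical aperture and magnification must be positive")
        if self.wavelength_mm < 0:
            raise ValueError("wavelength must be non-negative")


def depth_of_field(optics: OpticsParams) -> float:
    """Depth of field in millimetres.

    ``DF = 1e-3 * 7 / (A * M) + lambda / (2 * A**2)`` with ``A`` the numerical
    aperture, ``M`` the total magnification and ``lambda`` the wavelength in
    millimetres.  The first (geometric) term is expressed in millimetres; the
    second is the diffraction-limited axial term.
    """
    A = optics.numerical_aperture
    M = optics.total_magnification
    lam = optics.wavelength_mm
    return 1e-3 * 7.0 / (A * M) + lam / (2.0 * A * A)


def trend_of_triplet(scores: tuple[float, float, float], epsilon: float = 0.0) -> str:
    """Classify three consecutive scores as rising, falling or flat.

    Returns ``"increasing"`` iff each score exceeds its predecessor by more
    than ``epsilon``, ``"decreasing"`` for the mirrored condition, otherwise
    ``"indeterminate"``.  The tolerance suppresses noise-induced oscillation
    around flat regions of the focus curve.
    """
    s1, s2, s3 = scores
    if s1 + epsilon < s2 and s2 + epsilon < s3:
        return "increasing"
    if s1 > s2 + epsilon and s2 > s3 + epsilon:
        return "decreasing"
    return "indeterminate"


class FocusableStage(Protocol):
    """Behavioural contract for anything the controller can focus."""

    z_min: float
    z_max: float

    def capture(self, z: float) -> np.ndarray:  # pragma: no cover - protocol
        ...


class SimulatedStage:
    """A software stage: captures defocus-blurred frames of a synthetic scene.

    Wraps a scene and a defocus model so ``capture(z)`` returns the frame a
    camera would see with the stage at ``z``.  Deterministic per z within a
    run (the per-frame noise seed derives from z).
    """

    def __init__(self, params, model, z_min: float, z_max: float):
        from .synthetic_scene import _render_clean  # local import: avoids a cycle

        self.z_min = float(z_min)
        self.z_max = float(z_max)
        self._params = params
        self._model = model
        self._clean = _render_clean(params)
        self.n_captures = 0

    def capture(self, z: float) -> np.ndarray:
        from scipy.ndimage import gaussian_filter

        from .synthetic_scene import _finish

        if not (self.z_min <= z <= self.z_max):
            raise ValueError(f"requested z={z} outside [{self.z_min}, {self.z_max}]")
        self.n_captures += 1
        s = self._model.sigma(z)
        blurred = gaussian_filter(self._clean, sigma=s, mode="nearest") if s > 0 else self._clean
        noise_seed = (self._params.seed + 7919 * int(round(z))) % (2**31)
        return _finish(blurred, None, self._params.noise_sigma, noise_seed)


@dataclass(frozen=True)
class AutofocusConfig:
    """Controller parameters.

    coarse_step / fine_step are micrometres; the fine step should stay below
    the optical depth of field (see :func:`depth_of_field`).  ``epsilon_rel``
    scales the trend tolerance relative to the running maximum score.
    """

    coarse_step: float = 200.0
    fine_step: float = 50.0
    z_min: float = 0.0
    z_max: float = 6000.0
    epsilon_rel: float = 0.02
    max_evaluations: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.fine_step < self.coarse_step):
            raise ValueError("need 0 < fine_step < coarse_step")
        if self.z_max - self.z_min < 3 * self.coarse_step:
            raise ValueError("z range must span at least 3 coarse steps")
        if self.max_evaluations < 3:
            raise ValueError("max_evaluations must allow at least one triplet")


@dataclass
class AutofocusResult:
    """Outcome of one autofocus run.

    ``trace`` lists every distinct (phase, z, score) capture in order;
    ``best_z`` is the argmax over the trace.  ``converged`` is False when the
    range was exhausted or the evaluation budget ran out before a peak was
    bracketed.
    """

    best_z: float
    best_score: float
    n_evaluations: int
    trace: list[tuple[str, float, float]] = field(default_factory=list)
    converged: bool = True


class _BudgetExhausted(Exception):
    pass


def run_two_phase_autofocus(
    stage: FocusableStage,
    config: AutofocusConfig = AutofocusConfig(),
    measure: str = "brenner",
) -> AutofocusResult:
    """Locate the focal plane with a coarse scan followed by a fine scan.

    Coarse phase: step by ``coarse_step`` from ``z_min``, scoring each frame
    with the chosen focus measure.  Once the running triplet of scores has
    risen and subsequently falls, the focal plane is bracketed.  A falling
    triplet is first confirmed two frames past the coarse peak sample, and
    the true peak can sit up to one coarse step on either side of that
    sample, so the controller backtracks three coarse steps from the
    detection point and fine-scans forward by ``fine_step`` until the fine
    scores fall past their running maximum.  ``best_z`` is the argmax over
    every frame visited.

    If the initial coarse trend is strictly decreasing the scan direction is
    reversed once, to handle starting above focus.  A score profile that is
    monotone over the whole range (focal plane outside it) yields
    ``converged=False`` with the best z seen.  Captures are cached by z, so
    revisiting a coarse position during the fine scan costs nothing.
    """
    if measure not in FOCUS_MEASURES:
        raise ValueError(f"unknown focus measure {measure!r}")
    score_fn = FOCUS_MEASURES[measure]

    trace: list[tuple[str, float, float]] = []
    cache: dict[float, float] = {}

    def evaluate(phase: str, z: float) -> float:
        z = float(np.clip(z, stage.z_min, stage.z_max))
        if z not in cache:
            if len(cache) >= config.max_evaluations:
                raise _BudgetExhausted
            cache[z] = score_fn(stage.capture(z))
            trace.append((phase, z, cache[z]))
        return cache[z]

    def eps() -> float:
        return config.epsilon_rel * max(cache.values(), default=0.0)

    converged = False
    try:
        # ---- coarse phase -------------------------------------------------
        direction = 1.0
        z = config.z_min
        scores: list[float] = []
        seen_increase = False
        reversed_once = False
        detect_z: float | None = None
        while config.z_min <= z <= config.z_max:
            scores.append(evaluate("coarse", z))
            if len(scores) >= 3:
                trend = trend_of_triplet(tuple(scores[-3:]), eps())
                if trend == "increasing":
                    seen_increase = True
                elif trend == "decreasing":
                    if seen_increase:
                        detect_z = z
                        break
                    if len(scores) == 3 and not reversed_once:
                        # started above focus: rescan once from the far end
                        reversed_once = True
                        direction = -1.0
                        scores = []
                        z = config.z_max
                        continue
            z += direction * config.coarse_step
        if detect_z is None:
            best_idx = int(np.argmax([s for _, _, s in trace])) if trace else None
            if best_idx is None:
                raise ValueError("autofocus made no evaluations; check the z range")
            _, bz, bs = trace[best_idx]
            return AutofocusResult(bz, bs, len(trace), trace, converged=False)

        # ---- fine phase ---------------------------------------------------
        start = float(np.clip(detect_z - direction * 3.0 * config.coarse_step,
                              config.z_min, config.z_max))
        fine_scores: list[float] = []
        zf = start
        while (zf - detect_z) * direction <= 1e-9:
            fine_scores.append(evaluate("fine", zf))
            if len(fine_scores) >= 3:
                if trend_of_triplet(tuple(fine_scores[-3:]), eps()) == "decreasing":
                    break
            zf += direction * config.fine_step
        converged = True
    except _BudgetExhausted:
        converged = False

    best_idx = int(np.argmax([s for _, _, s in trace]))
    _, best_z, best_score = trace[best_idx]
    return AutofocusResult(
        best_z=best_z,
        best_score=best_score,
        n_evaluations=len(trace),
        trace=trace,
        converged=converged,
    )
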