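"""End-to-end simulated microinjection: the visual-servoing loop.

Per scene the pipeline mirrors the injection procedure an operator would run
at the microscope: (optionally) autofocus on a through-focus stack, locate
the embryo with the adaptive-threshold detector, locate the pipette tip by
template matching, compute the pixel displacement that carries the tip onto
the embryo centre, command the (simulated) move, then re-image and re-measure
the tip to score the residual error.  Penetration and deposition have no
image-space consequence in this simulation and are recorded as no-op events.

"Moving the pipette" re-renders the scene with the pipette tip translated by
the commanded displacement, under the same illumination and a fresh sensor
noise draw — exactly what the camera would see after the stage moved.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autofocus import AutofocusConfig, SimulatedStage, run_two_phase_autofocus
from .embryo_detection import DetectionConfig, EmbryoDetection, detect_embryo
from .pipette_tracking import TipTemplate, locate_tip, make_template
from .synthetic_scene import DefocusModel, Scene, SceneParams, render_scene

__all__ = [
    "ServoConfig",
    "SceneRecord",
    "ServoReport",
    "compute_displacement",
    "acquire_tip_template",
    "run_injection_sequence",
    "run_suite",
]


@dataclass(frozen=True)
class ServoConfig:
    """Configuration for the full injection pipeline.

    ``success_tolerance`` is the tip-to-target distance in pixels below which
    a simulated injection counts as successful; the default of 10 px is about
    half the apparent diameter of a 20 um injection tip at the working
    magnification.  When ``template`` is None the tip template is acquired
    automatically from a clean reference render of each scene.
    """

    autofocus: AutofocusConfig = field(default_factory=AutofocusConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    template: TipTemplate | None = None
    template_halfsize: int = 14
    success_tolerance: float = 10.0
    run_autofocus: bool = False
    defocus: DefocusModel = field(default_factory=DefocusModel)

    def __post_init__(self) -> None:
        if self.success_tolerance <= 0:
            raise ValueError("success_tolerance must be positive")


@dataclass
class SceneRecord:
    """One row of the report: every stage outcome for one scene."""

    autofocus_converged: bool | None
    autofocus_z_error: float | None
    embryo: EmbryoDetection | None
    tip_xy: tuple[float, float] | None
    displacement: tuple[float, float] | None
    final_error: float | None
    center_error_truth: float | None
    success: bool
    failure_stage: str | None = None

    def to_row(self) -> dict:
        e = self.embryo
        ok = e is not None and e.accepted and e.ellipse is not None
        return {
            "autofocus_converged": self.autofocus_converged,
            "major_axis": round(e.ellipse.major_axis_length, 1) if ok else None,
            "minor_axis": round(e.ellipse.minor_axis_length, 1) if ok else None,
            "b": e.params_used[0] if ok and e.params_used else None,
            "param1": e.params_used[1] if ok and e.params_used else None,
            "center_x": round(e.ellipse.center[0], 1) if ok else None,
            "center_y": round(e.ellipse.center[1], 1) if ok else None,
            "tip_x": round(self.tip_xy[0], 1) if self.tip_xy else None,
            "tip_y": round(self.tip_xy[1], 1) if self.tip_xy else None,
            "final_error": round(self.final_error, 2) if self.final_error is not None else None,
            "success": self.success,
            "failure_stage": self.failure_stage,
        }


@dataclass
class ServoReport:
    """Aggregated records plus the suite summary."""

    records: list[SceneRecord]

    @property
    def n_scenes(self) -> int:
        return len(self.records)

    @property
    def n_success(self) -> int:
        return sum(r.success for r in self.records)

    @property
    def success_rate(self) -> float:
        return self.n_success / self.n_scenes

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_scenes": self.n_scenes,
                "n_success": self.n_success,
                "success_rate": self.success_rate,
                "scenes": [r.to_row() for r in self.records],
            },
            indent=2,
        )

    def write_csv(self, path) -> None:
        rows = [r.to_row() for r in self.records]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)


def compute_displacement(
    embryo_center: tuple[float, float], tip: tuple[float, float]
) -> tuple[float, float]:
    """Pixel translation (dx, dy) that carries the tip onto the embryo centre."""
    return (embryo_center[0] - tip[0], embryo_center[1] - tip[1])


def acquire_tip_template(params: SceneParams, halfsize: int = 14) -> TipTemplate:
    """Build a tip template from a clean, evenly lit reference render.

    Mirrors the manual template preparation step: the operator images the
    pipette once under good conditions and marks the tip.  The rectangle is
    clamped to the frame, so the stored tip offsets are exact even near an
    edge.
    """
    ref_params = dataclasses.replace(params, noise_sigma=0.0)
    ref, truth = render_scene(ref_params, None)
    assert truth.tip_xy is not None
    tx, ty = truth.tip_xy
    r0 = int(np.clip(round(ty) - halfsize, 0, ref.shape[0] - 2 * halfsize - 1))
    c0 = int(np.clip(round(tx) - halfsize, 0, ref.shape[1] - 2 * halfsize - 1))
    size = (2 * halfsize + 1, 2 * halfsize + 1)
    return make_template(ref, (r0, c0), size, (tx, ty))


def run_injection_sequence(scene: Scene, config: ServoConfig = ServoConfig()) -> SceneRecord:
    """Run the full servo sequence on one scene; failures are recorded, never raised."""
    rec = SceneRecord(
        autofocus_converged=None,
        autofocus_z_error=None,
        embryo=None,
        tip_xy=None,
        displacement=None,
        final_error=None,
        center_error_truth=None,
        success=False,
    )

    # 1. autofocus on a simulated through-focus stage (optional: scenes are
    #    rendered in focus, so this stage only verifies convergence)
    if config.run_autofocus:
        stage = SimulatedStage(
            scene.params, config.defocus, config.autofocus.z_min, config.autofocus.z_max
        )
        af = run_two_phase_autofocus(stage, config.autofocus)
        rec.autofocus_converged = af.converged
        rec.autofocus_z_error = abs(af.best_z - config.defocus.focal_z)
        if not af.converged:
            rec.failure_stage = "autofocus"
            return rec

    # 2. embryo detection
    det = detect_embryo(scene.image, config.detection)
    rec.embryo = det
    if not det.accepted or det.ellipse is None:
        rec.failure_stage = "embryo_detection"
        return rec
    center = det.ellipse.center
    truth_c = scene.truth.embryo_center
    rec.center_error_truth = float(np.hypot(center[0] - truth_c[0], center[1] - truth_c[1]))

    # 3. pipette-tip localization
    if not scene.params.pipette_present:
        rec.failure_stage = "tip_localization"
        return rec
    tpl = config.template or acquire_tip_template(scene.params, config.template_halfsize)
    tip = locate_tip(scene.image, tpl)
    rec.tip_xy = tip

    # 4. displacement and simulated move: re-render with the pipette translated
    dx, dy = compute_displacement(center, tip)
    rec.displacement = (dx, dy)
    old_tip = scene.params.pipette_tip
    moved_params = dataclasses.replace(
        scene.params,
        pipette_tip=(old_tip[0] + dx, old_tip[1] + dy),
        seed=scene.params.seed + 977,  # fresh sensor-noise draw after the move
    )
    try:
        moved_img, _ = render_scene(moved_params, scene.illumination)
    except ValueError:
        rec.failure_stage = "move"
        return rec

    # 5. re-measure the tip and score the residual servo error
    new_tip = locate_tip(moved_img, tpl)
    rec.final_error = float(np.hypot(new_tip[0] - center[0], new_tip[1] - center[1]))
    # penetration and deposition: no-op events in this image-space simulation
    rec.success = rec.final_error <= config.success_tolerance
    if not rec.success:
        rec.failure_stage = "servo_residual"
    return rec


def run_suite(scenes: Sequence[Scene], config: ServoConfig = ServoConfig()) -> ServoReport:
    """Run the injection sequence over a fixture suite and aggregate results."""
    if len(scenes) == 0:
        raise ValueError("cannot run an empty suite")
    return ServoReport(records=[run_injection_sequence(s, config) for s in scenes])
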