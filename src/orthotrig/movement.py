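"""Per-tooth rotation, inclination and angulation, and their deltas.

Rotation is the signed angle between the distal->mesial line (projected on
the occlusal XY plane) and the anteroposterior Y axis, obtained with a
full-quadrant arctangent.  Before inclination and angulation are read, the
tooth is realigned about the frame Z axis so its mesiodistal line coincides
with the Y axis ("resetting the rotation"); this removes the influence of
rotation on the two tipping angles.  With v the vestibular-gingival ->
occlusal crown vector in realigned coordinates:

* inclination (buccolingual tip, torque) = atan2(v_x, v_z) — the angle of
  v's XZ projection to the Z axis;
* angulation (mesiodistal tip) = atan2(v_y, v_z) — the angle of v's YZ
  projection to the Z axis.

Sign conventions (documented, not clinical): rotation is positive from +Y
towards +X; a right-handed (counter-clockwise viewed from +Z) rotation of a
tooth therefore *decreases* its rotation angle.  Deltas are final minus
initial, both models measured in the single frame built on the initial
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateToothError
from .geometry import (
    FrameConfig,
    ReferenceFrame,
    build_reference_frame,
    rotation_about_z,
    to_frame_coords,
)
from .model_io import ArchModel, LandmarkKind, LANDMARK_ORDER, ToothLandmarks
from .registration import apply_transform, whole_arch_align

logger = logging.getLogger(__name__)

__all__ = [
    "ToothMeasures",
    "MovementDelta",
    "measure_rotation",
    "measure_inclination_angulation",
    "measure_tooth",
    "measure_arch",
    "compute_deltas",
    "measure_pair",
    "wrap_angle_deg",
]

_DEGENERATE_MM = 1e-9


def wrap_angle_deg(a: float) -> float:
    """Wrap an angle to (-180, 180]."""
    w = (float(a) + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


@dataclass(frozen=True)
class ToothMeasures:
    """Angular position of one tooth plus its realigned landmark coordinates."""

    tooth_id: int
    rotation_deg: float
    inclination_deg: float
    angulation_deg: float
    rotated_coords: dict[LandmarkKind, np.ndarray]


@dataclass(frozen=True)
class MovementDelta:
    """Angular change of one tooth between two timepoints (final - initial)."""

    tooth_id: int
    d_rotation_deg: float
    d_inclination_deg: float
    d_angulation_deg: float


def measure_rotation(tooth: ToothLandmarks, frame: ReferenceFrame) -> float:
    """Rotation angle (degrees, (-180, 180]) of one tooth.

    alpha = atan2(xm - xd, ym - yd) over the frame-XY coordinates of the
    mesial and distal landmarks: the signed angle from +Y to the
    distal->mesial direction, positive towards +X.
    """
    m = to_frame_coords(tooth[LandmarkKind.MESIAL], frame)
    d = to_frame_coords(tooth[LandmarkKind.DISTAL], frame)
    dx, dy = m[0] - d[0], m[1] - d[1]
    if np.hypot(dx, dy) < _DEGENERATE_MM:
        raise DegenerateToothError(
            tooth.tooth_id,
            "mesial-distal line is degenerate after XY projection",
        )
    return wrap_angle_deg(np.degrees(np.arctan2(dx, dy)))


def measure_inclination_angulation(
    tooth: ToothLandmarks, frame: ReferenceFrame
) -> tuple[float, float, dict[LandmarkKind, np.ndarray]]:
    """Inclination and angulation (degrees) after rotational realignment.

    The five landmarks are taken to frame coordinates and rotated about Z
    so the distal->mesial direction lands on +Y (the per-tooth "rotational
    matrix" that resets rotation); the two tipping angles are then read off
    the vestibular-gingival -> occlusal crown vector.  Returns
    ``(inclination_deg, angulation_deg, realigned coordinates)``.
    """
    alpha = measure_rotation(tooth, frame)
    realign = rotation_about_z(alpha)
    rotated = {
        kind: realign.apply(to_frame_coords(tooth[kind], frame))
        for kind in LANDMARK_ORDER
    }
    v = rotated[LandmarkKind.OCCLUSAL] - rotated[LandmarkKind.VESTIBULAR_GINGIVAL]
    if np.linalg.norm(v) < _DEGENERATE_MM:
        raise DegenerateToothError(
            tooth.tooth_id, "occlusal / vestibular-gingival crown vector vanishes"
        )
    if v[2] <= 0:
        logger.warning(
            "tooth %d: crown vector does not point occlusally (v_z = %.3g mm); "
            "angles returned but check landmark identities",
            tooth.tooth_id,
            v[2],
        )
    inclination = np.degrees(np.arctan2(v[0], v[2]))
    angulation = np.degrees(np.arctan2(v[1], v[2]))
    return float(inclination), float(angulation), rotated


def measure_tooth(tooth: ToothLandmarks, frame: ReferenceFrame) -> ToothMeasures:
    """All three angles plus realigned coordinates for one tooth."""
    alpha = measure_rotation(tooth, frame)
    inclination, angulation, rotated = measure_inclination_angulation(tooth, frame)
    return ToothMeasures(tooth.tooth_id, alpha, inclination, angulation, rotated)


def measure_arch(
    model: ArchModel, frame: ReferenceFrame, on_error: str = "raise"
) -> list[ToothMeasures]:
    """Measure every tooth of an arch model in the given frame.

    ``on_error='raise'`` (default) propagates per-tooth degeneracy errors
    with the tooth id in the message; ``'skip'`` logs and drops the tooth.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    out = []
    for fdi, tooth in model.teeth.items():
        try:
            out.append(measure_tooth(tooth, frame))
        except DegenerateToothError:
            if on_error == "raise":
                raise
            logger.warning("skipping unmeasurable tooth %d", fdi)
    return out


def compute_deltas(
    initial: list[ToothMeasures], final: list[ToothMeasures]
) -> list[MovementDelta]:
    """Per-tooth angular change, final - initial (inner join on tooth id).

    Rotation deltas are wrapped to (-180, 180]; inclination/angulation are
    plain differences (their magnitudes stay below 90 degrees for any
    anatomically oriented tooth).  Teeth present in only one list are
    excluded and logged.
    """
    by_id_i = {m.tooth_id: m for m in initial}
    by_id_f = {m.tooth_id: m for m in final}
    only = set(by_id_i) ^ set(by_id_f)
    for fdi in sorted(only):
        logger.warning("tooth %d present at only one timepoint; excluded", fdi)
    deltas = []
    for fdi, mi in by_id_i.items():
        mf = by_id_f.get(fdi)
        if mf is None:
            continue
        deltas.append(
            MovementDelta(
                fdi,
                wrap_angle_deg(mf.rotation_deg - mi.rotation_deg),
                mf.inclination_deg - mi.inclination_deg,
                mf.angulation_deg - mi.angulation_deg,
            )
        )
    return deltas


def measure_pair(
    initial: ArchModel,
    final: ArchModel,
    config: FrameConfig | None = None,
    align: bool = True,
) -> tuple[ReferenceFrame, list[ToothMeasures], list[ToothMeasures], list[MovementDelta]]:
    """Full pipeline: frame, both measurement sets, and deltas.

    The frame is built on the initial model and shared by both timepoints
    (the planes are "copied" to the final model).  With ``align=True`` the
    final model is first carried into the initial model's space by
    whole-arch best fit; use ``align=False`` when the two models already
    live in one coordinate system (e.g. synthetic data or scanner-registered
    exports).
    """
    config = config or FrameConfig()
    if align:
        final = apply_transform(
            whole_arch_align(initial, final, exclude=config.exclude), final
        )
    frame = build_reference_frame(initial, config)
    mi = measure_arch(initial, frame)
    mf = measure_arch(final, frame)
    return frame, mi, mf, compute_deltas(mi, mf)
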