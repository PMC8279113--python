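"""Synthetic paired arch models with known per-tooth movements.

Stands in for a clinical aligner cohort: it generates an initial arch of
template teeth on a parabolic arch form, applies known per-tooth planned
movements (rotation, inclination, angulation, translation) to produce the
final planned model, and optionally corrupts both with isotropic Gaussian
landmark-picking noise.  Because the applied movements are known exactly,
the whole measurement pipeline can be validated without external data.

The generative conventions are chosen so that the measurement pipeline's
single-axis recovery is the identity: ``PlannedMovement`` angles live on
the measurement scale (a planned rotation of +10 degrees yields a measured
rotation delta of +10 degrees, and likewise for the two tipping angles).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as ScipyRotation

from .errors import ValidationError
from .geometry import (
    FrameConfig,
    ReferenceFrame,
    build_reference_frame,
    from_frame_coords,
    rotation_about_z,
    to_frame_coords,
)
from .model_io import (
    ArchModel,
    LandmarkKind,
    ToothLandmarks,
    tooth_type,
    write_landmarks_csv,
)

__all__ = [
    "CrownTemplate",
    "ArchSpec",
    "PlannedMovement",
    "DEFAULT_TOOTH_IDS",
    "DEFAULT_CROWN_TEMPLATES",
    "generate_arch",
    "add_landmark_noise",
    "apply_movements",
    "generate_paired_dataset",
    "PairedDataset",
]

#: Full permanent arch to the second molars, patient-right to patient-left.
DEFAULT_TOOTH_IDS = {
    "upper": (17, 16, 15, 14, 13, 12, 11, 21, 22, 23, 24, 25, 26, 27),
    "lower": (47, 46, 45, 44, 43, 42, 41, 31, 32, 33, 34, 35, 36, 37),
}


@dataclass(frozen=True)
class CrownTemplate:
    """Per-tooth-type crown dimensions (mm)."""

    md_width_mm: float
    crown_height_mm: float
    gingival_offset_mm: float

    def __post_init__(self):
        if min(self.md_width_mm, self.crown_height_mm, self.gingival_offset_mm) <= 0:
            raise ValidationError("crown template dimensions must be positive")


#: Typical adult crown dimensions by tooth type (mesiodistal width,
#: crown height, buccolingual gingival half-offset), mm.
DEFAULT_CROWN_TEMPLATES = {
    "incisor": CrownTemplate(7.0, 9.0, 3.0),
    "canine": CrownTemplate(7.5, 9.5, 3.5),
    "premolar": CrownTemplate(7.0, 8.0, 3.5),
    "molar": CrownTemplate(10.0, 7.5, 4.5),
}


@dataclass(frozen=True)
class ArchSpec:
    """Specification of one synthetic arch.

    Defaults emulate an adult dentition: 14 teeth per arch (second molars
    included), a parabolic arch form of 60 x 45 mm (upper; 54 x 40 mm
    lower), and 0.05 mm isotropic landmark-picking noise.
    """

    arch: str = "upper"
    patient_id: str = "SIM01"
    tooth_ids: tuple[int, ...] | None = None
    arch_width_mm: float | None = None
    arch_depth_mm: float | None = None
    crown_templates: dict | None = None
    noise_sd_mm: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.arch not in DEFAULT_TOOTH_IDS:
            raise ValidationError(f"arch must be 'upper' or 'lower': {self.arch!r}")
        if self.noise_sd_mm < 0:
            raise ValidationError("noise_sd_mm must be >= 0")
        ids = self.tooth_ids or DEFAULT_TOOTH_IDS[self.arch]
        ids = tuple(int(t) for t in ids)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate tooth ids in arch spec")
        object.__setattr__(self, "tooth_ids", ids)
        if self.arch_width_mm is None:
            object.__setattr__(
                self, "arch_width_mm", 60.0 if self.arch == "upper" else 54.0
            )
        if self.arch_depth_mm is None:
            object.__setattr__(
                self, "arch_depth_mm", 45.0 if self.arch == "upper" else 40.0
            )
        if self.arch_width_mm <= 0 or self.arch_depth_mm <= 0:
            raise ValidationError("arch dimensions must be positive")
        object.__setattr__(
            self, "crown_templates", self.crown_templates or DEFAULT_CROWN_TEMPLATES
        )


@dataclass(frozen=True)
class PlannedMovement:
    """Ground-truth movement of one tooth, on the measurement scale."""

    tooth_id: int
    rotation_deg: float = 0.0
    inclination_deg: float = 0.0
    angulation_deg: float = 0.0
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vals = (
            self.rotation_deg,
            self.inclination_deg,
            self.angulation_deg,
            *self.translation_mm,
        )
        if not np.all(np.isfinite(vals)):
            raise ValidationError("planned movement has non-finite values")
        if abs(self.inclination_deg) >= 90 or abs(self.angulation_deg) >= 90:
            raise ValidationError("tipping angles must satisfy |angle| < 90")


def _arch_curve(spec: ArchSpec, n: int = 2001):
    """Dense sampling of the parabolic arch, posterior-right to posterior-left."""
    t = np.linspace(1.0, -1.0, n)
    x = t * spec.arch_width_mm / 2.0
    y = spec.arch_depth_mm * (1.0 - t * t)
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return t, x, y, s


def _clean_arch(spec: ArchSpec, timepoint: str = "initial") -> ArchModel:
    t, x, y, s = _arch_curve(spec)
    templates = {fdi: spec.crown_templates[tooth_type(fdi)] for fdi in spec.tooth_ids}
    widths = np.array([templates[f].md_width_mm for f in spec.tooth_ids])
    centers_s = (np.cumsum(widths) - widths / 2.0) / widths.sum() * s[-1]

    centers_t = np.interp(centers_s, s, t)
    half_w = spec.arch_width_mm / 2.0
    interior = np.array([0.0, spec.arch_depth_mm * 0.5])
    teeth = {}
    for fdi, tc in zip(spec.tooth_ids, centers_t):
        c = np.array([tc * half_w, spec.arch_depth_mm * (1.0 - tc * tc), 0.0])
        # traversal tangent (towards decreasing t), in the occlusal plane
        d = np.array([-half_w, 2.0 * spec.arch_depth_mm * tc, 0.0])
        d /= np.linalg.norm(d)
        mesial_dir = d if (fdi // 10) in (1, 4) else -d
        buccal = np.array([d[1], -d[0], 0.0])
        if np.dot(buccal[:2], c[:2] - interior) < 0:
            buccal = -buccal
        tpl = templates[fdi]
        vg = c + tpl.gingival_offset_mm * buccal
        teeth[fdi] = ToothLandmarks(
            fdi,
            {
                LandmarkKind.LINGUAL_GINGIVAL: c - tpl.gingival_offset_mm * buccal,
                LandmarkKind.MESIAL: c + tpl.md_width_mm / 2.0 * mesial_dir,
                LandmarkKind.DISTAL: c - tpl.md_width_mm / 2.0 * mesial_dir,
                LandmarkKind.OCCLUSAL: vg + np.array([0, 0, tpl.crown_height_mm]),
                LandmarkKind.VESTIBULAR_GINGIVAL: vg,
            },
        )
    return ArchModel(spec.patient_id, spec.arch, timepoint, teeth)


def add_landmark_noise(
    model: ArchModel, sd_mm: float, rng: np.random.Generator
) -> ArchModel:
    """Add isotropic Gaussian noise (mm) to every landmark coordinate."""
    if sd_mm == 0:
        return model
    return model.map_points(lambda pts: pts + rng.normal(0.0, sd_mm, pts.shape))


def generate_arch(spec: ArchSpec, timepoint: str = "initial") -> ArchModel:
    """Generate one synthetic arch model (deterministic given ``spec.seed``).

    Template teeth stand upright on the arch form: the lingual-gingival
    landmarks lie exactly in z = 0 (so the fitted occlusal plane is exact
    for zero noise) and the occlusal landmark sits crown-height directly
    above the vestibular-gingival one, making inclination and angulation
    zero for an unmoved tooth.
    """
    model = _clean_arch(spec, timepoint)
    rng = np.random.default_rng(spec.seed)
    return add_landmark_noise(model, spec.noise_sd_mm, rng)


def apply_movements(
    model: ArchModel,
    movements: Iterable[PlannedMovement],
    frame: ReferenceFrame,
) -> ArchModel:
    """Move teeth by known amounts, expressed in the measurement frame.

    Each tooth is transformed about its five-landmark centroid, in frame
    coordinates: first the buccolingual tip (inclination, about the local
    mesiodistal axis), then the mesiodistal tip (angulation, about the
    local buccolingual axis), then the rotation (about the frame Z axis),
    then the translation.  Teeth without a movement entry are copied
    unchanged.

    The measured tipping angles are projections, not Euler components, so
    the applied buccolingual tip is pre-compensated
    (``theta_applied = atan(tan(inclination) * cos(angulation))``): for an
    upright template tooth all three planned angles are then recovered
    exactly by the measurement pipeline.  For teeth that are already
    tipped the compensation is approximate (small cross-terms remain).
    """
    moves = {int(m.tooth_id): m for m in movements}
    unknown = set(moves) - set(model.teeth)
    if unknown:
        raise ValidationError(f"movements reference unknown teeth: {sorted(unknown)}")
    teeth = {}
    for fdi, tooth in model.teeth.items():
        mv = moves.get(fdi)
        if mv is None:
            teeth[fdi] = tooth
            continue
        pts = to_frame_coords(tooth.points(), frame)
        c = pts.mean(axis=0)
        m = pts[1]  # LANDMARK_ORDER: mesial, distal at indices 1, 2
        d = pts[2]
        alpha = np.arctan2(m[0] - d[0], m[1] - d[1])
        e_md = np.array([np.sin(alpha), np.cos(alpha), 0.0])
        e_bl = np.array([np.cos(alpha), -np.sin(alpha), 0.0])
        ang = np.deg2rad(mv.angulation_deg)
        inc = np.arctan(np.tan(np.deg2rad(mv.inclination_deg)) * np.cos(ang))
        R = (
            rotation_about_z(-mv.rotation_deg).rotation
            @ ScipyRotation.from_rotvec(-e_bl * ang).as_matrix()
            @ ScipyRotation.from_rotvec(e_md * inc).as_matrix()
        )
        moved = (pts - c) @ R.T + c + np.asarray(mv.translation_mm, float)
        teeth[fdi] = tooth.with_points(from_frame_coords(moved, frame))
    return ArchModel(model.patient_id, model.arch, model.timepoint, teeth)


@dataclass
class PairedDataset:
    """Paired initial/final models with their ground-truth movements."""

    records: list  # (initial: ArchModel, final: ArchModel, movements: list)

    def initial_models(self) -> list[ArchModel]:
        return [r[0] for r in self.records]

    def final_models(self) -> list[ArchModel]:
        return [r[1] for r in self.records]

    def ground_truth(self) -> pd.DataFrame:
        rows = []
        for initial, _final, movements in self.records:
            for mv in movements:
                rows.append(
                    {
                        "patient_id": initial.patient_id,
                        "arch": initial.arch,
                        "tooth_fdi": mv.tooth_id,
                        "rotation_deg": mv.rotation_deg,
                        "inclination_deg": mv.inclination_deg,
                        "angulation_deg": mv.angulation_deg,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_landmarks_csv(self.initial_models(), out / "landmarks_initial.csv")
        write_landmarks_csv(self.final_models(), out / "landmarks_final.csv")
        self.ground_truth().to_csv(out / "planned_movements.csv", index=False)


def _random_movements(
    tooth_ids: Sequence[int], rng: np.random.Generator
) -> list[PlannedMovement]:
    """Planned movements emulating mild-crowding aligner setups.

    Per tooth: rotation ~ N(0, 5 deg), inclination and angulation
    ~ N(0, 3 deg), translation ~ N(0, 0.3 mm) per axis.
    """
    out = []
    for fdi in tooth_ids:
        out.append(
            PlannedMovement(
                fdi,
                rotation_deg=float(rng.normal(0, 5.0)),
                inclination_deg=float(np.clip(rng.normal(0, 3.0), -45, 45)),
                angulation_deg=float(np.clip(rng.normal(0, 3.0), -45, 45)),
                translation_mm=tuple(rng.normal(0, 0.3, 3)),
            )
        )
    return out


def generate_paired_dataset(
    specs: ArchSpec | Sequence[ArchSpec],
    movements: Sequence[PlannedMovement] | None = None,
    replicates: int = 14,
    seed: int = 0,
    frame_config: FrameConfig | None = None,
) -> PairedDataset:
    """Generate a cohort of paired initial/final arch models.

    Parameters
    ----------
    specs
        One or several arch specifications (e.g. an upper and a lower
        arch); each is generated for every replicate "patient".
    movements
        Fixed per-tooth movements applied to every replicate; ``None``
        draws random movements per replicate (see ``_random_movements``).
    replicates
        Number of simulated patients (paper-scale cohort: 14).
    seed
        Master seed; per-replicate, per-arch streams are derived
        deterministically from it.

    The final model is the moved clean geometry; landmark noise
    (``spec.noise_sd_mm``) is then added independently to both timepoints,
    emulating two independent point-picking sessions.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if isinstance(specs, ArchSpec):
        specs = [specs]
    records = []
    for r in range(replicates):
        for a, spec in enumerate(specs):
            rng = np.random.default_rng(np.random.SeedSequence([seed, r, a]))
            pid = f"SIM{r + 1:02d}"
            spec_r = replace(spec, patient_id=pid)
            clean = _clean_arch(spec_r, "initial")
            frame = build_reference_frame(clean, frame_config)
            mv = (
                list(movements)
                if movements is not None
                else _random_movements(spec_r.tooth_ids, rng)
            )
            final_clean = apply_movements(clean, mv, frame)
            final_clean = ArchModel(
                pid, spec.arch, "final_planned", final_clean.teeth
            )
            initial = add_landmark_noise(clean, spec.noise_sd_mm, rng)
            final = add_landmark_noise(final_clean, spec.noise_sd_mm, rng)
            records.append((initial, final, mv))
    return PairedDataset(records)
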