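"""Rotation / inclination / angulation measurement and movement deltas."""

import numpy as np
import pytest

from orthotrig import (
    ArchSpec,
    DegenerateToothError,
    PlannedMovement,
    apply_movements,
    apply_transform,
    build_reference_frame,
    compute_deltas,
    generate_arch,
    measure_arch,
    measure_inclination_angulation,
    measure_pair,
    measure_rotation,
    measure_tooth,
    rotation_about_z,
)
from orthotrig.geometry import ReferenceFrame
from orthotrig.model_io import ArchModel, LandmarkKind, ToothLandmarks
from orthotrig.movement import MovementDelta, wrap_angle_deg

from conftest import random_rigid

IDENTITY_FRAME = ReferenceFrame(np.zeros(3), np.eye(3))


def make_tooth(mesial, distal, occlusal=None, vestibular=None, fdi=11):
    """A tooth in identity-frame coordinates with sensible defaults."""
    occlusal = occlusal if occlusal is not None else [0.0, 4.0, 8.0]
    vestibular = vestibular if vestibular is not None else [0.0, 4.0, 0.0]
    return ToothLandmarks(
        fdi,
        {
            LandmarkKind.MESIAL: np.asarray(mesial, float),
            LandmarkKind.DISTAL: np.asarray(distal, float),
            LandmarkKind.OCCLUSAL: np.asarray(occlusal, float),
            LandmarkKind.VESTIBULAR_GINGIVAL: np.asarray(vestibular, float),
            LandmarkKind.LINGUAL_GINGIVAL: np.array([0.0, 2.0, 0.0]),
        },
    )


class TestMeasureRotation:
    def test_mesiodistal_line_along_y_is_zero(self):
        tooth = make_tooth(mesial=[0, 5, 0], distal=[0, 3, 0])
        assert measure_rotation(tooth, IDENTITY_FRAME) == pytest.approx(0.0)

    def test_mesiodistal_line_along_x_is_ninety(self):
        tooth = make_tooth(mesial=[1, 4, 0], distal=[-1, 4, 0])
        assert measure_rotation(tooth, IDENTITY_FRAME) == pytest.approx(90.0)

    def test_ccw_rotation_about_centroid_decreases_angle(self):
        # right-handed (counter-clockwise) Z rotation moves the
        # distal->mesial direction from +Y towards -X: alpha drops by the
        # rotated amount under the documented sign conventions
        tooth = make_tooth(mesial=[0, 5, 0], distal=[0, 3, 0])
        c = tooth.points().mean(axis=0)
        rot = rotation_about_z(10.0)
        rotated = tooth.with_points(rot.apply(tooth.points() - c) + c)
        assert measure_rotation(rotated, IDENTITY_FRAME) == pytest.approx(
            -10.0, abs=1e-9
        )

    def test_degenerate_projection_rejected(self):
        tooth = make_tooth(mesial=[0, 4, 4], distal=[0, 4, 0])
        with pytest.raises(DegenerateToothError, match="11"):
            measure_rotation(tooth, IDENTITY_FRAME)


class TestInclinationAngulation:
    def test_upright_tooth_measures_zero(self):
        tooth = make_tooth(
            mesial=[0, 5, 0], distal=[0, 3, 0],
            vestibular=[0, 0, 0], occlusal=[0, 0, 2],
        )
        inc, ang, _ = measure_inclination_angulation(tooth, IDENTITY_FRAME)
        assert inc == pytest.approx(0.0, abs=1e-12)
        assert ang == pytest.approx(0.0, abs=1e-12)

    def test_pure_buccal_tip_is_inclination(self):
        v = 2.0 * np.array([np.sin(np.deg2rad(20)), 0.0, np.cos(np.deg2rad(20))])
        tooth = make_tooth(
            mesial=[0, 5, 0], distal=[0, 3, 0],
            vestibular=[0, 0, 0], occlusal=v,
        )
        inc, ang, _ = measure_inclination_angulation(tooth, IDENTITY_FRAME)
        assert inc == pytest.approx(20.0, abs=1e-9)
        assert ang == pytest.approx(0.0, abs=1e-9)

    def test_pure_mesial_tip_is_angulation(self):
        v = 2.0 * np.array([0.0, np.sin(np.deg2rad(12)), np.cos(np.deg2rad(12))])
        tooth = make_tooth(
            mesial=[0, 5, 0], distal=[0, 3, 0],
            vestibular=[0, 0, 0], occlusal=v,
        )
        inc, ang, _ = measure_inclination_angulation(tooth, IDENTITY_FRAME)
        assert inc == pytest.approx(0.0, abs=1e-9)
        assert ang == pytest.approx(12.0, abs=1e-9)

    @pytest.mark.parametrize("spin", [-170.0, -30.0, 30.0, 89.0, 170.0])
    def test_rotation_reset_removes_tooth_rotation(self, spin):
        # the per-tooth rotational realignment makes the two tipping
        # angles invariant under any rotation of the tooth about frame Z
        tooth = make_tooth(
            mesial=[1, 5, 0.5], distal=[-0.5, 3, 0],
            vestibular=[0.3, 4, 0], occlusal=[1.0, 4.5, 7.0],
        )
        inc0, ang0, _ = measure_inclination_angulation(tooth, IDENTITY_FRAME)
        pivot = np.array([3.0, -2.0, 1.0])  # arbitrary pivot point
        rot = rotation_about_z(spin)
        spun = tooth.with_points(rot.apply(tooth.points() - pivot) + pivot)
        inc, ang, _ = measure_inclination_angulation(spun, IDENTITY_FRAME)
        assert inc == pytest.approx(inc0, abs=1e-9)
        assert ang == pytest.approx(ang0, abs=1e-9)

    def test_inverted_crown_vector_warns_but_returns(self, caplog):
        tooth = make_tooth(
            mesial=[0, 5, 0], distal=[0, 3, 0],
            vestibular=[0, 0, 2], occlusal=[0.5, 0, -2],
        )
        with caplog.at_level("WARNING"):
            inc, ang, _ = measure_inclination_angulation(tooth, IDENTITY_FRAME)
        assert any("occlusally" in r.message for r in caplog.records)
        assert np.isfinite(inc) and np.isfinite(ang)


class TestMeasureArch:
    def test_synthetic_upright_arch_all_zero(self, clean_arch, frame):
        for m in measure_arch(clean_arch, frame):
            assert m.inclination_deg == pytest.approx(0.0, abs=1e-9)
            assert m.angulation_deg == pytest.approx(0.0, abs=1e-9)

    def test_tooth_order_does_not_matter(self, clean_arch, frame):
        reordered = ArchModel(
            clean_arch.patient_id,
            clean_arch.arch,
            clean_arch.timepoint,
            dict(reversed(list(clean_arch.teeth.items()))),
        )
        a = {m.tooth_id: m for m in measure_arch(clean_arch, frame)}
        b = {m.tooth_id: m for m in measure_arch(reordered, frame)}
        assert set(a) == set(b)
        for fdi in a:
            assert a[fdi].rotation_deg == b[fdi].rotation_deg
            assert a[fdi].inclination_deg == b[fdi].inclination_deg

    def test_full_cohort_batch_measures_386_teeth(self):
        # 14 patients x 2 arches at 14 teeth each, minus 6 absent teeth,
        # matches a clinical 386-tooth cohort
        rows = 0
        drop = [(0, "upper", 17), (1, "lower", 36), (2, "upper", 24),
                (3, "lower", 45), (4, "upper", 12), (5, "lower", 47)]
        for p in range(14):
            for arch in ("upper", "lower"):
                model = generate_arch(
                    ArchSpec(arch=arch, noise_sd_mm=0.05, seed=100 + p)
                )
                for pp, aa, fdi in drop:
                    if pp == p and aa == arch:
                        del model.teeth[fdi]
                rows += len(measure_arch(model, build_reference_frame(model)))
        assert rows == 386


class TestDeltas:
    def test_identical_measures_give_zero(self, clean_arch, frame):
        m = measure_arch(clean_arch, frame)
        for d in compute_deltas(m, m):
            assert d.d_rotation_deg == 0 and d.d_inclination_deg == 0

    def test_rotation_delta_wraps(self):
        a = [measure_fake(11, 179.0)]
        b = [measure_fake(11, -179.0)]
        (d,) = compute_deltas(a, b)
        assert d.d_rotation_deg == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "movement,expected",
        [
            (PlannedMovement(13, rotation_deg=10), (10, 0, 0)),
            (PlannedMovement(24, inclination_deg=5), (0, 5, 0)),
            (PlannedMovement(15, angulation_deg=-8), (0, 0, -8)),
            (PlannedMovement(11, translation_mm=(1.0, -2.0, 0.5)), (0, 0, 0)),
        ],
    )
    def test_single_axis_recovery_is_exact(self, clean_arch, frame, movement, expected):
        final = apply_movements(clean_arch, [movement], frame)
        _, _, _, deltas = measure_pair(clean_arch, final, align=False)
        d = {x.tooth_id: x for x in deltas}[movement.tooth_id]
        assert d.d_rotation_deg == pytest.approx(expected[0], abs=1e-9)
        assert d.d_inclination_deg == pytest.approx(expected[1], abs=1e-9)
        assert d.d_angulation_deg == pytest.approx(expected[2], abs=1e-9)

    def test_unmatched_teeth_excluded(self, clean_arch, frame):
        m = measure_arch(clean_arch, frame)
        deltas = compute_deltas(m, m[:-2])
        assert len(deltas) == len(m) - 2


def measure_fake(fdi, rotation):
    from orthotrig.movement import ToothMeasures

    return ToothMeasures(fdi, rotation, 0.0, 0.0, {})


class TestInvariances:
    def test_deltas_invariant_under_common_rigid_motion(self, clean_arch, frame):
        # transforming both models by the same rigid motion (frame rebuilt
        # from the transformed initial model) leaves every delta unchanged
        rng = np.random.default_rng(11)
        movements = [
            PlannedMovement(
                fdi,
                rotation_deg=float(rng.normal(0, 5)),
                inclination_deg=float(rng.normal(0, 3)),
                angulation_deg=float(rng.normal(0, 3)),
            )
            for fdi in clean_arch.teeth
        ]
        final = apply_movements(clean_arch, movements, frame)
        _, _, _, ref = measure_pair(clean_arch, final, align=False)
        ref = {d.tooth_id: d for d in ref}
        for _ in range(25):
            T = random_rigid(rng)
            _, _, _, moved = measure_pair(
                apply_transform(T, clean_arch), apply_transform(T, final), align=False
            )
            for d in moved:
                r = ref[d.tooth_id]
                assert d.d_rotation_deg == pytest.approx(r.d_rotation_deg, abs=1e-9)
                assert d.d_inclination_deg == pytest.approx(r.d_inclination_deg, abs=1e-9)
                assert d.d_angulation_deg == pytest.approx(r.d_angulation_deg, abs=1e-9)

    def test_noise_recovery_is_unbiased(self):
        # Gaussian landmark noise (sd 0.05 mm) on a standard 8 mm tooth:
        # rotation-delta errors average out over replicates
        rng = np.random.default_rng(12)
        sd, half_md = 0.05, 4.0
        errors = []
        for _ in range(1000):
            md = np.array([0.0, 2 * half_md, 0.0]) + rng.normal(0, sd, 3) - rng.normal(0, sd, 3)
            errors.append(np.degrees(np.arctan2(md[0], md[1])))
        se = np.std(errors, ddof=1) / np.sqrt(len(errors))
        assert abs(np.mean(errors)) < 3 * se + 1e-12


@pytest.mark.parametrize(
    "angle,expected",
    [(0, 0), (180, 180), (-180, 180), (360, 0), (539, 179), (541, -179)],
)
def test_wrap_angle(angle, expected):
    assert wrap_angle_deg(angle) == pytest.approx(expected)
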