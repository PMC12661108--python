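"""Registration engine: MRI centering, landmark, cost, multi-stage search, fusion."""

import itertools

import numpy as np
import pytest

from prostalign.atlas import ReferenceGeometry, build_atlas
from prostalign.errors import (
    DegenerateSimilarityError,
    EmptyMaskError,
    LandmarkFailureError,
    ValidationError,
)
from prostalign.geometry import (
    IDENTITY,
    RigidTransform,
    SegmentationMask,
    VoxelGrid,
    mask_centroid,
)
from prostalign.phantom import PhantomSpec, generate_phantom_pair, offset_spec, random_spec
from prostalign.register import (
    CostConfig,
    Stage,
    StageSchedule,
    detect_pelvic_landmark,
    fuse,
    optimize_ct,
    register_mri,
    registration_cost,
    rough_ct_init,
    run_pipeline,
)

COARSE = dict(
    ct_shape=(100, 100, 50), ct_spacing=(4.0, 4.0, 4.0),
    mri_spacing=(3.0, 3.0, 4.0),
)

FAST_SCHEDULE = StageSchedule(
    stages=(
        Stage(spacing=4.0, strategy="grid", grid_radius=12.0, grid_step=4.0),
        Stage(spacing=2.0, strategy="local", tolerance=0.5),
    )
)


def coarse_case(rng=None, **kw):
    if rng is None:
        spec = PhantomSpec(**{**COARSE, **kw})
    else:
        spec = offset_spec(rng)
        spec = PhantomSpec(**{**spec.__dict__, **COARSE, **kw})
    return generate_phantom_pair(spec)


class TestRegisterMri:
    def test_translation_is_anchor_minus_centroid(self, mri_atlas):
        vals = np.zeros((10, 10, 10), dtype=np.uint8)
        vals[4, 4, 4] = 1  # single voxel at a known world position
        mask = SegmentationMask(values=vals, spacing=(1, 1, 1), origin=(146, 226, 36))
        mri = VoxelGrid(values=np.ones((10, 10, 10)), spacing=(1, 1, 1), origin=(146, 226, 36))
        t = register_mri(mri, mask, mri_atlas)
        np.testing.assert_allclose(t.translation, (50.0, -30.0, 10.0))

    def test_phantom_centroid_maps_exactly_onto_anchor(self, mri_atlas, held_out_case):
        case = held_out_case
        t = register_mri(case.mri, case.prostate_mask_mri, mri_atlas)
        mapped = t.apply(mask_centroid(case.prostate_mask_mri))
        np.testing.assert_allclose(mapped, mri_atlas.anchor, atol=1e-9)

    def test_empty_mask_raises(self, mri_atlas):
        mri = VoxelGrid(values=np.ones((4, 4, 4)), spacing=(1, 1, 1), origin=(0, 0, 0))
        empty = SegmentationMask(values=np.zeros((4, 4, 4)), spacing=(1, 1, 1), origin=(0, 0, 0))
        with pytest.raises(EmptyMaskError):
            register_mri(mri, empty, mri_atlas)

    def test_wrong_atlas_modality_rejected(self, ct_atlas, held_out_case):
        with pytest.raises(ValidationError):
            register_mri(held_out_case.mri, held_out_case.prostate_mask_mri, ct_atlas)


class TestLandmark:
    def test_midpoint_matches_analytic_sphere_centers(self):
        case = coarse_case()
        lm = detect_pelvic_landmark(case.ct)
        expected = np.mean(np.asarray(case.spec.femoral_head_centers), axis=0)
        assert np.linalg.norm(lm - expected) <= np.linalg.norm(case.ct.spacing) / 2

    def test_symmetric_phantom_landmark_on_midline(self):
        case = coarse_case(noise_sigma_ct=0.0)
        lm = detect_pelvic_landmark(case.ct)
        assert abs(lm[0] - 200.0) <= case.ct.spacing[0] / 2

    def test_soft_tissue_only_volume_fails(self):
        vals = np.full((20, 20, 20), 40.0)
        ct = VoxelGrid(values=vals, spacing=(4, 4, 4), origin=(0, 0, 0))
        with pytest.raises(LandmarkFailureError):
            detect_pelvic_landmark(ct)

    def test_single_bone_blob_fails(self):
        vals = np.full((20, 20, 20), 40.0)
        vals[8:12, 8:12, 8:12] = 700.0
        ct = VoxelGrid(values=vals, spacing=(4, 4, 4), origin=(0, 0, 0))
        with pytest.raises(LandmarkFailureError):
            detect_pelvic_landmark(ct)


class TestRoughInit:
    def test_landmark_plus_offset_at_anchor_gives_identity(self, ct_atlas):
        case = coarse_case()
        landmark = np.asarray(ct_atlas.anchor) - np.array([0.0, 25.0, 10.0])
        t = rough_ct_init(case.ct, landmark, ct_atlas)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)

    def test_initialization_error_within_grid_radius(self, ct_atlas):
        """Rough init must land inside the stage-1 search radius."""
        rng = np.random.default_rng(55)
        for _ in range(10):
            case = coarse_case(rng)
            lm = detect_pelvic_landmark(case.ct)
            init = rough_ct_init(case.ct, lm, ct_atlas)
            ideal = np.asarray(ct_atlas.anchor) - case.prostate_center_ct
            assert np.linalg.norm(init.translation - ideal) <= 15.0


class TestRegistrationCost:
    def test_atlas_against_itself_is_zero(self, ct_atlas):
        cost = registration_cost(ct_atlas.mean_intensity, ct_atlas, IDENTITY)
        assert cost == pytest.approx(0.0, abs=1e-9)

    def test_constant_roi_degenerate(self, ct_atlas):
        flat = VoxelGrid(
            values=np.zeros((50, 50, 25)), spacing=(8, 8, 8), origin=(0, 0, 0)
        )
        with pytest.raises(DegenerateSimilarityError):
            registration_cost(flat, ct_atlas, IDENTITY)

    def test_true_transform_beats_shifted_transform(self, ct_atlas):
        rng = np.random.default_rng(66)
        for _ in range(5):
            case = coarse_case(rng)
            t_true = RigidTransform.from_translation(
                np.asarray(ct_atlas.anchor) - case.prostate_center_ct
            )
            t_off = RigidTransform.from_translation(t_true.translation + (10.0, 0.0, 0.0))
            c_true = registration_cost(case.ct, ct_atlas, t_true, spacing=2.0)
            c_off = registration_cost(case.ct, ct_atlas, t_off, spacing=2.0)
            assert c_true < c_off

    def test_nonfinite_transform_rejected(self, ct_atlas):
        bad = RigidTransform.from_translation((0, 0, 0))
        object.__setattr__(bad, "translation", np.array([np.nan, 0.0, 0.0]))
        with pytest.raises(ValidationError):
            registration_cost(ct_atlas.mean_intensity, ct_atlas, bad)


class TestOptimizeCt:
    def test_self_registration_recovers_identity(self, ct_atlas):
        t, diag = optimize_ct(ct_atlas.mean_intensity, ct_atlas, IDENTITY, FAST_SCHEDULE)
        assert np.linalg.norm(t.translation) <= FAST_SCHEDULE.stages[-1].tolerance

    def test_stage_trace_monotone(self, ct_atlas, held_out_case):
        case = held_out_case
        lm = detect_pelvic_landmark(case.ct)
        init = rough_ct_init(case.ct, lm, ct_atlas)
        _, diag = optimize_ct(case.ct, ct_atlas, init)
        finest = [s["best_cost_finest"] for s in diag["stages"]]
        assert all(a >= b for a, b in zip(finest, finest[1:]))
        for s in diag["stages"]:
            assert s["best_cost"] <= s["init_cost"] + 1e-12
            trace = s["trace"]
            assert all(a >= b - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_grid_argmin_matches_brute_force_enumeration(self, ct_atlas, held_out_case):
        """Stage-1 exhaustive scan vs an independent loop over the same grid,
        bit-exact cost ordering."""
        case = held_out_case
        lm = detect_pelvic_landmark(case.ct)
        init = rough_ct_init(case.ct, lm, ct_atlas)
        schedule = StageSchedule(
            stages=(
                Stage(spacing=4.0, strategy="grid", grid_radius=8.0, grid_step=4.0),
                Stage(spacing=2.0, strategy="local", tolerance=2.0, max_iter=1),
            )
        )
        _, diag = optimize_ct(case.ct, ct_atlas, init, schedule)
        stage1 = diag["stages"][0]

        offsets = np.arange(-8.0, 8.1, 4.0)
        brute = []
        for dx, dy, dz in itertools.product(offsets, offsets, offsets):
            t = RigidTransform.from_translation(init.translation + (dx, dy, dz))
            brute.append(registration_cost(case.ct, ct_atlas, t, spacing=4.0))
        brute = np.asarray(brute)
        assert stage1["n_evaluations"] == len(brute)
        assert stage1["best_cost"] == brute.min()  # bit-exact agreement
        # full ordering of the enumerated grid matches the stage's scan
        internal = np.minimum.accumulate(np.asarray(stage1["trace"]))
        assert internal[-1] == brute.min()

    def test_recovers_known_offset_within_two_mm(self, ct_atlas, held_out_case):
        case = held_out_case
        lm = detect_pelvic_landmark(case.ct)
        init = rough_ct_init(case.ct, lm, ct_atlas)
        t, _ = optimize_ct(case.ct, ct_atlas, init)
        ideal = np.asarray(ct_atlas.anchor) - case.prostate_center_ct
        assert np.linalg.norm(t.translation - ideal) <= 2.0

    def test_origin_shift_equivariance(self, ct_atlas, held_out_case):
        """Moving the CT world origin by delta shifts the recovered translation
        by -delta (up to grid effects at the finest spacing)."""
        case = held_out_case
        delta = np.array([7.0, -3.0, 4.0])
        shifted = VoxelGrid(
            values=case.ct.values, spacing=case.ct.spacing,
            origin=case.ct.origin + delta, orientation=case.ct.orientation,
        )
        lm0 = detect_pelvic_landmark(case.ct)
        lm1 = detect_pelvic_landmark(shifted)
        np.testing.assert_allclose(lm1 - lm0, delta, atol=1e-9)
        t0, _ = optimize_ct(case.ct, ct_atlas, rough_ct_init(case.ct, lm0, ct_atlas), FAST_SCHEDULE)
        t1, _ = optimize_ct(shifted, ct_atlas, rough_ct_init(shifted, lm1, ct_atlas), FAST_SCHEDULE)
        np.testing.assert_allclose(
            t1.translation - t0.translation, -delta,
            atol=FAST_SCHEDULE.finest_spacing / 2,
        )


class TestRotationRefinement:
    def test_refinement_on_translation_only_case_stays_small(self, ct_atlas, held_out_case):
        """The phantom has no rotation: the optional refinement must not
        invent one, and must never regress the cost."""
        from prostalign.register import refine_rotation

        case = held_out_case
        init = RigidTransform.from_translation(
            np.asarray(ct_atlas.anchor) - case.prostate_center_ct
        )
        t, diag = refine_rotation(case.ct, ct_atlas, init, spacing=2.0)
        assert diag["best_cost"] <= diag["init_cost"] + 1e-12
        angles = np.abs(np.asarray(diag["euler_zyx_deg"]))
        assert np.all(angles <= 5.0)
        # the recovered map must still land the prostate within tolerance
        mapped = t.apply(case.prostate_center_ct)
        assert np.linalg.norm(mapped - ct_atlas.anchor) <= 2.0


class TestFuseAndPipeline:
    def test_fuse_identities(self):
        assert np.allclose(fuse(IDENTITY, IDENTITY).translation, 0.0)

    def test_fuse_cancellation(self):
        t = RigidTransform.from_translation((10.0, 0.0, 0.0))
        np.testing.assert_allclose(fuse(t, t).translation, 0.0, atol=1e-12)

    def test_fused_transform_maps_mri_centroid_near_ct_centroid(
        self, mri_atlas, ct_atlas, held_out_case
    ):
        case = held_out_case
        t, report = run_pipeline(
            case.mri, case.prostate_mask_mri, case.ct, mri_atlas, ct_atlas
        )
        mapped = t.apply(mask_centroid(case.prostate_mask_mri))
        assert np.linalg.norm(mapped - mask_centroid(case.prostate_mask_ct)) <= 2.0
        assert report["fallbacks"] == []
        tre = np.linalg.norm(t.apply(case.prostate_center_mri) - case.prostate_center_ct)
        assert tre <= 2.0

    def test_landmark_failure_falls_back_to_volume_center(self, mri_atlas, ct_atlas, held_out_case):
        """A boneless CT must not abort: volume-center init, flagged in report."""
        case = held_out_case
        vals = np.asarray(case.ct.values)
        boneless = VoxelGrid(
            values=np.where(vals >= 300.0, 40.0, vals),
            spacing=case.ct.spacing, origin=case.ct.origin,
        )
        t, report = run_pipeline(
            case.mri, case.prostate_mask_mri, boneless, mri_atlas, ct_atlas,
            schedule=FAST_SCHEDULE,
        )
        assert report["fallbacks"], "expected a fallback record"
        assert np.all(np.isfinite(t.translation))
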