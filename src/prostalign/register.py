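"""The two-step automated prostate-specific MRI->CT rigid registration engine.

Step 1 (MRI): the prostate segmentation centroid is translated onto the
atlas anchor — a closed-form pure translation.

Step 2 (CT): a pelvic bone landmark (the femoral-head midpoint) gives a
rough initialization of the prostate position; a multi-stage, coarse-to-fine
translation search then aligns the patient CT with the CT atlas by
minimizing a weighted combination of an intensity metric (normalized
cross-correlation, NCC) and a statistical metric (Studholme normalized
mutual information, NMI), evaluated over a region of interest around the
atlas anchor:

    cost(T) = w_i * (1 - NCC) + w_s * (2 - NMI),   w_i + w_s = 1

NCC is the Pearson correlation of the fixed (atlas) and moving (patient CT)
intensities over the ROI; NMI = (H(A) + H(B)) / H(A, B) from a joint
histogram, ranging from 1 (independent) to 2 (identical), so the cost is
bounded and 0 for identical ROIs.

Because the MRI and CT atlases are inherently co-registered at the anchor,
composing the CT->atlas inverse with the MRI->atlas translation yields the
prostate-specific MRI->CT map. The search is translation-only; rotation is
available in the transform algebra but off by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import ndimage, optimize

from .atlas import Atlas, CT_FILL
from .errors import (
    ConvergenceWarningFlag,
    DegenerateSimilarityError,
    EmptyMaskError,
    LandmarkFailureError,
    ValidationError,
)
from .geometry import (
    RigidTransform,
    SegmentationMask,
    VoxelGrid,
    compose,
    grid_point,
    invert,
    mask_centroid,
    sample_at_world,
)

__all__ = [
    "CostConfig",
    "Stage",
    "StageSchedule",
    "register_mri",
    "detect_pelvic_landmark",
    "rough_ct_init",
    "registration_cost",
    "optimize_ct",
    "refine_rotation",
    "fuse",
    "run_pipeline",
]

BONE_HU = 300.0
#: minimum lateral (left-right) separation of the two femoral-head candidates, mm
FEMORAL_MIN_SEPARATION = 60.0
#: default offset from the femoral-head midpoint to the prostate estimate, mm
#: (posterior and superior of the midpoint in LPS coordinates)
DEFAULT_LANDMARK_OFFSET = (0.0, 25.0, 10.0)


@dataclass(frozen=True)
class CostConfig:
    """Weights and ROI for the registration cost."""

    w_intensity: float = 0.5
    roi_half_width: float = 50.0      # mm, cube about the atlas anchor
    histogram_bins: int = 32

    def __post_init__(self):
        if not (0.0 <= self.w_intensity <= 1.0):
            raise ValidationError(f"w_intensity must be in [0, 1], got {self.w_intensity}")
        if self.histogram_bins < 2:
            raise ValidationError("histogram_bins must be >= 2")
        if self.roi_half_width <= 0:
            raise ValidationError("roi_half_width must be positive")

    @property
    def w_statistical(self) -> float:
        return 1.0 - self.w_intensity


@dataclass(frozen=True)
class Stage:
    """One stage of the coarse-to-fine schedule."""

    spacing: float                    # ROI sampling spacing, mm
    strategy: str                     # "grid" or "local"
    grid_radius: float = 0.0          # mm (grid stages)
    grid_step: float = 0.0            # mm (grid stages)
    tolerance: float = 0.0            # mm convergence tolerance (local stages)
    max_iter: int = 200

    def __post_init__(self):
        if self.strategy not in ("grid", "local"):
            raise ValidationError(f"stage strategy must be 'grid' or 'local', got {self.strategy!r}")
        if self.spacing <= 0:
            raise ValidationError("stage spacing must be positive")
        if self.strategy == "grid" and (self.grid_radius <= 0 or self.grid_step <= 0):
            raise ValidationError("grid stages need positive grid_radius and grid_step")
        if self.strategy == "local" and self.tolerance <= 0:
            raise ValidationError("local stages need a positive tolerance")


@dataclass(frozen=True)
class StageSchedule:
    """Ordered coarse-to-fine stages; spacings must strictly decrease."""

    stages: tuple = (
        Stage(spacing=4.0, strategy="grid", grid_radius=20.0, grid_step=4.0),
        Stage(spacing=2.0, strategy="local", tolerance=0.5),
        Stage(spacing=1.0, strategy="local", tolerance=0.1),
    )

    def __post_init__(self):
        if len(self.stages) < 2:
            raise ValidationError("a multi-stage schedule needs at least 2 stages")
        spac = [s.spacing for s in self.stages]
        if not all(a > b for a, b in zip(spac, spac[1:])):
            raise ValidationError(f"stage spacings must strictly decrease, got {spac}")

    @property
    def finest_spacing(self) -> float:
        return self.stages[-1].spacing


def register_mri(mri: VoxelGrid, prostate_mask: SegmentationMask, atlas: Atlas) -> RigidTransform:
    """Pure translation taking the MRI prostate centroid onto the atlas anchor."""
    if atlas.modality != "MRI":
        raise ValidationError(f"register_mri needs the MRI atlas, got modality {atlas.modality}")
    centroid = mask_centroid(prostate_mask)  # raises EmptyMaskError on empty mask
    return RigidTransform.from_translation(atlas.anchor - centroid)


def detect_pelvic_landmark(ct: VoxelGrid) -> np.ndarray:
    """Locate the femoral-head midpoint on a planning CT (world mm).

    Bone is thresholded at >= 300 HU and split into 6-connected components.
    Among components whose centroids lie in the middle axial third of the
    volume, the two largest with a lateral (left-right) centroid separation
    of at least 60 mm are taken as the femoral heads; their centroid midpoint
    is returned. Raises :class:`LandmarkFailureError` when no bone is present
    or no such lateral pair exists — the pipeline then falls back to
    volume-center initialization.
    """
    vals = np.asarray(ct.values)
    bone = vals >= BONE_HU
    if not bone.any():
        raise LandmarkFailureError("no bone-range (>= 300 HU) voxels in CT")
    structure = ndimage.generate_binary_structure(3, 1)
    labeled, n = ndimage.label(bone, structure=structure)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0

    # z extent of the voxel-center lattice -> middle axial third
    z_centers = ct.origin[2] + ct.spacing[2] * np.arange(ct.dims[2])
    z_lo, z_hi = z_centers.min(), z_centers.max()
    third = (z_hi - z_lo) / 3.0
    mid_lo, mid_hi = z_lo + third, z_hi - third

    candidates = []
    for lab in range(1, n + 1):
        if sizes[lab] == 0:
            continue
        idx_mean = np.asarray(ndimage.center_of_mass(bone, labeled, lab))
        world = grid_point(ct, idx_mean)
        if mid_lo <= world[2] <= mid_hi:
            candidates.append((sizes[lab], world))
    candidates.sort(key=lambda c: -c[0])

    for i, j in itertools.combinations(range(len(candidates)), 2):
        a, b = candidates[i][1], candidates[j][1]
        if abs(a[0] - b[0]) >= FEMORAL_MIN_SEPARATION:
            return (a + b) / 2.0
    raise LandmarkFailureError(
        "fewer than two laterally separated bone components in the middle axial third"
    )


def rough_ct_init(
    ct: VoxelGrid,
    landmark: np.ndarray,
    atlas: Atlas,
    offset=DEFAULT_LANDMARK_OFFSET,
) -> RigidTransform:
    """Rough CT->atlas translation from the pelvic landmark.

    The prostate is estimated at ``landmark + offset`` (default 25 mm
    posterior and 10 mm superior of the femoral-head midpoint); the returned
    translation maps that estimate onto the atlas anchor.
    """
    landmark = np.asarray(landmark, dtype=float)
    if not np.all(np.isfinite(landmark)):
        raise ValidationError(f"landmark must be finite, got {landmark}")
    estimate = landmark + np.asarray(offset, dtype=float)
    return RigidTransform.from_translation(atlas.anchor - estimate)


class _RoiSampler:
    """Fixed-image ROI samples at one spacing, reused across cost evaluations.

    ROI points are a cubic lattice about the atlas anchor in atlas world
    coordinates; the atlas side is sampled and binned once, the patient CT
    is sampled per candidate transform at the inverse-mapped points. For
    translation-only transforms on axis-aligned grids the per-candidate work
    reduces to shifting precomputed voxel coordinates, which keeps the
    multi-resolution search fast.
    """

    def __init__(self, atlas: Atlas, cfg: CostConfig, spacing: float, ct: Optional[VoxelGrid] = None):
        h = cfg.roi_half_width
        anchor = atlas.anchor
        ax = [np.arange(a - h, a + h + spacing / 2, spacing) for a in anchor]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        self.points = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
        if self.points.shape[0] < 1000:
            raise ValidationError(
                f"ROI contains only {self.points.shape[0]} samples at spacing {spacing}; "
                "enlarge roi_half_width or refine spacing"
            )
        self.fixed = sample_at_world(
            atlas.mean_intensity, self.points, interpolation="linear",
            fill_value=CT_FILL if atlas.modality == "CT" else 0.0,
        )
        if np.ptp(self.fixed) == 0:
            raise DegenerateSimilarityError("atlas ROI is constant")
        self.cfg = cfg
        # precompute fixed-image moments and histogram bin indices
        bins = cfg.histogram_bins
        fmin, fmax = self.fixed.min(), self.fixed.max()
        self._fixed_bin = np.minimum(
            ((self.fixed - fmin) * (bins / (fmax - fmin))).astype(np.intp), bins - 1
        )
        fc = self.fixed - self.fixed.mean()
        self._fixed_centered = fc
        self._fixed_ss = float(fc @ fc)
        self._ct_cache = {}
        if ct is not None:
            self._bind(ct)

    def _bind(self, ct: VoxelGrid):
        key = id(ct)
        if key not in self._ct_cache:
            vals = np.ascontiguousarray(np.asarray(ct.values), dtype=np.float32)
            axis_aligned = np.allclose(ct.orientation, np.eye(3))
            base_idx = None
            if axis_aligned:
                base_idx = ((self.points - ct.origin) / ct.spacing).T.copy()
            self._ct_cache[key] = (vals, axis_aligned, base_idx)
        return self._ct_cache[key]

    def moving(self, ct: VoxelGrid, transform: RigidTransform) -> np.ndarray:
        vals, axis_aligned, base_idx = self._bind(ct)
        if axis_aligned and transform.is_translation_only:
            coords = base_idx - (transform.translation / ct.spacing)[:, np.newaxis]
        else:
            pts = invert(transform).apply(self.points)
            coords = (((pts - ct.origin) @ ct.orientation) / ct.spacing).T
        return ndimage.map_coordinates(
            vals, coords, order=1, mode="constant", cval=CT_FILL, prefilter=False
        )

    def cost(self, ct: VoxelGrid, transform: RigidTransform) -> float:
        moving = self.moving(ct, transform).astype(np.float64)  # accumulate moments in double
        mmin, mmax = moving.min(), moving.max()
        if mmax == mmin:
            raise DegenerateSimilarityError("constant ROI: NCC is undefined")
        cfg = self.cfg
        # Pearson NCC against precomputed fixed moments
        mc = moving - moving.mean()
        denom = np.sqrt(self._fixed_ss * (mc @ mc))
        ncc = float(self._fixed_centered @ mc) / denom

        # joint histogram via flat bincount (equal-width bins over each range)
        bins = cfg.histogram_bins
        mbin = np.minimum(((moving - mmin) * (bins / (mmax - mmin))).astype(np.intp), bins - 1)
        joint = np.bincount(self._fixed_bin * bins + mbin, minlength=bins * bins).astype(float)
        joint /= joint.sum()
        p2 = joint.reshape(bins, bins)
        px = p2.sum(axis=1)
        py = p2.sum(axis=0)

        def entropy(q):
            q = q[q > 0]
            return float(-(q * np.log(q)).sum())

        h_joint = entropy(joint)
        if h_joint == 0.0:
            raise DegenerateSimilarityError("degenerate joint histogram")
        nmi = (entropy(px) + entropy(py)) / h_joint
        return cfg.w_intensity * (1.0 - ncc) + cfg.w_statistical * (2.0 - nmi)


def registration_cost(
    ct: VoxelGrid,
    atlas: Atlas,
    transform: RigidTransform,
    cfg: CostConfig = CostConfig(),
    spacing: Optional[float] = None,
) -> float:
    """Weighted NCC + NMI dissimilarity of the CT to the atlas under ``transform``.

    ``transform`` maps CT world points into atlas world coordinates. The ROI
    is a cube of half-width ``cfg.roi_half_width`` about the anchor, sampled
    at ``spacing`` (default: the atlas grid spacing). 0 for identical ROIs.
    """
    if not np.all(np.isfinite(transform.translation)):
        raise ValidationError("transform must be finite")
    if spacing is None:
        spacing = float(min(atlas.geometry.spacing))
    sampler = _RoiSampler(atlas, cfg, spacing)
    return sampler.cost(ct, transform)


def _grid_candidates(init: RigidTransform, radius: float, step: float) -> List[RigidTransform]:
    offsets = np.arange(-radius, radius + step / 2, step)
    cands = []
    for dx, dy, dz in itertools.product(offsets, offsets, offsets):
        t = init.translation + np.array([dx, dy, dz])
        cands.append(RigidTransform(translation=t, rotation=init.rotation))
    return cands


def _argmin_with_tiebreak(costs, candidates, init):
    """Lowest cost, then smallest offset norm from init, then lexicographic order."""
    keys = []
    for c, cand in zip(costs, candidates):
        d = cand.translation - init.translation
        keys.append((c, float(np.linalg.norm(d)), tuple(d)))
    best = min(range(len(keys)), key=lambda i: keys[i])
    return best


def optimize_ct(
    ct: VoxelGrid,
    atlas: Atlas,
    init: RigidTransform,
    schedule: StageSchedule = StageSchedule(),
    cfg: CostConfig = CostConfig(),
):
    """Multi-stage coarse-to-fine translation optimization of CT->atlas.

    Stage 1 exhaustively scans a translation grid about ``init``; later
    stages run derivative-free Nelder-Mead descent over the three translation
    components at successively finer ROI sampling, each seeded by the
    previous stage's best. A running best is maintained at the finest stage's
    sampling, so the reported across-stage best-cost trace is non-increasing
    by construction. Returns ``(transform, diagnostics)``.
    """
    if not np.all(np.isfinite(init.translation)):
        raise ValidationError("init transform must be finite")

    finest = _RoiSampler(atlas, cfg, schedule.finest_spacing)
    diagnostics = {"stages": [], "warnings": []}

    current = init
    best_overall = None  # (cost_at_finest, transform)

    for si, stage in enumerate(schedule.stages):
        sampler = finest if stage.spacing == schedule.finest_spacing else _RoiSampler(atlas, cfg, stage.spacing)
        stage_diag = {
            "stage": si + 1,
            "strategy": stage.strategy,
            "spacing_mm": stage.spacing,
            "trace": [],
        }

        if stage.strategy == "grid":
            candidates = _grid_candidates(current, stage.grid_radius, stage.grid_step)
            costs = []
            n_degenerate = 0
            best_so_far = np.inf
            for cand in candidates:
                try:
                    c = sampler.cost(ct, cand)
                except DegenerateSimilarityError:
                    c = np.inf
                    n_degenerate += 1
                costs.append(c)
                if c < best_so_far:
                    best_so_far = c
                stage_diag["trace"].append(best_so_far)
            if n_degenerate == len(candidates):
                raise DegenerateSimilarityError("every grid candidate produced a constant ROI")
            idx = _argmin_with_tiebreak(costs, candidates, current)
            stage_best = candidates[idx]
            center = min(
                range(len(candidates)),
                key=lambda i: float(np.linalg.norm(candidates[i].translation - current.translation)),
            )
            stage_diag["init_cost"] = costs[center]  # zero-offset candidate = incoming
            stage_diag["best_cost"] = costs[idx]
            stage_diag["n_evaluations"] = len(candidates)
        else:
            init_cost = sampler.cost(ct, current)
            trace = [init_cost]

            def fun(t):
                try:
                    c = sampler.cost(ct, RigidTransform(translation=t, rotation=current.rotation))
                except DegenerateSimilarityError:
                    c = np.inf
                trace.append(min(trace[-1], c))
                return c

            x0 = current.translation
            step = stage.spacing
            simplex = np.vstack([x0] + [x0 + step * e for e in np.eye(3)])
            res = optimize.minimize(
                fun, x0, method="Nelder-Mead",
                options={
                    "initial_simplex": simplex,
                    # convergence is spatial (simplex diameter <= tolerance mm);
                    # the cost has an interpolation-noise floor, so no f-test
                    "xatol": stage.tolerance,
                    "fatol": np.inf,
                    "maxiter": stage.max_iter,
                    "adaptive": True,
                },
            )
            if not res.success and res.status != 0:
                msg = f"stage {si + 1} hit its iteration cap; returning best-so-far"
                diagnostics["warnings"].append(msg)
                warnings.warn(msg, ConvergenceWarningFlag)
            cand = RigidTransform(translation=res.x, rotation=current.rotation)
            cand_cost = float(res.fun)
            # never regress past the incoming point at this stage's sampling
            if cand_cost <= init_cost:
                stage_best, stage_cost = cand, cand_cost
            else:
                stage_best, stage_cost = current, init_cost
            stage_diag["init_cost"] = init_cost
            stage_diag["best_cost"] = stage_cost
            stage_diag["n_evaluations"] = len(trace) - 1
            stage_diag["trace"] = trace

        # score the stage result at the finest sampling; keep the running best
        try:
            fine_cost = finest.cost(ct, stage_best)
        except DegenerateSimilarityError:
            fine_cost = np.inf
        if best_overall is None or fine_cost < best_overall[0]:
            best_overall = (fine_cost, stage_best)
        stage_diag["best_cost_finest"] = best_overall[0]
        diagnostics["stages"].append(stage_diag)
        current = best_overall[1]

    diagnostics["final_cost"] = best_overall[0]
    return best_overall[1], diagnostics


#: rotation-refinement search range, degrees per Euler angle
ROTATION_LIMIT_DEG = 5.0


def refine_rotation(
    ct: VoxelGrid,
    atlas: Atlas,
    init: RigidTransform,
    cfg: CostConfig = CostConfig(),
    spacing: float = 1.0,
    tolerance: float = 0.1,
    max_iter: int = 200,
):
    """Optional small-angle rotation refinement (off by default in the pipeline).

    Jointly refines translation and an intrinsic z-y-x Euler rotation about
    the atlas anchor, limited to +/-5 degrees per angle, by Nelder-Mead at
    the given ROI sampling. Rotating about the anchor keeps the rotation
    parameters decoupled from the translation (a rotation about the world
    origin would drag the distant prostate with it). Returns
    ``(transform, diagnostics)``; the result never regresses past ``init``.
    """
    from scipy.spatial.transform import Rotation

    sampler = _RoiSampler(atlas, cfg, spacing, ct=ct)
    anchor = atlas.anchor
    init_cost = sampler.cost(ct, init)
    limit = np.deg2rad(ROTATION_LIMIT_DEG)

    def build(params):
        t, angles = params[:3], params[3:]
        r = Rotation.from_euler("zyx", angles).as_matrix()
        # rotate about the anchor: p -> R (p - a) + a + t
        return RigidTransform(rotation=r, translation=anchor - r @ anchor + t)

    def fun(params):
        if np.any(np.abs(params[3:]) > limit):
            return np.inf
        try:
            return sampler.cost(ct, build(params))
        except DegenerateSimilarityError:
            return np.inf

    x0 = np.concatenate([init.translation, np.zeros(3)])
    steps = np.concatenate([np.full(3, spacing), np.full(3, np.deg2rad(0.5))])
    simplex = np.vstack([x0] + [x0 + s * e for s, e in zip(steps, np.eye(6))])
    res = optimize.minimize(
        fun, x0, method="Nelder-Mead",
        options={"initial_simplex": simplex, "xatol": tolerance, "fatol": np.inf,
                 "maxiter": max_iter, "adaptive": True},
    )
    diagnostics = {"init_cost": init_cost, "best_cost": float(res.fun),
                   "n_evaluations": int(res.nfev),
                   "euler_zyx_deg": np.rad2deg(res.x[3:]).tolist()}
    if res.fun <= init_cost:
        return build(res.x), diagnostics
    diagnostics["best_cost"] = init_cost
    return init, diagnostics


def fuse(t_mri_atlas: RigidTransform, t_ct_atlas: RigidTransform) -> RigidTransform:
    """MRI world -> CT world map through the co-registered atlas frame."""
    return compose(invert(t_ct_atlas), t_mri_atlas)


def run_pipeline(
    mri: VoxelGrid,
    prostate_mask: SegmentationMask,
    ct: VoxelGrid,
    mri_atlas: Atlas,
    ct_atlas: Atlas,
    cfg: CostConfig = CostConfig(),
    schedule: StageSchedule = StageSchedule(),
    landmark_offset=DEFAULT_LANDMARK_OFFSET,
    estimate_rotation: bool = False,
):
    """Full automated workflow: MRI centering, CT landmark + optimization, fusion.

    Returns ``(mri_to_ct: RigidTransform, report: dict)``. Landmark failure
    falls back to volume-center initialization (recorded in the report), it
    does not abort. ``estimate_rotation`` enables the optional small-angle
    rotation refinement of the CT->atlas transform (translation-only is the
    default behaviour).
    """
    report = {"fallbacks": []}

    t_mri = register_mri(mri, prostate_mask, mri_atlas)
    centroid = mask_centroid(prostate_mask)
    report["mri_prostate_centroid_mm"] = centroid.tolist()
    report["mri_to_atlas_translation_mm"] = t_mri.translation.tolist()

    try:
        landmark = detect_pelvic_landmark(ct)
        report["landmark_mm"] = landmark.tolist()
    except LandmarkFailureError as exc:
        lo, hi = ct.world_extent()
        landmark = (np.asarray(lo) + np.asarray(hi)) / 2.0 - np.asarray(landmark_offset)
        report["fallbacks"].append(f"landmark detection failed ({exc}); using CT volume center")
        report["landmark_mm"] = None

    init = rough_ct_init(ct, landmark, ct_atlas, offset=landmark_offset)
    report["ct_init_translation_mm"] = init.translation.tolist()

    t_ct, diagnostics = optimize_ct(ct, ct_atlas, init, schedule=schedule, cfg=cfg)
    if estimate_rotation:
        t_ct, rot_diag = refine_rotation(
            ct, ct_atlas, t_ct, cfg=cfg, spacing=schedule.finest_spacing
        )
        diagnostics["rotation_refinement"] = rot_diag
    report["optimization"] = {
        "final_cost": diagnostics["final_cost"],
        "stage_best_costs": [s["best_cost"] for s in diagnostics["stages"]],
        "best_cost_finest_trace": [s["best_cost_finest"] for s in diagnostics["stages"]],
        "warnings": diagnostics["warnings"],
    }
    report["ct_to_atlas_translation_mm"] = t_ct.translation.tolist()

    fused = fuse(t_mri, t_ct)
    report["mri_to_ct_translation_mm"] = fused.translation.tolist()
    report["mapped_prostate_centroid_mm"] = fused.apply(centroid).tolist()
    report["diagnostics"] = diagnostics
    return fused, report
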