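"""Seeded synthetic pelvic phantom: paired MRI/CT with a known rigid offset.

The generator emulates the imaging situation the registration pipeline is
built for: an axial T2-weighted prostate MRI with a tight field of view
around the gland, paired with a pelvic planning CT covering a much larger
region, the two related by an unknown rigid (translation-only) offset.
Organs are analytic solids rasterized at voxel centers:

* prostate — ellipsoid;
* bladder — sphere, anterior-superior to the prostate;
* rectum — cylinder along the superior-inferior axis, posterior to the
  prostate, with an optional superior gas column;
* femoral heads — two lateral spheres (the pelvic landmark the CT
  initialization relies on);
* pelvic ring — a superior ellipsoidal bone shell;
* body — an elliptic soft-tissue cylinder surrounded by air.

Modality-specific tissue intensities (CT in Hounsfield units) and additive
Gaussian noise make the two volumes realistically dissimilar; the
ground-truth MRI->CT transform is recorded so target registration error can
be measured exactly.

All stochastic choices that shape a case (offset, organ jitter, gas
fraction, crop jitter) are drawn when the *spec* is created, so a spec plus
its noise seed reproduces a case bit-exactly, and two specs differing only
in noise seed differ only in noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, ValidationError
from .geometry import RigidTransform, SegmentationMask, VoxelGrid, grid_point

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "random_spec",
    "offset_spec",
    "generate_phantom_pair",
    "threshold_segment",
    "crop_fov",
]

#: default tissue intensities (CT in HU, MRI arbitrary units)
CT_INTENSITIES = {
    "air": -1000.0,
    "fat": -90.0,
    "soft": 40.0,
    "urine": 10.0,
    "prostate": 40.0,   # prostate is iso-intense with soft tissue on CT
    "bone": 700.0,
    "gas": -1000.0,
}
MRI_INTENSITIES = {
    "air": 2.0,
    "fat": 120.0,
    "soft": 80.0,       # muscle
    "urine": 250.0,     # bladder fluid is bright on T2
    "prostate": 180.0,
    "bone": 40.0,
    "gas": 5.0,
}

HU_MIN, HU_MAX = -1024.0, 2000.0


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic case.

    Organ geometry is expressed in the CT world frame (400 x 400 x 200 mm
    pelvis); the same anatomy appears in the MRI frame displaced by the
    inverse of ``true_offset`` (the ground-truth MRI->CT rigid map).
    """

    # grids
    ct_shape: tuple = (200, 200, 100)
    ct_spacing: tuple = (2.0, 2.0, 2.0)
    mri_spacing: tuple = (1.5, 1.5, 3.0)
    mri_fov: tuple = (240.0, 240.0, 120.0)   # mm, centered near the prostate
    mri_center_jitter: tuple = (0.0, 0.0, 0.0)  # displacement of MRI FOV center from prostate

    # organs (CT-frame centers, mm)
    prostate_center: tuple = (200.0, 220.0, 100.0)
    prostate_semiaxes: tuple = (22.0, 18.0, 20.0)
    bladder_center: tuple = (200.0, 185.0, 140.0)
    bladder_radius: float = 28.0
    rectum_center_xy: tuple = (200.0, 258.0)
    rectum_radius: float = 14.0
    rectum_z_range: tuple = (50.0, 150.0)
    rectal_gas_fraction: float = 0.3
    femoral_head_centers: tuple = ((118.0, 195.0, 90.0), (282.0, 195.0, 90.0))
    femoral_head_radius: float = 22.0
    pelvic_ring_center: tuple = (200.0, 200.0, 158.0)
    pelvic_ring_semiaxes: tuple = (150.0, 120.0, 38.0)
    pelvic_ring_thickness: float = 9.0
    body_semiaxes_xy: tuple = (185.0, 145.0)
    fiducials: tuple = ()        # optional high-HU spheres (center, radius); off by default

    # intensities & noise
    ct_intensities: dict = field(default_factory=lambda: dict(CT_INTENSITIES))
    mri_intensities: dict = field(default_factory=lambda: dict(MRI_INTENSITIES))
    noise_sigma_mri: float = 8.0
    noise_sigma_ct: float = 15.0

    # ground truth and reproducibility
    true_offset: RigidTransform = field(default_factory=RigidTransform)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rectal_gas_fraction <= 1.0):
            raise ValidationError(f"gas fraction must be in [0, 1], got {self.rectal_gas_fraction}")
        for name, val in [
            ("prostate_semiaxes", self.prostate_semiaxes),
            ("pelvic_ring_semiaxes", self.pelvic_ring_semiaxes),
        ]:
            if np.any(np.asarray(val) <= 0):
                raise ValidationError(f"{name} must be positive, got {val}")
        for name, val in [
            ("bladder_radius", self.bladder_radius),
            ("rectum_radius", self.rectum_radius),
            ("femoral_head_radius", self.femoral_head_radius),
            ("pelvic_ring_thickness", self.pelvic_ring_thickness),
        ]:
            if val <= 0:
                raise ValidationError(f"{name} must be positive, got {val}")
        self._validate_fov()

    # CT world spans [0, extent) with voxel centers at spacing/2 + k*spacing
    @property
    def ct_extent(self) -> np.ndarray:
        return np.asarray(self.ct_shape) * np.asarray(self.ct_spacing)

    def _validate_fov(self):
        extent = self.ct_extent
        checks = [
            ("prostate", np.asarray(self.prostate_center), max(self.prostate_semiaxes)),
            ("bladder", np.asarray(self.bladder_center), self.bladder_radius),
        ]
        for c in self.femoral_head_centers:
            checks.append(("femoral head", np.asarray(c), self.femoral_head_radius))
        for name, center, radius in checks:
            if np.any(center - radius < 0) or np.any(center + radius > extent):
                raise ValidationError(
                    f"{name} (center {center.tolist()}, radius {radius}) lies outside the CT FOV {extent.tolist()}"
                )

    def mri_prostate_center(self) -> np.ndarray:
        """Analytic prostate center in the MRI world frame."""
        from .geometry import invert
        return invert(self.true_offset).apply(np.asarray(self.prostate_center, dtype=float))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_offset"] = self.true_offset.matrix().tolist()
        return d


@dataclass
class PhantomCase:
    """One generated case: paired volumes, masks and the ground-truth transform."""

    mri: VoxelGrid
    ct: VoxelGrid
    prostate_mask_mri: SegmentationMask
    prostate_mask_ct: SegmentationMask
    bone_mask_ct: SegmentationMask
    truth: RigidTransform                 # MRI world -> CT world
    prostate_center_mri: np.ndarray       # analytic, mm
    prostate_center_ct: np.ndarray        # analytic, mm
    spec: PhantomSpec


def random_spec(rng: np.random.Generator, *,
                max_offset: float = 15.0,
                organ_jitter_sigma: float = 1.0,
                size_jitter: float = 0.10,
                noise_sigma_mri: float = 8.0,
                noise_sigma_ct: float = 15.0,
                crop_jitter_max: float = 10.0) -> PhantomSpec:
    """Draw one case's parameters: the study conditions for the phantom battery.

    The MRI->CT offset is uniform in +/-``max_offset`` mm per axis; organs get
    small independent residual jitter (bladder/rectal filling, setup change)
    and +/-``size_jitter`` relative size variation; rectal gas fraction is
    uniform in [0, 0.7].
    """
    offset = rng.uniform(-max_offset, max_offset, size=3)
    jit = lambda: rng.normal(0.0, organ_jitter_sigma, size=3)  # noqa: E731
    scale = lambda: 1.0 + rng.uniform(-size_jitter, size_jitter)  # noqa: E731

    base = PhantomSpec()
    crop_dir = rng.normal(size=3)
    crop_dir /= np.linalg.norm(crop_dir)
    crop_jitter = crop_dir * rng.uniform(0.0, crop_jitter_max)

    heads = tuple(
        tuple(np.asarray(c) + jit()) for c in base.femoral_head_centers
    )
    return PhantomSpec(
        mri_center_jitter=tuple(crop_jitter),
        prostate_center=tuple(np.asarray(base.prostate_center) + jit()),
        prostate_semiaxes=tuple(np.asarray(base.prostate_semiaxes) * scale()),
        bladder_center=tuple(np.asarray(base.bladder_center) + jit()),
        bladder_radius=base.bladder_radius * scale(),
        rectum_center_xy=tuple(np.asarray(base.rectum_center_xy) + jit()[:2]),
        rectum_radius=base.rectum_radius * scale(),
        rectal_gas_fraction=float(rng.uniform(0.0, 0.7)),
        femoral_head_centers=heads,
        femoral_head_radius=base.femoral_head_radius * scale(),
        noise_sigma_mri=noise_sigma_mri,
        noise_sigma_ct=noise_sigma_ct,
        true_offset=RigidTransform.from_translation(offset),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def offset_spec(rng: np.random.Generator, *, max_offset: float = 15.0,
                crop_jitter_max: float = 10.0) -> PhantomSpec:
    """Draw a case with default anatomy and a random rigid MRI->CT offset.

    The parameter-recovery battery conditions: the unknown is the rigid
    offset (uniform in +/-``max_offset`` mm per axis); anatomy, intensities
    and noise levels stay at their defaults so the recovered transform can
    be compared against an exactly known ground truth.
    """
    offset = rng.uniform(-max_offset, max_offset, size=3)
    crop_dir = rng.normal(size=3)
    crop_dir /= np.linalg.norm(crop_dir)
    crop_jitter = crop_dir * rng.uniform(0.0, crop_jitter_max)
    return PhantomSpec(
        mri_center_jitter=tuple(crop_jitter),
        true_offset=RigidTransform.from_translation(offset),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _voxel_centers(shape, spacing, origin):
    ax = [origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def _rasterize(spec: PhantomSpec, shape, spacing, origin, shift: np.ndarray):
    """Label voxel centers of a grid whose anatomy is displaced by ``shift``.

    ``shift`` is the world displacement applied to every organ center
    (zero for the CT frame; ``-true_offset`` for the MRI frame). Returns a
    label array plus the prostate and bone boolean masks.
    """
    xx, yy, zz = _voxel_centers(shape, spacing, origin)

    def sph(center, radius):
        c = np.asarray(center) + shift
        return (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= radius ** 2

    def ellip(center, semi):
        c = np.asarray(center) + shift
        s = np.asarray(semi)
        return ((xx - c[0]) / s[0]) ** 2 + ((yy - c[1]) / s[1]) ** 2 + ((zz - c[2]) / s[2]) ** 2 <= 1.0

    # body: elliptic cylinder around the pelvic ring center (xy), full z
    bc = np.asarray(spec.pelvic_ring_center[:2]) + shift[:2]
    bs = np.asarray(spec.body_semiaxes_xy)
    body = ((xx - bc[0]) / bs[0]) ** 2 + ((yy - bc[1]) / bs[1]) ** 2 <= 1.0

    # pelvic ring shell: between two concentric ellipsoid surfaces
    rc = np.asarray(spec.pelvic_ring_center) + shift
    rs = np.asarray(spec.pelvic_ring_semiaxes)
    q = ((xx - rc[0]) / rs[0]) ** 2 + ((yy - rc[1]) / rs[1]) ** 2 + ((zz - rc[2]) / rs[2]) ** 2
    inner = 1.0 - spec.pelvic_ring_thickness / np.mean(rs)
    ring = (q <= 1.0) & (q >= inner ** 2) & body

    heads = np.zeros_like(body)
    for c in spec.femoral_head_centers:
        heads |= sph(c, spec.femoral_head_radius)

    bladder = sph(spec.bladder_center, spec.bladder_radius)

    rcx, rcy = np.asarray(spec.rectum_center_xy) + shift[:2]
    z0, z1 = np.asarray(spec.rectum_z_range) + shift[2]
    rect = ((xx - rcx) ** 2 + (yy - rcy) ** 2 <= spec.rectum_radius ** 2) & (zz >= z0) & (zz <= z1)
    gas_z = z1 - spec.rectal_gas_fraction * (z1 - z0)
    gas = rect & (zz >= gas_z)

    prostate = ellip(spec.prostate_center, spec.prostate_semiaxes)

    # precedence: later assignments win where solids overlap
    labels = np.zeros(shape, dtype=np.uint8)
    labels[body] = _TISSUE_CODES["soft"]
    labels[ring] = _TISSUE_CODES["bone"]
    labels[heads] = _TISSUE_CODES["bone"]
    labels[bladder] = _TISSUE_CODES["urine"]
    labels[rect] = _TISSUE_CODES["soft"]
    labels[gas] = _TISSUE_CODES["gas"]
    labels[prostate] = _TISSUE_CODES["prostate"]

    for c, r in spec.fiducials:
        labels[sph(c, r)] = _TISSUE_CODES["bone"]

    # masks reflect final label precedence, not the raw solids
    return labels, labels == _TISSUE_CODES["prostate"], labels == _TISSUE_CODES["bone"]


_TISSUE_CODES = {"air": 0, "soft": 1, "fat": 2, "urine": 3, "prostate": 4, "bone": 5, "gas": 6}


def _intensity_volume(labels, table, rng, sigma):
    lut = np.zeros(len(_TISSUE_CODES), dtype=np.float32)
    for tissue, code in _TISSUE_CODES.items():
        lut[code] = table.get(tissue, 0.0)
    out = lut[labels]
    if sigma > 0:
        out += rng.normal(0.0, sigma, size=labels.shape).astype(np.float32)
    return out


def generate_phantom_pair(spec: PhantomSpec) -> PhantomCase:
    """Generate one paired MRI/CT case from a spec (bit-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    ct_origin = np.asarray(spec.ct_spacing) / 2.0

    # --- CT frame: anatomy at its canonical positions -----------------------
    ct_labels, ct_prost, ct_bone = _rasterize(
        spec, spec.ct_shape, np.asarray(spec.ct_spacing), ct_origin, shift=np.zeros(3)
    )
    ct_vals = _intensity_volume(ct_labels, spec.ct_intensities, rng, spec.noise_sigma_ct)
    np.clip(ct_vals, HU_MIN, HU_MAX, out=ct_vals)
    ct = VoxelGrid(values=ct_vals, spacing=spec.ct_spacing, origin=ct_origin)

    # --- MRI frame: anatomy displaced by -true_offset ------------------------
    from .geometry import invert

    shift = invert(spec.true_offset).translation  # translation-only ground truth
    p_mri = np.asarray(spec.prostate_center) + shift
    fov = np.asarray(spec.mri_fov)
    sp = np.asarray(spec.mri_spacing)
    mri_shape = tuple(int(round(f / s)) for f, s in zip(fov, sp))
    mri_center = p_mri + np.asarray(spec.mri_center_jitter)
    mri_origin = mri_center - fov / 2.0 + sp / 2.0
    mri_labels, mri_prost, _ = _rasterize(spec, mri_shape, sp, mri_origin, shift=shift)
    mri_vals = _intensity_volume(mri_labels, spec.mri_intensities, rng, spec.noise_sigma_mri)
    mri = VoxelGrid(values=mri_vals, spacing=sp, origin=mri_origin)

    def _mask(geom: VoxelGrid, arr) -> SegmentationMask:
        return SegmentationMask(
            values=arr.astype(np.uint8), spacing=geom.spacing,
            origin=geom.origin, orientation=geom.orientation,
        )

    if not mri_prost.any():
        raise ValidationError("prostate fell outside the MRI FOV; enlarge mri_fov or reduce jitter")

    return PhantomCase(
        mri=mri,
        ct=ct,
        prostate_mask_mri=_mask(mri, mri_prost),
        prostate_mask_ct=_mask(ct, ct_prost),
        bone_mask_ct=_mask(ct, ct_bone),
        truth=spec.true_offset,
        prostate_center_mri=p_mri,
        prostate_center_ct=np.asarray(spec.prostate_center, dtype=float),
        spec=spec,
    )


def threshold_segment(grid: VoxelGrid, low: float, high: float) -> SegmentationMask:
    """Band-threshold segmentation keeping the largest 6-connected component.

    Serves as the phantom-scale stand-in for a learned prostate segmenter:
    on a noiseless phantom MRI an intensity band around the prostate value
    recovers the generated mask almost exactly.
    """
    if low > high:
        raise ValidationError(f"low ({low}) must be <= high ({high})")
    band = (np.asarray(grid.values) >= low) & (np.asarray(grid.values) <= high)
    if not band.any():
        raise EmptyMaskError(f"no voxels in intensity band [{low}, {high}]")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labeled, n = ndimage.label(band, structure=structure)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    keep = sizes.argmax()
    return SegmentationMask(
        values=(labeled == keep).astype(np.uint8),
        spacing=grid.spacing, origin=grid.origin, orientation=grid.orientation,
    )


def crop_fov(grid: VoxelGrid, box_lo, box_hi) -> VoxelGrid:
    """Crop to voxels whose centers lie inside the world-space box [lo, hi].

    The origin is updated so world coordinates of retained voxels are
    unchanged. Only axis-aligned grids (identity orientation) are supported.
    """
    if not np.allclose(grid.orientation, np.eye(3)):
        raise ValidationError("crop_fov supports axis-aligned grids only")
    lo = np.asarray(box_lo, dtype=float)
    hi = np.asarray(box_hi, dtype=float)
    slices = []
    for d in range(3):
        centers = grid.origin[d] + grid.spacing[d] * np.arange(grid.dims[d])
        inside = np.nonzero((centers >= lo[d]) & (centers <= hi[d]))[0]
        if inside.size == 0:
            raise ValidationError(f"crop box does not intersect the grid FOV on axis {d}")
        slices.append(slice(inside[0], inside[-1] + 1))
    first_idx = np.array([s.start for s in slices], dtype=float)
    new_origin = grid_point(grid, first_idx)
    cropped = np.asarray(grid.values)[tuple(slices)]
    cls = type(grid)
    return cls(values=cropped, spacing=grid.spacing.copy(),
               origin=new_origin, orientation=grid.orientation.copy())
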