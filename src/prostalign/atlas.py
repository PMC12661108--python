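"""Probabilistic MRI and CT atlas construction on a standardized reference grid.

Every training case's prostate centroid is translated onto a fixed anchor
point (the geometric center of a 400 x 400 x 100 mm reference volume,
i.e. (200, 200, 50) mm), intensities are normalized, and the aligned
images and binary prostate masks are averaged voxelwise. Because the MRI
and CT atlases live on the same reference grid with the same anchor, they
are inherently co-registered: registering a patient's MRI and CT each to
its own atlas yields a bidirectional MRI<->CT mapping at the prostate.

Normalization is modality-specific: MRI intensities (arbitrary units,
scanner-dependent) are mapped linearly so the 1st/99th percentiles land on
0/1 and clipped; CT values are already calibrated Hounsfield units and are
only clipped to [-1000, 1500] HU.

Voxels a case never saw (outside its field of view after resampling) are
excluded from that voxel's average through a per-voxel coverage counter, so
small-FOV MRIs do not drag the atlas periphery toward the fill value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, EmptyMaskError, ValidationError
from .geometry import (
    RigidTransform,
    SegmentationMask,
    VoxelGrid,
    load_volume,
    mask_centroid,
    resample,
    save_volume,
)

__all__ = [
    "ReferenceGeometry",
    "Atlas",
    "make_reference_grid",
    "normalize_intensities",
    "center_on_anchor",
    "build_atlas",
    "save_atlas",
    "load_atlas",
]

MRI_FILL = 0.0
CT_FILL = -1000.0
CT_CLIP = (-1000.0, 1500.0)


@dataclass(frozen=True)
class ReferenceGeometry:
    """The standardized atlas volume: extent in mm, isotropic-ish spacing, anchor.

    The anchor is the fixed world point where every case's prostate centroid
    is placed; it is exactly ``extent / 2``.
    """

    extent: tuple = (400.0, 400.0, 100.0)
    spacing: tuple = (2.0, 2.0, 2.0)

    def __post_init__(self):
        ext = np.asarray(self.extent, dtype=float)
        sp = np.asarray(self.spacing, dtype=float)
        if np.any(ext <= 0) or np.any(sp <= 0):
            raise ValidationError("extent and spacing must be positive")
        dims = ext / sp
        if not np.allclose(dims, np.round(dims)):
            raise ValidationError(f"extent {self.extent} is not an integer multiple of spacing {self.spacing}")

    @property
    def anchor(self) -> np.ndarray:
        return np.asarray(self.extent, dtype=float) / 2.0

    @property
    def dims(self) -> tuple:
        return tuple(int(round(e / s)) for e, s in zip(self.extent, self.spacing))


@dataclass
class Atlas:
    """Mean-intensity and prostate-probability volumes on the reference grid."""

    modality: str                     # "MRI" or "CT"
    mean_intensity: VoxelGrid
    prostate_probability: VoxelGrid
    n_cases: int
    geometry: ReferenceGeometry

    @property
    def anchor(self) -> np.ndarray:
        return self.geometry.anchor

    def probability_centroid(self) -> np.ndarray:
        """Probability-weighted centroid of the prostate map (world mm)."""
        p = np.asarray(self.prostate_probability.values, dtype=float)
        total = p.sum()
        if total <= 0:
            raise DegenerateInputError("prostate probability map is identically zero")
        idx = np.indices(p.shape).reshape(3, -1)
        w = p.reshape(-1)
        mean_idx = (idx * w).sum(axis=1) / total
        from .geometry import grid_point
        return grid_point(self.prostate_probability, mean_idx)


def make_reference_grid(geometry: ReferenceGeometry = ReferenceGeometry()) -> VoxelGrid:
    """Empty (zero) volume whose voxel-center lattice spans [0, extent) mm.

    The origin is ``spacing / 2`` so voxel centers tile [0, extent) and the
    geometric center of the volume is the anchor at ``extent / 2``.
    """
    sp = np.asarray(geometry.spacing, dtype=float)
    return VoxelGrid(
        values=np.zeros(geometry.dims, dtype=np.float32),
        spacing=sp,
        origin=sp / 2.0,
    )


def normalize_intensities(grid: VoxelGrid, modality: str) -> VoxelGrid:
    """Modality-specific intensity scaling (see module docstring)."""
    vals = np.asarray(grid.values, dtype=float)
    modality = modality.upper()
    if modality == "MRI":
        lo, hi = np.percentile(vals, [1.0, 99.0])
        if hi <= lo:
            raise DegenerateInputError("MRI volume is (nearly) constant; cannot normalize")
        out = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    elif modality == "CT":
        out = np.clip(vals, *CT_CLIP)
    else:
        raise ValidationError(f"modality must be 'MRI' or 'CT', got {modality!r}")
    return grid.with_values(out.astype(np.float32))


def center_on_anchor(
    image: VoxelGrid,
    mask: SegmentationMask,
    geometry: ReferenceGeometry = ReferenceGeometry(),
    fill_value: float = 0.0,
):
    """Translate the prostate centroid onto the anchor and resample.

    Returns ``(resampled_image, resampled_mask, coverage, transform)`` where
    ``transform`` is the pure translation ``anchor - centroid`` (case world ->
    reference world) and ``coverage`` is a boolean array marking reference
    voxels that fall inside the case's field of view.
    """
    centroid = mask_centroid(mask)  # raises EmptyMaskError if empty
    t = RigidTransform.from_translation(geometry.anchor - centroid)
    ref = make_reference_grid(geometry)
    img_r = resample(image, t, ref, interpolation="linear", fill_value=fill_value)
    mask_r = resample(mask, t, ref, interpolation="nearest", fill_value=0.0)
    ones = image.with_values(np.ones(image.dims, dtype=np.float32))
    cov = resample(ones, t, ref, interpolation="linear", fill_value=0.0)
    coverage = np.asarray(cov.values) > 0.999
    mask_out = SegmentationMask(
        values=(np.asarray(mask_r.values) > 0.5).astype(np.uint8),
        spacing=ref.spacing, origin=ref.origin, orientation=ref.orientation,
    )
    return img_r, mask_out, coverage, t


def build_atlas(
    cases: Sequence,
    modality: str,
    geometry: ReferenceGeometry = ReferenceGeometry(),
) -> Atlas:
    """Average anchor-centered, normalized cases into a probabilistic atlas.

    ``cases`` is a sequence of ``(image: VoxelGrid, mask: SegmentationMask)``
    pairs. Intensities are normalized per case before centering; the mean at
    each voxel runs over the cases that actually cover that voxel. Voxels no
    case covers receive the modality fill value (MRI 0, CT -1000 HU) and
    probability 0.
    """
    cases = list(cases)
    if len(cases) == 0:
        raise ValidationError("cannot build an atlas from an empty case list")
    modality = modality.upper()
    fill = MRI_FILL if modality == "MRI" else CT_FILL

    ref = make_reference_grid(geometry)
    sum_int = np.zeros(ref.dims, dtype=np.float64)
    sum_msk = np.zeros(ref.dims, dtype=np.float64)
    count = np.zeros(ref.dims, dtype=np.int64)

    for image, mask in cases:
        if int(np.asarray(mask.values).sum()) == 0:
            raise EmptyMaskError("atlas case has an empty prostate mask")
        norm = normalize_intensities(image, modality)
        img_r, mask_r, coverage, _ = center_on_anchor(norm, mask, geometry, fill_value=fill)
        sum_int[coverage] += np.asarray(img_r.values, dtype=np.float64)[coverage]
        sum_msk[coverage] += np.asarray(mask_r.values, dtype=np.float64)[coverage]
        count += coverage

    seen = count > 0
    mean_int = np.full(ref.dims, fill, dtype=np.float64)
    mean_int[seen] = sum_int[seen] / count[seen]
    prob = np.zeros(ref.dims, dtype=np.float64)
    prob[seen] = sum_msk[seen] / count[seen]

    return Atlas(
        modality=modality,
        mean_intensity=ref.with_values(mean_int.astype(np.float32)),
        prostate_probability=ref.with_values(prob.astype(np.float32)),
        n_cases=len(cases),
        geometry=geometry,
    )


def save_atlas(atlas: Atlas, out_dir) -> None:
    """Persist an atlas as two NIfTI volumes plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(atlas.mean_intensity, out / "mean_intensity.nii.gz")
    save_volume(atlas.prostate_probability, out / "prostate_probability.nii.gz")
    sidecar = {
        "modality": atlas.modality,
        "n_cases": atlas.n_cases,
        "extent_mm": list(atlas.geometry.extent),
        "spacing_mm": list(atlas.geometry.spacing),
        "anchor_mm": atlas.anchor.tolist(),
        "normalization": "MRI: percentile 1/99 -> [0,1]; CT: clip [-1000, 1500] HU",
    }
    (out / "atlas.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_atlas(in_dir) -> Atlas:
    src = Path(in_dir)
    sidecar = json.loads((src / "atlas.json").read_text())
    geometry = ReferenceGeometry(
        extent=tuple(sidecar["extent_mm"]), spacing=tuple(sidecar["spacing_mm"])
    )
    return Atlas(
        modality=sidecar["modality"],
        mean_intensity=load_volume(src / "mean_intensity.nii.gz"),
        prostate_probability=load_volume(src / "prostate_probability.nii.gz"),
        n_cases=int(sidecar["n_cases"]),
        geometry=geometry,
    )
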