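"""Voxel phantoms for the segmentation stage: simple ellipsoid/sphere
activity distributions on a regular grid, physical-style decay to the
imaging times, fixed-threshold VOI segmentation, and SUV conversion.

The phantom path exercises the image-side operations the time–activity
analysis rests on — a 20%-of-maximum threshold VOI around each hot object
and body-weight SUV normalisation — without simulating SPECT acquisition,
reconstruction, partial volume or registration (volumes are generated
pre-aligned).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DomainError, ValidationError

logger = logging.getLogger("stpdosim")

# 26-connected neighbourhood in 3-D (all voxels sharing a face, edge or corner)
_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PhantomObject:
    """One hot object: axis-aligned ellipsoid (or sphere) in voxel units."""

    shape: str  # "sphere" | "ellipsoid"
    center_vox: tuple[float, float, float]
    radii_vox: tuple[float, float, float]
    concentration_kBq_per_ml: float

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValidationError(f"unknown object shape {self.shape!r}")
        if self.shape == "sphere" and len(set(self.radii_vox)) != 1:
            raise ValidationError("a sphere needs equal radii")
        if any(r <= 0 for r in self.radii_vox):
            raise ValidationError("radii must be > 0")
        if self.concentration_kBq_per_ml < 0:
            raise ValidationError("concentration must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """A 3-D phantom: grid, isotropic voxel size, objects and background."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    objects: tuple[PhantomObject, ...] = ()
    background_concentration: float = 0.0
    body_weight_kg: float = 80.0
    injected_activity_MBq: float = 6090.0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise ValidationError("grid_shape entries must be >= 1")
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel_size_mm must be > 0")
        if self.background_concentration < 0:
            raise ValidationError("background concentration must be >= 0")
        for obj in self.objects:
            for c, r, n in zip(obj.center_vox, obj.radii_vox, self.grid_shape):
                if c - r < -0.5 or c + r > n - 0.5:
                    raise ValidationError(
                        f"object at {obj.center_vox} with radii {obj.radii_vox} "
                        f"does not fit inside grid {self.grid_shape}"
                    )

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3  # mm^3 -> cm^3 = ml


def _object_fill(
    obj: PhantomObject, grid_shape: tuple[int, int, int], subsamples: int = 4
) -> np.ndarray:
    """Per-voxel fill fraction of the ellipsoid, by subdividing each voxel
    into ``subsamples**3`` points. Keeps the voxelized volume within ~1% of
    the analytic ellipsoid volume down to radii of a few voxels."""
    s = subsamples
    offs = (np.arange(s) + 0.5) / s - 0.5  # sub-voxel offsets in [-0.5, 0.5)
    axes = [
        (np.arange(n, dtype=float)[:, None] + offs[None, :]).ravel()
        for n in grid_shape
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=True)
    cx, cy, cz = obj.center_vox
    rx, ry, rz = obj.radii_vox
    inside = (
        ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2
    ) <= 1.0
    nx, ny, nz = grid_shape
    return (
        inside.reshape(nx, s, ny, s, nz, s)
        .mean(axis=(1, 3, 5))
        .astype(float)
    )


def build_phantom(
    spec: PhantomSpec,
    half_lives_h: Sequence[float],
    times_h: Sequence[float],
) -> dict[float, np.ndarray]:
    """Concentration grids (kBq/ml) at each requested time.

    Each object decays with its own effective half-life; the background
    decays with the first object's half-life (or not at all if there are no
    objects). Overlapping objects: the later object in the list wins, with
    a logged warning.
    """
    if len(half_lives_h) != len(spec.objects):
        raise ValidationError(
            "need one half-life per object "
            f"({len(spec.objects)} objects, {len(half_lives_h)} half-lives)"
        )
    if any(h <= 0 for h in half_lives_h):
        raise ValidationError("half-lives must be > 0")
    fills = [_object_fill(obj, spec.grid_shape) for obj in spec.objects]
    masks = [f > 0 for f in fills]
    for i, j in ((i, j) for j in range(len(masks)) for i in range(j)):
        if np.any(masks[i] & masks[j]):
            logger.warning("phantom objects %d and %d overlap; %d wins", i, j, j)
    bg_half_life = half_lives_h[0] if half_lives_h else math.inf
    grids: dict[float, np.ndarray] = {}
    for t in times_h:
        if t < 0:
            raise ValidationError("times must be >= 0")
        grid = np.full(
            spec.grid_shape,
            spec.background_concentration * 2.0 ** (-t / bg_half_life),
            dtype=float,
        )
        for obj, fill, mask, hl in zip(spec.objects, fills, masks, half_lives_h):
            grid[mask] = (
                obj.concentration_kBq_per_ml * fill[mask] * 2.0 ** (-t / hl)
            )
        grids[float(t)] = grid
    return grids


def segment_fixed_threshold(
    grid: np.ndarray,
    seed_region: np.ndarray | tuple[slice, ...] | None = None,
    fraction: float = 0.20,
) -> np.ndarray:
    """Fixed-threshold VOI: the 26-connected component, containing the
    hottest voxel of ``seed_region``, of voxels >= ``fraction`` x that
    maximum.

    ``seed_region`` may be a boolean mask, a tuple of slices, or None for
    the whole grid. ``fraction=0`` returns the entire connected non-zero
    region around the maximum; ``fraction=1`` returns only the maximal
    voxel(s) connected to it.
    """
    if not (0 <= fraction <= 1):
        raise ValidationError(f"fraction must be in [0, 1], got {fraction}")
    grid = np.asarray(grid, dtype=float)
    if seed_region is None:
        region_mask = np.ones(grid.shape, dtype=bool)
    elif isinstance(seed_region, tuple):
        region_mask = np.zeros(grid.shape, dtype=bool)
        region_mask[seed_region] = True
    else:
        region_mask = np.asarray(seed_region, dtype=bool)
        if region_mask.shape != grid.shape:
            raise ValidationError("seed_region mask shape mismatch")
    region_vals = np.where(region_mask, grid, -np.inf)
    peak = float(region_vals.max())
    if peak <= 0:
        raise DomainError("seed region contains no positive activity")
    peak_idx = np.unravel_index(int(np.argmax(region_vals)), grid.shape)
    if fraction == 0:
        above = grid > 0
    else:
        above = grid >= fraction * peak
    labels, _ = ndimage.label(above, structure=_CONNECTIVITY_26)
    return labels == labels[peak_idx]


def mask_activity_MBq(
    grid_kBq_per_ml: np.ndarray, mask: np.ndarray, spec: PhantomSpec
) -> float:
    """Total activity in a mask: voxel sum x voxel volume, kBq -> MBq."""
    return float(grid_kBq_per_ml[mask].sum() * spec.voxel_volume_ml / 1000.0)


def concentration_to_suv(
    concentration_kBq_per_ml: float | np.ndarray,
    injected_activity_MBq: float,
    body_weight_kg: float,
):
    """Body-weight SUV with unit-density tissue (1 g/ml):

        SUV = C [kBq/ml] * BW [g] / A_inj [kBq].
    """
    if injected_activity_MBq <= 0 or body_weight_kg <= 0:
        raise ValidationError("injected activity and body weight must be > 0")
    conc = np.asarray(concentration_kBq_per_ml, dtype=float)
    if np.any(conc < 0):
        raise ValidationError("concentration must be >= 0")
    suv = conc * (body_weight_kg * 1000.0) / (injected_activity_MBq * 1000.0)
    return float(suv) if np.isscalar(concentration_kBq_per_ml) else suv


def write_nifti(grid: np.ndarray, spec: PhantomSpec, path) -> None:
    """Write a grid as NIfTI with an isotropic affine (mm)."""
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine), str(path))


def read_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
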