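"""Synthetic CT phantom patches for low-contrast detectability studies.

This module emulates the image material of a phantom observer study:
5 x 5 cm^2 crops of a homogeneous CT background (mean ~70 HU) with
dose-dependent quantum noise, optionally processed by an iterative-
reconstruction-like noise reduction ("ADMIRE" flavor), and circular
hyperattenuating low-contrast objects rendered at random in-bounds
locations.

Two dataset builders reproduce the factorial structure of the study:

* :func:`generate_training_set` -- a single acquisition condition
  (default 200 mAs, FBP), half of the images carrying one object with
  size drawn from 3-20 mm and contrast from 5-30 HU.
* :func:`generate_test_set` -- a full dose x reconstruction x size
  factorial (default 4 doses x 2 recons x {5, 9} mm at +10 HU) with an
  exact present/absent split per cell; 640 images under the defaults.

No projection or reconstruction physics is simulated: noise is drawn
directly in image space with a standard deviation scaled as
``1/sqrt(mAs)``, which is the leading-order behavior of quantum noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import InvalidConditionError, InvalidDesignError, PlacementError

__all__ = [
    "AcquisitionCondition",
    "NoiseModel",
    "ObjectSpec",
    "ImagePatch",
    "PatchGeometry",
    "noise_sigma_for",
    "make_background",
    "render_object",
    "render_case",
    "generate_training_set",
    "generate_test_set",
    "case_seed_for",
    "MANIFEST_COLUMNS",
]

#: Background mean in HU (the display window level used in the study).
BACKGROUND_HU = 70.0

#: Reconstruction labels accepted by :class:`AcquisitionCondition`.
RECON_LABELS = ("FBP", "ADMIRE")

MANIFEST_COLUMNS = [
    "case_id",
    "split",
    "present",
    "diameter_mm",
    "contrast_hu",
    "center_x_mm",
    "center_y_mm",
    "mas",
    "recon",
    "seed",
]


@dataclass(frozen=True)
class AcquisitionCondition:
    """A (tube current-time product, reconstruction) pair.

    Parameters
    ----------
    mas:
        Tube current-time product in mAs; the study grid is
        {200, 100, 50, 26}. Must be positive.
    recon:
        Reconstruction label, ``"FBP"`` or ``"ADMIRE"``.
    kvp:
        Tube potential in kVp. Carried as metadata only (fixed 100 in
        the study); it does not enter the noise model.
    """

    mas: float
    recon: str = "FBP"
    kvp: float = 100.0

    def __post_init__(self) -> None:
        if not self.mas > 0:
            raise InvalidConditionError(f"mas must be positive, got {self.mas}")
        if self.recon not in RECON_LABELS:
            raise InvalidConditionError(
                f"recon must be one of {RECON_LABELS}, got {self.recon!r}"
            )


@dataclass(frozen=True)
class NoiseModel:
    """Image-space noise parameterization.

    ``sigma_ref`` is the noise standard deviation in HU at the reference
    condition (``mas_ref`` mAs, FBP). Noise at other doses scales as
    ``sqrt(mas_ref / mas)``. The ADMIRE flavor multiplies the noise
    amplitude by ``admire_factor`` and, when ``smooth_px > 0``, smooths
    the noise field with an isotropic Gaussian of that width, emulating
    the noise-magnitude reduction and mild texture change of iterative
    reconstruction. ``corr_px > 0`` additionally applies an isotropic
    correlation kernel to *all* patches (off by default: white noise
    keeps the analytic oracles exact).
    """

    sigma_ref: float = 10.0
    mas_ref: float = 200.0
    admire_factor: float = 0.7
    smooth_px: float = 0.5
    corr_px: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_ref < 0:
            raise InvalidConditionError("sigma_ref must be >= 0")
        if not (0 < self.admire_factor <= 1):
            raise InvalidConditionError("admire_factor must be in (0, 1]")
        if self.smooth_px < 0 or self.corr_px < 0:
            raise InvalidConditionError("smoothing widths must be >= 0")


@dataclass(frozen=True)
class ObjectSpec:
    """A circular low-contrast object (or its absence).

    Coordinates are in mm from the patch's top-left corner, x rightward
    and y downward; pixel centers sit at ``(i + 0.5) * spacing``.
    """

    present: bool
    diameter_mm: float = float("nan")
    contrast_hu: float = float("nan")
    center_mm: tuple[float, float] = (float("nan"), float("nan"))


@dataclass
class ImagePatch:
    """A square patch of HU values with isotropic pixel spacing."""

    pixels: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2-D array")

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    @property
    def side_mm(self) -> float:
        return self.n_pixels * self.spacing_mm


@dataclass(frozen=True)
class PatchGeometry:
    """Patch raster: 64 px at 0.78125 mm/px maps 5 cm exactly onto a
    power-of-two grid (convenient for the detector's pooling chain)."""

    n_pixels: int = 64
    spacing_mm: float = 0.78125
    mean_hu: float = BACKGROUND_HU

    @property
    def side_mm(self) -> float:
        return self.n_pixels * self.spacing_mm


def noise_sigma_for(condition: AcquisitionCondition, model: NoiseModel) -> float:
    """Nominal noise standard deviation (HU) for an acquisition condition.

    ``sigma = sigma_ref * sqrt(mas_ref / mas)``, further multiplied by
    ``admire_factor`` for ADMIRE reconstructions. This is the amplitude
    of the generated noise field *before* any ADMIRE smoothing.
    """
    if not condition.mas > 0:
        raise InvalidConditionError(f"mas must be positive, got {condition.mas}")
    sigma = model.sigma_ref * float(np.sqrt(model.mas_ref / condition.mas))
    if condition.recon == "ADMIRE":
        sigma *= model.admire_factor
    return sigma


def _correlated_unit_noise(rng: np.random.Generator, n: int, width_px: float) -> np.ndarray:
    """White noise passed through a Gaussian kernel and renormalized to
    unit variance (so `sigma` keeps its meaning for correlated noise)."""
    noise = rng.standard_normal((n, n))
    if width_px <= 0:
        return noise
    smoothed = gaussian_filter(noise, width_px, mode="wrap")
    impulse = np.zeros((n, n))
    impulse[n // 2, n // 2] = 1.0
    kernel = gaussian_filter(impulse, width_px, mode="wrap")
    norm = float(np.sqrt(np.sum(kernel**2)))
    return smoothed / norm


def make_background(
    n_pixels: int,
    mean_hu: float,
    sigma: float,
    seed: int,
    *,
    spacing_mm: float = PatchGeometry.spacing_mm,
    corr_px: float = 0.0,
) -> ImagePatch:
    """Homogeneous background patch with Gaussian noise about ``mean_hu``.

    Deterministic for a fixed ``seed``. ``corr_px > 0`` draws correlated
    noise (Gaussian kernel of that width, variance-renormalized); the
    default is white noise.
    """
    if n_pixels < 8:
        raise InvalidDesignError(f"n_pixels must be >= 8, got {n_pixels}")
    if sigma < 0:
        raise InvalidDesignError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if sigma == 0:
        pixels = np.full((n_pixels, n_pixels), mean_hu, dtype=np.float64)
    else:
        pixels = mean_hu + sigma * _correlated_unit_noise(rng, n_pixels, corr_px)
    return ImagePatch(pixels=pixels, spacing_mm=spacing_mm)


def _disk_coverage(
    n_pixels: int,
    spacing_mm: float,
    center_mm: tuple[float, float],
    radius_mm: float,
    supersample: int = 4,
) -> np.ndarray:
    """Per-pixel covered-area fraction of a disk, by ``supersample``^2
    subpixel sampling restricted to the disk's bounding box."""
    cx, cy = center_mm
    lo_px = max(0, int(np.floor((cx - radius_mm) / spacing_mm)) - 1)
    hi_px = min(n_pixels, int(np.ceil((cx + radius_mm) / spacing_mm)) + 1)
    lo_py = max(0, int(np.floor((cy - radius_mm) / spacing_mm)) - 1)
    hi_py = min(n_pixels, int(np.ceil((cy + radius_mm) / spacing_mm)) + 1)
    coverage = np.zeros((n_pixels, n_pixels))
    if hi_px <= lo_px or hi_py <= lo_py:
        return coverage
    sub = (np.arange(supersample) + 0.5) / supersample
    xs = (lo_px + np.add.outer(np.arange(hi_px - lo_px), sub).ravel()) * spacing_mm
    ys = (lo_py + np.add.outer(np.arange(hi_py - lo_py), sub).ravel()) * spacing_mm
    dx2 = (xs - cx) ** 2
    dy2 = (ys - cy) ** 2
    inside = (dy2[:, None] + dx2[None, :]) <= radius_mm**2
    block = inside.reshape(
        hi_py - lo_py, supersample, hi_px - lo_px, supersample
    ).mean(axis=(1, 3))
    coverage[lo_py:hi_py, lo_px:hi_px] = block
    return coverage


def render_object(patch: ImagePatch, spec: ObjectSpec) -> ImagePatch:
    """Add a circular object to a patch (returns a new patch).

    Pixels fully inside the disk are incremented by ``contrast_hu``;
    boundary pixels by the covered-area fraction (4x-per-axis subpixel
    anti-aliasing). The disk must lie entirely inside the patch.
    """
    if not spec.present:
        raise PlacementError("render_object requires spec.present")
    radius = spec.diameter_mm / 2.0
    cx, cy = spec.center_mm
    side = patch.side_mm
    if not (radius <= cx <= side - radius and radius <= cy <= side - radius):
        raise PlacementError(
            f"disk (center=({cx:.2f}, {cy:.2f}) mm, r={radius:.2f} mm) "
            f"does not fit inside a {side:.1f} mm patch"
        )
    coverage = _disk_coverage(patch.n_pixels, patch.spacing_mm, (cx, cy), radius)
    out = patch.pixels.astype(np.float64) + spec.contrast_hu * coverage
    return ImagePatch(pixels=out, spacing_mm=patch.spacing_mm)


def case_seed_for(global_seed: int, index: int) -> int:
    """Per-case RNG seed from a global seed and a case counter.

    Uses numpy's SeedSequence entropy pooling so that nearby (seed,
    index) pairs give statistically independent streams; the result is
    folded below 2^31 so it round-trips through any integer column.
    """
    ss = np.random.SeedSequence((int(global_seed), int(index)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def render_case(
    seed: int,
    condition: AcquisitionCondition,
    model: NoiseModel,
    obj: ObjectSpec,
    geometry: PatchGeometry = PatchGeometry(),
) -> ImagePatch:
    """Render one case deterministically from its recorded seed.

    The noise field is drawn at the condition's nominal sigma; for
    ADMIRE, the (already rescaled) noise is additionally smoothed with
    ``model.smooth_px`` before the object is added, so the object edge
    profile itself stays reconstruction-independent.
    """
    sigma = noise_sigma_for(condition, model)
    rng = np.random.default_rng(seed)
    noise = _correlated_unit_noise(rng, geometry.n_pixels, model.corr_px)
    if condition.recon == "ADMIRE" and model.smooth_px > 0:
        noise = gaussian_filter(noise * sigma, model.smooth_px)
    else:
        noise = noise * sigma
    patch = ImagePatch(
        pixels=geometry.mean_hu + noise, spacing_mm=geometry.spacing_mm
    )
    if obj.present:
        patch = render_object(patch, obj)
    return patch


def _draw_center(
    rng: np.random.Generator, radius_mm: float, side_mm: float
) -> tuple[float, float]:
    lo, hi = radius_mm, side_mm - radius_mm
    if hi < lo:
        raise PlacementError(
            f"object of radius {radius_mm} mm cannot fit in {side_mm} mm patch"
        )
    return (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))


def _object_from_row(row) -> ObjectSpec:
    if not row.present:
        return ObjectSpec(present=False)
    return ObjectSpec(
        present=True,
        diameter_mm=row.diameter_mm,
        contrast_hu=row.contrast_hu,
        center_mm=(row.center_x_mm, row.center_y_mm),
    )


def render_manifest(
    manifest: pd.DataFrame,
    model: NoiseModel,
    geometry: PatchGeometry = PatchGeometry(),
) -> np.ndarray:
    """Render every manifest row; rows are pure functions of their fields."""
    images = np.empty(
        (len(manifest), geometry.n_pixels, geometry.n_pixels), dtype=np.float32
    )
    for i, row in enumerate(manifest.itertuples(index=False)):
        condition = AcquisitionCondition(mas=row.mas, recon=row.recon)
        images[i] = render_case(
            row.seed, condition, model, _object_from_row(row), geometry
        ).pixels
    return images


def generate_training_set(
    n_images: int = 10_000,
    size_range_mm: tuple[float, float] = (3.0, 20.0),
    contrast_range_hu: tuple[float, float] = (5.0, 30.0),
    condition: AcquisitionCondition = AcquisitionCondition(mas=200.0, recon="FBP"),
    model: NoiseModel = NoiseModel(),
    seed: int = 0,
    geometry: PatchGeometry = PatchGeometry(),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Training material: one acquisition condition, binary ground truth.

    Exactly ``n_images / 2`` patches contain a single object with
    diameter ~ U(size_range) and contrast ~ U(contrast_range) at a
    uniform in-bounds center; the other half are object-absent. Order
    is a seeded shuffle. Returns ``(manifest, images)`` with images
    aligned to manifest rows.
    """
    if n_images <= 0 or n_images % 2 != 0:
        raise InvalidDesignError(f"n_images must be even and > 0, got {n_images}")
    design_rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xD351)))
    n_present = n_images // 2
    present = np.zeros(n_images, dtype=bool)
    present[:n_present] = True
    design_rng.shuffle(present)

    rows = []
    for i in range(n_images):
        rec: dict = {
            "case_id": f"train-{i:05d}",
            "split": "train",
            "present": bool(present[i]),
            "diameter_mm": np.nan,
            "contrast_hu": np.nan,
            "center_x_mm": np.nan,
            "center_y_mm": np.nan,
            "mas": condition.mas,
            "recon": condition.recon,
            "seed": case_seed_for(seed, i),
        }
        if present[i]:
            d = float(design_rng.uniform(*size_range_mm))
            c = float(design_rng.uniform(*contrast_range_hu))
            cx, cy = _draw_center(design_rng, d / 2.0, geometry.side_mm)
            rec.update(
                diameter_mm=d, contrast_hu=c, center_x_mm=cx, center_y_mm=cy
            )
        rows.append(rec)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    images = render_manifest(manifest, model, geometry)
    return manifest, images


def generate_test_set(
    per_cell_present: int = 20,
    per_cell_absent: int = 20,
    sizes_mm: Sequence[float] = (5.0, 9.0),
    contrast_hu: float = 10.0,
    doses: Sequence[float] = (200.0, 100.0, 50.0, 26.0),
    recons: Sequence[str] = RECON_LABELS,
    model: NoiseModel = NoiseModel(),
    seed: int = 0,
    geometry: PatchGeometry = PatchGeometry(),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Test material: full dose x reconstruction x size factorial.

    Every cell holds exactly ``per_cell_present`` object-present and
    ``per_cell_absent`` object-absent patches; each present patch
    carries a single object of the cell's size at ``contrast_hu`` (+10
    HU default) at a random in-bounds center. Object-absent rows record
    the cell's nominal ``diameter_mm`` so that the factorial stratum of
    every image is recoverable from the manifest; their contrast and
    center are NaN. Defaults give the study's 640-image design
    (40 x 2 recons x 4 doses x 2 sizes).
    """
    if per_cell_present <= 0 or per_cell_absent < 0:
        raise InvalidDesignError("per-cell counts must be positive")
    if not (len(sizes_mm) and len(doses) and len(recons)):
        raise InvalidDesignError("sizes_mm, doses and recons must be non-empty")
    design_rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x7E57)))
    rows = []
    index = 0
    for mas, recon, size in product(doses, recons, sizes_mm):
        cell = f"{mas:g}mAs-{recon}-{size:g}mm"
        for kind, count in (("p", per_cell_present), ("a", per_cell_absent)):
            for j in range(count):
                rec = {
                    "case_id": f"test-{cell}-{kind}{j:03d}",
                    "split": "test",
                    "present": kind == "p",
                    "diameter_mm": float(size),
                    "contrast_hu": np.nan,
                    "center_x_mm": np.nan,
                    "center_y_mm": np.nan,
                    "mas": float(mas),
                    "recon": recon,
                    "seed": case_seed_for(seed, index),
                }
                if kind == "p":
                    cx, cy = _draw_center(design_rng, size / 2.0, geometry.side_mm)
                    rec.update(
                        contrast_hu=float(contrast_hu), center_x_mm=cx, center_y_mm=cy
                    )
                rows.append(rec)
                index += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    images = render_manifest(manifest, model, geometry)
    return manifest, images
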