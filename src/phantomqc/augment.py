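"""Noise-based training-set augmentation.

Two families of modified images widen the conspicuity range of a QC
archive whose images all sit near the standard dose:

* degraded images: a weighted mean of a source image with a mosaic of
  randomly sampled 10x10-pixel patches from a target-free wax noise
  template, the template first rescaled to the source's wax-area mean
  (mixing weights 30-80% in 5% steps, ten images per weight -> 110
  degraded images per device);
* noise-reduced images: pixel averages of 2, 3, 4 or K (5-20) aligned
  acquisitions, thirty images per level -> 120 improved images per
  device.  Alignment recovers a small rotation on a 0.05-degree grid by
  matching predefined microcalcification landmarks, and the final image
  is produced by a single rotation of the original (no chained
  interpolations).

A random +-3 degree rotation of each training sub-image provides the
final augmentation applied during corpus assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (AlignmentFailedError, DegenerateTemplateError,
                     InvalidArgumentError)
from .phantom_synth import PhantomImage
from .preprocess import SubImage, WaxImage

PATCH_SIZE = 10

from .phantom_synth import DEFAULT_LAYOUT as _LAYOUT

#: fractional wax positions of the three most conspicuous speck groups,
#: the default landmarks for rotational alignment
DEFAULT_ALIGNMENT_LANDMARKS = tuple(_LAYOUT.cell_center(p) for p in (7, 8, 9))


def _default_weights() -> tuple:
    return tuple(np.round(np.arange(0.30, 0.801, 0.05), 2))


@dataclass
class AugmentPlan:
    """Counts and parameters of one device's augmentation campaign."""

    mixing_weights: tuple = field(default_factory=_default_weights)
    images_per_weight: int = 10
    averaging_levels: tuple = (2, 3, 4, 8)
    images_per_level: int = 30
    rotation_range_deg: float = 3.0
    alignment_step_deg: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for w in self.mixing_weights:
            if not 0.0 < w < 1.0:
                raise InvalidArgumentError(f"mixing weight {w} outside (0, 1)")
        k = max(self.averaging_levels)
        if not 2 <= k <= 20:
            raise InvalidArgumentError("averaging levels must lie in [2, 20]")


@dataclass
class NoiseTemplate:
    """A target-free wax crop used as the noise source for degradation."""

    pixels: np.ndarray
    device_id: str = ""
    patch_size: int = PATCH_SIZE

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or min(p.shape) < self.patch_size:
            raise InvalidArgumentError(
                f"template must be at least {self.patch_size} px in both axes")


def _rects_intersect(a, b) -> bool:
    ar0, ac0, ar1, ac1 = a
    br0, bc0, br1, bc1 = b
    return not (ar1 <= br0 or br1 <= ar0 or ac1 <= bc0 or bc1 <= ac0)


def build_noise_template(wax: WaxImage, region: tuple[int, int, int, int],
                         target_squares: list | None = None,
                         device_id: str = "") -> NoiseTemplate:
    """Crop a noise template from the wax, refusing regions that touch any
    configured target square.  ``region`` is (r0, c0, r1, c1) in wax pixels;
    ``target_squares`` are fractional (row0, col0, size) rectangles."""
    h, w = wax.pixels.shape
    r0, c0, r1, c1 = region
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise InvalidArgumentError("template region outside wax bounds")
    if target_squares:
        for fr, fc, fs in target_squares:
            size = fs * max(h, w)
            sq = (fr * h, fc * w, fr * h + size, fc * w + size)
            if _rects_intersect((r0, c0, r1, c1), sq):
                raise InvalidArgumentError(
                    "template region intersects a target square")
    return NoiseTemplate(pixels=wax.pixels[r0:r1, c0:c1].copy(),
                         device_id=device_id or wax.source_id)


def sample_patch_mosaic(template: NoiseTemplate, shape: tuple[int, int],
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Tile an array of the requested shape from randomly drawn (with
    replacement) 10x10 patches of the template; edge tiles are cropped."""
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise InvalidArgumentError("mosaic shape must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ps = template.patch_size
    th, tw = template.pixels.shape
    n_pr, n_pc = th // ps, tw // ps  # full non-overlapping tiling of the template
    out = np.empty((rows, cols), dtype=np.float64)
    for i in range(0, rows, ps):
        for j in range(0, cols, ps):
            pi = int(rng.integers(0, n_pr))
            pj = int(rng.integers(0, n_pc))
            patch = template.pixels[pi * ps:(pi + 1) * ps, pj * ps:(pj + 1) * ps]
            hi = min(ps, rows - i)
            wj = min(ps, cols - j)
            out[i:i + hi, j:j + wj] = patch[:hi, :wj]
    return out


def degrade_image(image: PhantomImage, template: NoiseTemplate, w: float,
                  seed: int | np.random.Generator = 0,
                  wax_bounds: tuple[int, int, int, int] | None = None,
                  ) -> PhantomImage:
    """Weighted mean of an image with a mean-matched noise mosaic.

    The mosaic is rescaled so its mean equals the image's wax-area mean
    (the whole image when ``wax_bounds`` is None), which preserves the
    wax mean for every mixing weight ``w`` in [0, 1].
    """
    if not 0.0 <= w <= 1.0:
        raise InvalidArgumentError("mixing weight must be in [0, 1]")
    pix = np.asarray(image.pixels, dtype=np.float64)
    if w == 0.0:
        return PhantomImage(pixels=pix.copy(), pixel_size_um=image.pixel_size_um,
                            device_id=image.device_id, intent=image.intent,
                            dose_factor=image.dose_factor)
    mosaic = sample_patch_mosaic(template, pix.shape, seed)
    m_mean = mosaic.mean()
    if m_mean == 0:
        raise DegenerateTemplateError("noise template mean is zero")
    if wax_bounds is not None:
        r0, c0, r1, c1 = wax_bounds
        ref_mean = pix[r0:r1, c0:c1].mean()
    else:
        ref_mean = pix.mean()
    mosaic *= ref_mean / m_mean
    out = (1.0 - w) * pix + w * mosaic
    return PhantomImage(pixels=out, pixel_size_um=image.pixel_size_um,
                        device_id=image.device_id, intent=image.intent,
                        dose_factor=image.dose_factor)


def generate_degraded_set(images: list[PhantomImage], template: NoiseTemplate,
                          plan: AugmentPlan,
                          wax_bounds: tuple | None = None,
                          ) -> list[tuple[PhantomImage, float]]:
    """One degradation campaign: ``images_per_weight`` outputs per mixing
    weight, each built from a randomly chosen source image.  Returns
    (image, weight) pairs; the default plan yields 110 per device."""
    if not images:
        raise InvalidArgumentError("need at least one source image")
    rng = np.random.default_rng(plan.seed)
    out = []
    for w in plan.mixing_weights:
        for _ in range(plan.images_per_weight):
            src = images[int(rng.integers(0, len(images)))]
            out.append((degrade_image(src, template, float(w), rng,
                                      wax_bounds=wax_bounds), float(w)))
    return out


def _detect_landmarks(pix: np.ndarray, landmarks_frac: list[tuple[float, float]],
                      window_frac: float = 0.04) -> np.ndarray:
    """Locate bright specks near expected fractional positions.

    Returns an (n, 2) array of (row, col) peak coordinates; raises
    ``AlignmentFailedError`` when a peak does not stand out of the local
    background."""
    h, w = pix.shape
    sm = ndimage.gaussian_filter(pix, 1.5)
    win = max(int(window_frac * min(h, w)), 4)
    found = []
    for fr, fc in landmarks_frac:
        r, c = int(fr * h), int(fc * w)
        r0, r1 = max(0, r - win), min(h, r + win + 1)
        c0, c1 = max(0, c - win), min(w, c + win + 1)
        local = sm[r0:r1, c0:c1]
        peak = np.unravel_index(np.argmax(local), local.shape)
        # robust z: MAD-based scale so the speck itself does not inflate
        # the background estimate
        med = np.median(local)
        mad = np.median(np.abs(local - med))
        z = (local[peak] - med) / max(1.4826 * mad, 1e-12)
        if z < 5.5:
            raise AlignmentFailedError("landmark speck not detectable")
        # subpixel refinement: intensity-weighted centroid around the peak
        pr, pc = r0 + peak[0], c0 + peak[1]
        rr0, rr1 = max(0, pr - 4), min(h, pr + 5)
        cc0, cc1 = max(0, pc - 4), min(w, pc + 5)
        blob = sm[rr0:rr1, cc0:cc1] - np.median(local)
        blob = np.clip(blob, 0, None)
        ri, ci = np.mgrid[rr0:rr1, cc0:cc1]
        total = blob.sum()
        if total > 0:
            found.append(((blob * ri).sum() / total, (blob * ci).sum() / total))
        else:
            found.append((float(pr), float(pc)))
    return np.asarray(found, dtype=np.float64)


def align_by_specks(reference: WaxImage, moving: WaxImage,
                    landmarks_frac: list[tuple[float, float]],
                    step_deg: float = 0.05, search_deg: float = 2.0,
                    ) -> tuple[float, WaxImage]:
    """Recover the small rotation between two wax images from speck landmarks.

    Landmark positions detected in the moving image are rotated about the
    image centre over a +-``search_deg`` grid with ``step_deg`` spacing;
    the angle minimising the summed displacement to the reference
    landmarks is applied once to the original moving image.
    """
    ref_pts = _detect_landmarks(reference.pixels, landmarks_frac)
    mov_pts = _detect_landmarks(moving.pixels, landmarks_frac)
    h, w = moving.pixels.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    n_steps = int(round(search_deg / step_deg))
    angles = step_deg * np.arange(-n_steps, n_steps + 1)  # exact 0 on the grid
    rel = mov_pts - center
    best_angle, best_cost = 0.0, np.inf
    for a in angles:
        t = np.deg2rad(a)
        # rotating an image by +a deg moves a point p - c to
        # [[cos, -sin], [sin, cos]] @ (p - c) in (row, col) coordinates
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        moved = rel @ rot.T + center
        cost = np.linalg.norm(moved - ref_pts, axis=1).sum()
        if cost < best_cost:
            best_cost, best_angle = cost, float(a)
    aligned = ndimage.rotate(moving.pixels, best_angle, reshape=False,
                             order=1, mode="nearest")
    out = WaxImage(pixels=aligned, crop_bounds=moving.crop_bounds,
                   rotation_applied=moving.rotation_applied,
                   masked_regions=list(moving.masked_regions),
                   warnings=list(moving.warnings), source_id=moving.source_id)
    return best_angle, out


def average_images(images: list[WaxImage]) -> WaxImage:
    """Pixel-wise arithmetic mean of aligned wax images."""
    if len(images) < 2:
        raise InvalidArgumentError("need at least two images to average")
    shape = images[0].pixels.shape
    for im in images[1:]:
        if im.pixels.shape != shape:
            raise InvalidArgumentError("images must share a shape")
    mean = np.mean([im.pixels for im in images], axis=0)
    first = images[0]
    return WaxImage(pixels=mean, crop_bounds=first.crop_bounds,
                    rotation_applied=first.rotation_applied,
                    masked_regions=list(first.masked_regions),
                    warnings=list(first.warnings), source_id=first.source_id)


def generate_averaged_set(images: list[WaxImage], plan: AugmentPlan,
                          ) -> list[tuple[WaxImage, int]]:
    """One noise-reduction campaign: ``images_per_level`` outputs per
    averaging level, each the mean of randomly chosen acquisitions.
    Returns (image, level) pairs; the default plan yields 120 per device."""
    if len(images) < 2:
        raise InvalidArgumentError("need at least two source images")
    rng = np.random.default_rng(plan.seed + 1)
    out = []
    for level in plan.averaging_levels:
        for _ in range(plan.images_per_level):
            idx = rng.integers(0, len(images), size=level)
            out.append((average_images([images[i] for i in idx]), int(level)))
    return out


def rotation_augment(sub: SubImage, seed: int | np.random.Generator = 0,
                     range_deg: float = 3.0) -> SubImage:
    """Rotate a sub-image by an angle uniform on [-range_deg, range_deg],
    bilinear interpolation, re-clipped to [0, 1]."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angle = float(rng.uniform(-range_deg, range_deg))
    rotated = ndimage.rotate(sub.pixels, angle, reshape=False, order=1,
                             mode="nearest")
    return SubImage(pixels=np.clip(rotated, 0.0, 1.0), position=sub.position,
                    source_id=sub.source_id)
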