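"""Raw phantom image -> 16 normalized 128x128 target sub-images.

The chain mirrors routine QC image preparation: locate the phantom on the
open-field background by its signal intensity, crop the wax insert from
the strong intensity transitions along each axis, rotate to canonical
orientation using the largest mass, replace the burned-in phantom name
with matched noise, cut 16 target squares at configured wax-relative
locations, remove low-frequency background with a 2-D polynomial fit
(order 5 for fibres, order 1 for speck groups and masses), and min-max
scale each patch to [0, 1] at 128x128.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (ConstantPatchError, InvalidArgumentError,
                     NoPhantomDetectedError, WaxNotFoundError)
from .phantom_synth import DEFAULT_LAYOUT, PhantomImage

SUBIMAGE_SIZE = 128


def _default_squares() -> list[tuple[float, float, float]]:
    return [DEFAULT_LAYOUT.target_square(p) for p in range(1, 17)]


@dataclass
class PreprocessConfig:
    """Wax-relative geometry driving sub-image extraction.

    Target squares are fractional (row0, col0, size) rectangles of the wax
    area so one configuration serves every pixel size.  ``m1_quadrant`` is
    the (row, col) half-plane (0 = top/left, 1 = bottom/right) where the
    largest mass must sit after orientation correction.
    """

    target_squares: list = field(default_factory=_default_squares)
    poly_order_fibre: int = 5
    poly_order_other: int = 1
    name_mask_region: tuple = (0.0, 0.30, 0.09, 0.40)
    m1_quadrant: tuple = (1, 1)
    min_contrast_margin: float = 0.10  # fraction of dynamic range
    profile_smooth_px: int = 5

    def __post_init__(self) -> None:
        if len(self.target_squares) != 16:
            raise InvalidArgumentError("need exactly 16 target squares")
        for sq in self.target_squares:
            if len(sq) != 3 or sq[2] <= 0:
                raise InvalidArgumentError(f"degenerate target square {sq}")
        if self.poly_order_fibre < 0 or self.poly_order_other < 0:
            raise InvalidArgumentError("polynomial orders must be >= 0")


@dataclass
class WaxImage:
    """The cropped wax insert and a record of the transforms applied."""

    pixels: np.ndarray
    crop_bounds: tuple[int, int, int, int]  # (r0, c0, r1, c1) in source coords
    rotation_applied: int = 0
    masked_regions: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    source_id: str = ""


@dataclass
class SubImage:
    """A unit-scaled square patch tied to one of the 16 target positions."""

    pixels: np.ndarray
    position: int
    source_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise InvalidArgumentError("sub-image must be square")
        if not 1 <= self.position <= 16:
            raise InvalidArgumentError("position must be 1..16")
        if p.size and (p.min() < -1e-9 or p.max() > 1 + 1e-9):
            raise InvalidArgumentError("sub-image values must lie in [0, 1]")


def extract_phantom(image: PhantomImage,
                    config: PreprocessConfig | None = None,
                    ) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Crop the phantom block from the full radiograph.

    The phantom is the largest contiguous region whose intensity differs
    from the open-field background; returns the crop and its bounding box
    (r0, c0, r1, c1) in source coordinates.
    """
    config = config or PreprocessConfig()
    pix = np.asarray(image.pixels, dtype=np.float64)
    if pix.size == 0 or not np.all(np.isfinite(pix)):
        raise InvalidArgumentError("image pixels must be non-empty and finite")
    lo, hi = np.percentile(pix, [1, 99])
    if hi - lo < config.min_contrast_margin * max(abs(hi), 1.0):
        raise NoPhantomDetectedError("image has no region distinct from background")
    from skimage.filters import threshold_otsu

    thr = threshold_otsu(pix)
    mask = pix > thr
    labels, n = ndimage.label(mask)
    if n == 0:
        raise NoPhantomDetectedError("no bright region found")
    sizes = ndimage.sum_labels(np.ones_like(pix), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    rows, cols = np.where(labels == best)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    if (r1 - r0) * (c1 - c0) < 0.01 * pix.size:
        raise NoPhantomDetectedError("candidate region implausibly small")
    return pix[r0:r1, c0:c1], (r0, c0, r1, c1)


def _axis_transitions(profile: np.ndarray, smooth: int) -> tuple[int, int] | None:
    """Locate the strongest rising/falling intensity-change pair along an axis."""
    sm = ndimage.uniform_filter1d(profile, max(smooth, 1), mode="nearest")
    grad = np.gradient(sm)
    scale = np.max(np.abs(grad)) if grad.size else 0.0
    span = sm.max() - sm.min()
    mean_abs = max(abs(sm.mean()), 1e-12)
    if span < 0.02 * mean_abs:
        return None  # flat profile: no transitions to find
    n = len(grad)
    mid = n // 2
    left = int(np.argmax(grad[:mid]))
    right = mid + int(np.argmin(grad[mid:]))
    if grad[left] < 0.25 * scale or -grad[right] < 0.25 * scale:
        return None

    def _centroid(idx: int, sign: float) -> float:
        # smoothing spreads a step edge into a plateau of near-equal
        # gradient; its centroid marks the true transition
        g = sign * grad
        thr = 0.8 * g[idx]
        lo = idx
        while lo > 0 and g[lo - 1] >= thr:
            lo -= 1
        hi = idx
        while hi < n - 1 and g[hi + 1] >= thr:
            hi += 1
        window = np.arange(lo, hi + 1)
        return float(np.average(window, weights=g[lo:hi + 1]))

    l_idx = int(round(_centroid(left, 1.0)))
    r_idx = int(round(_centroid(right, -1.0))) + 1
    if r_idx - l_idx < 2:
        return None
    # the wax insert sits interior to the phantom; edges hugging the crop
    # border are artefacts (e.g. the burned-in name), not the insert
    if l_idx < 0.02 * n or r_idx > 0.98 * n:
        return None
    # a genuine insert is a level shift, not a noise excursion: the
    # interior plateau must stand clear of the exterior
    inside = sm[l_idx:r_idx].mean()
    outside = np.concatenate([sm[:l_idx], sm[r_idx:]])
    if outside.size and (inside - outside.mean()) < 0.25 * span:
        return None
    return l_idx, r_idx


def extract_wax_area(phantom: np.ndarray,
                     config: PreprocessConfig | None = None,
                     source_id: str = "") -> WaxImage:
    """Crop the wax insert using row/column mean-profile transitions.

    A pre-cropped wax-only input (flat profiles at a plausible intensity
    plateau) is returned unchanged; an input with structure but no
    detectable transition pair raises ``WaxNotFoundError``.
    """
    config = config or PreprocessConfig()
    pix = np.asarray(phantom, dtype=np.float64)
    if pix.ndim != 2 or min(pix.shape) < 8:
        raise InvalidArgumentError("phantom crop must be a 2-D array")
    smooth = max(config.profile_smooth_px, min(pix.shape) // 50)
    rows = _axis_transitions(pix.mean(axis=1), smooth)
    cols = _axis_transitions(pix.mean(axis=0), smooth)

    if rows is None and cols is None:
        # flat everywhere: either an already-cropped wax area or pure noise
        sm_r = ndimage.uniform_filter1d(pix.mean(axis=1), smooth, mode="nearest")
        rel_var = sm_r.std() / max(abs(sm_r.mean()), 1e-12)
        if rel_var < 0.05:
            return WaxImage(pixels=pix.copy(),
                            crop_bounds=(0, 0, pix.shape[0], pix.shape[1]),
                            source_id=source_id)
        raise WaxNotFoundError("no intensity plateau resembling a wax insert")

    r0, r1 = rows if rows is not None else (0, pix.shape[0])
    c0, c1 = cols if cols is not None else (0, pix.shape[1])
    if r1 - r0 < 0.2 * pix.shape[0] or c1 - c0 < 0.2 * pix.shape[1]:
        raise WaxNotFoundError("detected wax region implausibly small")
    return WaxImage(pixels=pix[r0:r1, c0:c1].copy(),
                    crop_bounds=(r0, c0, r1, c1), source_id=source_id)


def _mass_response(pix: np.ndarray) -> np.ndarray:
    """Band-pass response tuned to the largest mass's spatial scale."""
    h, w = pix.shape
    sigma = max(min(h, w) * 0.02, 2.0)
    fine = ndimage.gaussian_filter(pix, sigma)
    coarse = ndimage.gaussian_filter(pix, 4 * sigma)
    return fine - coarse


def orient_by_largest_mass(wax: WaxImage,
                           config: PreprocessConfig | None = None) -> WaxImage:
    """Rotate the wax crop (in 90-degree steps) so the largest mass lands in
    its configured quadrant.  If no blob stands out, the input is returned
    with an ``orientation-ambiguous`` warning recorded."""
    config = config or PreprocessConfig()
    pix = wax.pixels
    resp = _mass_response(pix)
    # ignore a border band where cropping artefacts dominate
    b = max(min(pix.shape) // 20, 1)
    inner = resp[b:-b, b:-b]
    peak = np.unravel_index(np.argmax(inner), inner.shape)
    z = (inner[peak] - inner.mean()) / max(inner.std(), 1e-12)
    if z < 4.0:
        out = WaxImage(pixels=pix.copy(), crop_bounds=wax.crop_bounds,
                       rotation_applied=0,
                       masked_regions=list(wax.masked_regions),
                       warnings=list(wax.warnings) + ["orientation-ambiguous"],
                       source_id=wax.source_id)
        return out
    r, c = peak[0] + b, peak[1] + b
    quad = (int(r >= pix.shape[0] / 2), int(c >= pix.shape[1] / 2))
    target = tuple(config.m1_quadrant)
    # number of counter-clockwise 90-degree turns (np.rot90 convention)
    # mapping the observed quadrant onto the configured one
    order = {(0, 0): 0, (0, 1): 1, (1, 1): 2, (1, 0): 3}  # CCW quadrant cycle
    k = (order[quad] - order[target]) % 4
    rotated = np.rot90(pix, k) if k else pix.copy()
    return WaxImage(pixels=rotated, crop_bounds=wax.crop_bounds,
                    rotation_applied=(90 * k) % 360,
                    masked_regions=list(wax.masked_regions),
                    warnings=list(wax.warnings), source_id=wax.source_id)


def mask_name_region(wax: WaxImage, config: PreprocessConfig | None = None,
                     seed: int = 0) -> WaxImage:
    """Replace the phantom-name area with noise matching the local wax.

    The fill is drawn from a normal distribution whose mean and variance
    are measured in a frame surrounding the masked rectangle, so the CNN
    cannot key on the burned-in text.
    """
    config = config or PreprocessConfig()
    pix = wax.pixels.copy()
    h, w = pix.shape
    fr0, fc0, fh, fw = config.name_mask_region
    r0, c0 = int(fr0 * h), int(fc0 * w)
    r1, c1 = r0 + int(fh * h), c0 + int(fw * w)
    if r0 == r1 or c0 == c1:
        return WaxImage(pixels=pix, crop_bounds=wax.crop_bounds,
                        rotation_applied=wax.rotation_applied,
                        masked_regions=list(wax.masked_regions),
                        warnings=list(wax.warnings), source_id=wax.source_id)
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise InvalidArgumentError("mask region outside wax bounds")
    pad = max((r1 - r0) // 2, (c1 - c0) // 8, 4)
    fr0_, fr1_ = max(0, r0 - pad), min(h, r1 + pad)
    fc0_, fc1_ = max(0, c0 - pad), min(w, c1 + pad)
    frame = pix[fr0_:fr1_, fc0_:fc1_].copy()
    inner = np.zeros(frame.shape, dtype=bool)
    inner[r0 - fr0_:r1 - fr0_, c0 - fc0_:c1 - fc0_] = True
    surround = frame[~inner]
    rng = np.random.default_rng(seed)
    pix[r0:r1, c0:c1] = rng.normal(surround.mean(), surround.std(),
                                   (r1 - r0, c1 - c0))
    return WaxImage(pixels=pix, crop_bounds=wax.crop_bounds,
                    rotation_applied=wax.rotation_applied,
                    masked_regions=list(wax.masked_regions) + [(r0, c0, r1, c1)],
                    warnings=list(wax.warnings), source_id=wax.source_id)


def split_subimages(wax: WaxImage, config: PreprocessConfig | None = None,
                    ) -> list[tuple[np.ndarray, int]]:
    """Cut the 16 configured target squares out of the wax crop.

    Squares exceeding the wax bounds are shifted inward and a warning is
    recorded on the wax image.  Overlapping squares are permitted.
    """
    config = config or PreprocessConfig()
    pix = wax.pixels
    h, w = pix.shape
    out = []
    for pos, (fr, fc, fs) in enumerate(config.target_squares, start=1):
        size = max(int(round(fs * max(h, w))), 2)
        size = min(size, h, w)
        r0 = int(round(fr * h))
        c0 = int(round(fc * w))
        r0c = min(max(r0, 0), h - size)
        c0c = min(max(c0, 0), w - size)
        if (r0c, c0c) != (r0, c0):
            wax.warnings.append(f"clamped-square-position-{pos}")
        out.append((pix[r0c:r0c + size, c0c:c0c + size].copy(), pos))
    return out


def _poly_basis(shape: tuple[int, int], order: int) -> np.ndarray:
    """Full bivariate polynomial basis of given total order on [-1, 1]^2."""
    yy = np.linspace(-1.0, 1.0, shape[0])[:, None] * np.ones((1, shape[1]))
    xx = np.ones((shape[0], 1)) * np.linspace(-1.0, 1.0, shape[1])[None, :]
    cols = [ (yy ** i * xx ** j).ravel()
             for i in range(order + 1) for j in range(order + 1 - i) ]
    return np.stack(cols, axis=1)


def detrend_background(patch: np.ndarray, position: int,
                       config: PreprocessConfig | None = None) -> np.ndarray:
    """Subtract a least-squares 2-D polynomial surface from a patch.

    Fibre positions (1..6) use the fifth-order surface; speck groups and
    masses (7..16) use first order.  Thin fibres near the phantom edge sit
    on stronger background non-uniformity, hence the higher order.
    """
    config = config or PreprocessConfig()
    p = np.asarray(patch, dtype=np.float64)
    if p.ndim != 2 or min(p.shape) < 8:
        raise InvalidArgumentError("patch must be at least 8x8")
    if not np.all(np.isfinite(p)):
        raise InvalidArgumentError("patch contains non-finite values")
    order = config.poly_order_fibre if position <= 6 else config.poly_order_other
    basis = _poly_basis(p.shape, order)
    coef, *_ = np.linalg.lstsq(basis, p.ravel(), rcond=None)
    return p - (basis @ coef).reshape(p.shape)


def to_model_input(patch: np.ndarray, position: int = 1,
                   source_id: str = "", size: int = SUBIMAGE_SIZE) -> SubImage:
    """Resize to ``size`` x ``size`` (bilinear) and min-max scale to [0, 1]."""
    p = np.asarray(patch, dtype=np.float64)
    if p.ndim != 2 or p.size == 0:
        raise InvalidArgumentError("patch must be a non-empty 2-D array")
    lo, hi = p.min(), p.max()
    if hi <= lo:
        raise ConstantPatchError("constant patch cannot be scaled to [0, 1]")
    from skimage.transform import resize

    resized = resize(p, (size, size), order=1, anti_aliasing=p.shape[0] > size,
                     preserve_range=True, mode="reflect")
    lo, hi = resized.min(), resized.max()
    scaled = (resized - lo) / (hi - lo)
    return SubImage(pixels=scaled.astype(np.float64), position=position,
                    source_id=source_id)


def preprocess_image(image: PhantomImage, config: PreprocessConfig | None = None,
                     seed: int = 0, source_id: str | None = None,
                     size: int = SUBIMAGE_SIZE) -> list[SubImage]:
    """Full chain: phantom crop -> wax crop -> orient -> mask -> 16 sub-images."""
    config = config or PreprocessConfig()
    sid = source_id if source_id is not None else image.device_id
    phantom, _ = extract_phantom(image, config)
    wax = extract_wax_area(phantom, config, source_id=sid)
    wax = orient_by_largest_mass(wax, config)
    wax = mask_name_region(wax, config, seed=seed)
    subs = []
    for patch, pos in split_subimages(wax, config):
        flat = detrend_background(patch, pos, config)
        subs.append(to_model_input(flat, position=pos, source_id=sid, size=size))
    return subs
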