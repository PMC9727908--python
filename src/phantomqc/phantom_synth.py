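"""Synthetic ACR mammography accreditation phantom images.

The ACR phantom holds 16 low-contrast targets in a wax insert: six fibres of
decreasing diameter, five microcalcification (speck) groups of decreasing
speck size, and five masses of decreasing thickness/diameter.  Daily QC
consists of radiographing the phantom and scoring how many targets of each
family are visible.  This module renders such images with a known,
dose-dependent ground truth so that every downstream stage (cropping,
sub-image extraction, augmentation, CNN training, scoring, statistics) can
be exercised without access to clinical QC archives.

The image model is intentionally simple:

* a bright phantom block on a darker open-field background,
* a brighter wax insert carrying a smooth low-frequency texture and a
  gentle intensity gradient (so background detrending has work to do),
* 16 additive targets with per-phantom geometry (fibre angles and speck
  cluster patterns differ between phantoms, as they do between real ACR
  phantoms),
* additive Gaussian noise whose variance is the sum of a fixed read-noise
  term and a quantum term scaling as 1/dose_factor.

Ground-truth visibility is assigned from the contrast-to-noise ratio
(target amplitude over noise standard deviation) with a hysteresis band:
CNR >= cnr_visible scores 1 point, >= cnr_barely scores 0.5, else 0.
Microcalcification groups are scored speck-by-speck through the ACR
counting rule (see :mod:`phantomqc.scoring`).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classes import POSITION_KINDS
from .errors import InvalidArgumentError
from .scoring import score_mc_group


@dataclass(frozen=True)
class DeviceProfile:
    """Acquisition characteristics of one mammography system.

    ``gaussian_sigma`` is the dose-independent read-noise standard deviation
    and ``quantum_gain`` scales the dose-dependent quantum-noise variance:
    ``var = gaussian_sigma**2 + quantum_gain * wax_level / dose_factor``.
    """

    device_id: str
    pixel_size_um: float
    detector_kind: str  # "FFDM" or "CR"
    gaussian_sigma: float = 40.0
    quantum_gain: float = 0.9
    name_overlay: tuple[float, float, float, float] | None = (0.015, 0.34, 0.05, 0.32)
    phantom_seed: int = 0

    def __post_init__(self) -> None:
        if not 50.0 <= self.pixel_size_um <= 100.0:
            raise InvalidArgumentError(
                f"pixel_size_um must be in [50, 100], got {self.pixel_size_um}")
        if self.detector_kind not in ("FFDM", "CR"):
            raise InvalidArgumentError(f"unknown detector kind {self.detector_kind!r}")
        if self.gaussian_sigma < 0:
            raise InvalidArgumentError("gaussian_sigma must be >= 0")
        if self.quantum_gain <= 0:
            raise InvalidArgumentError("quantum_gain must be > 0")


@dataclass(frozen=True)
class TargetSpec:
    """One embedded target: geometry, contrast, and (for specks) multiplicity."""

    kind: str  # fibre | mc_group | mass
    index: int
    center_mm: tuple[float, float]  # (row, col) in wax coordinates
    size_param: float  # fibre diameter / speck diameter / mass diameter, mm
    contrast: float  # additive intensity amplitude
    specks_per_group: int = 6


@dataclass
class PhantomLayout:
    """Geometry and intensity model of the synthetic phantom image.

    All physical dimensions are millimetres; the image is rendered at the
    device pixel size.  The 16 targets sit on a 4x4 grid inside the wax
    insert; the largest mass (m1) occupies the lower-right quadrant, which
    the orientation-correction step relies on.
    """

    image_size_mm: tuple[float, float] = (140.0, 120.0)
    phantom_origin_mm: tuple[float, float] = (10.0, 10.0)
    phantom_size_mm: tuple[float, float] = (110.0, 100.0)
    wax_origin_mm: tuple[float, float] = (25.0, 20.0)
    wax_size_mm: tuple[float, float] = (80.0, 80.0)
    background_level: float = 3000.0
    phantom_level: float = 8000.0
    wax_level: float = 10000.0
    texture_sigma_mm: float = 6.0
    texture_amplitude: float = 50.0
    gradient_amplitude: float = 120.0
    name_overlay_amplitude: float = -2500.0  # engraved (dark) lettering
    cnr_visible: float = 2.0
    cnr_barely: float = 1.0
    speck_jitter: float = 0.18  # deterministic per-speck contrast spread

    # 4x4 grid of target cells, fractional wax coordinates
    grid_row0: float = 0.10
    grid_col0: float = 0.06
    grid_step: float = 0.22
    square_size: float = 0.24

    fibre_diameters_mm: tuple = (1.56, 1.12, 0.89, 0.75, 0.54, 0.40)
    fibre_length_mm: float = 10.0
    fibre_contrasts: tuple = (500.0, 380.0, 300.0, 230.0, 170.0, 120.0)
    speck_diameters_mm: tuple = (0.54, 0.40, 0.32, 0.24, 0.16)
    speck_contrasts: tuple = (650.0, 500.0, 380.0, 260.0, 160.0)
    mass_diameters_mm: tuple = (9.0, 7.0, 5.5, 4.0, 2.5)
    mass_contrasts: tuple = (550.0, 430.0, 330.0, 240.0, 160.0)

    def cell_center(self, position: int) -> tuple[float, float]:
        """Fractional wax coordinates of the centre of a target cell (1..16)."""
        i, j = divmod(position - 1, 4)
        half = self.grid_step / 2.0
        return (self.grid_row0 + self.grid_step * i + half,
                self.grid_col0 + self.grid_step * j + half)

    def target_square(self, position: int) -> tuple[float, float, float]:
        """Fractional (row0, col0, size) of the sub-image square for a position."""
        rc, cc = self.cell_center(position)
        s = self.square_size
        return (rc - s / 2.0, cc - s / 2.0, s)

    def target_specs(self) -> list[TargetSpec]:
        specs = []
        for pos in range(1, 17):
            kind, idx = POSITION_KINDS[pos - 1]
            rc, cc = self.cell_center(pos)
            center = (rc * self.wax_size_mm[0], cc * self.wax_size_mm[1])
            if kind == "fibre":
                specs.append(TargetSpec(kind, idx, center,
                                        self.fibre_diameters_mm[idx - 1],
                                        self.fibre_contrasts[idx - 1]))
            elif kind == "mc_group":
                specs.append(TargetSpec(kind, idx, center,
                                        self.speck_diameters_mm[idx - 1],
                                        self.speck_contrasts[idx - 1]))
            else:
                specs.append(TargetSpec(kind, idx, center,
                                        self.mass_diameters_mm[idx - 1],
                                        self.mass_contrasts[idx - 1]))
        return specs


DEFAULT_LAYOUT = PhantomLayout()


@dataclass
class PhantomImage:
    """A rendered (or loaded) phantom radiograph plus acquisition metadata."""

    pixels: np.ndarray
    pixel_size_um: float
    device_id: str = "unknown"
    intent: str = "for_presentation"
    dose_factor: float = 1.0


@dataclass
class GroundTruth:
    """Known per-target visibility of a generated phantom image."""

    points: dict[int, float]  # position -> {0, 0.5, 1}
    speck_flags: dict[int, list[bool]]  # mc positions -> per-speck visibility
    dose_factor: float
    noise_sigma: float
    phantom_bbox_px: tuple[int, int, int, int]  # (r0, c0, r1, c1) in image coords
    wax_bbox_px: tuple[int, int, int, int]  # in image coords
    target_centers_px: dict[int, tuple[float, float]]  # wax-relative pixels
    target_amplitudes: dict[int, float]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["points"] = {str(k): v for k, v in d["points"].items()}
        d["speck_flags"] = {str(k): v for k, v in d["speck_flags"].items()}
        d["target_centers_px"] = {str(k): list(v) for k, v in d["target_centers_px"].items()}
        d["target_amplitudes"] = {str(k): v for k, v in d["target_amplitudes"].items()}
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            points={int(k): v for k, v in d["points"].items()},
            speck_flags={int(k): v for k, v in d["speck_flags"].items()},
            dose_factor=d["dose_factor"],
            noise_sigma=d["noise_sigma"],
            phantom_bbox_px=tuple(d["phantom_bbox_px"]),
            wax_bbox_px=tuple(d["wax_bbox_px"]),
            target_centers_px={int(k): tuple(v) for k, v in d["target_centers_px"].items()},
            target_amplitudes={int(k): v for k, v in d["target_amplitudes"].items()},
        )


def make_device_profiles(count: int, seed: int = 0) -> list[DeviceProfile]:
    """Create ``count`` distinct device profiles.

    FFDM systems draw pixel sizes from the 83-100 um range; when eight or
    more devices are requested exactly one of them is a 50 um CR system,
    mirroring a typical multi-vendor fleet.
    """
    if count < 1:
        raise InvalidArgumentError("count must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(count):
        if count >= 8 and i == count - 1:
            pixel, kind = 50.0, "CR"
        else:
            pixel, kind = float(rng.choice([83.0, 85.0, 90.0, 94.0, 100.0])), "FFDM"
        profiles.append(DeviceProfile(
            device_id=f"dev{i + 1:02d}",
            pixel_size_um=pixel,
            detector_kind=kind,
            gaussian_sigma=float(rng.uniform(30.0, 50.0)),
            quantum_gain=float(rng.uniform(0.7, 1.1)),
            phantom_seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return profiles


def _mm_to_px(mm: float, pixel_size_um: float) -> float:
    return mm * 1000.0 / pixel_size_um


def render_target(canvas: np.ndarray, spec: TargetSpec, pixel_size_um: float,
                  pattern_rng: np.random.Generator | None = None) -> np.ndarray:
    """Additively render one target onto a wax canvas (returns a new array).

    Fibres are anti-aliased line segments with a Gaussian cross-profile,
    masses are flat-topped disks with a Gaussian-tapered edge, and speck
    groups are clusters of small Gaussian blobs.  The peak added intensity
    equals ``spec.contrast``.
    """
    if spec.contrast == 0:
        return canvas.copy()
    rng = pattern_rng or np.random.default_rng(1234 + spec.index)
    out = canvas.astype(np.float64, copy=True)
    h, w = out.shape
    cr = _mm_to_px(spec.center_mm[0], pixel_size_um)
    cc = _mm_to_px(spec.center_mm[1], pixel_size_um)
    if not (0 <= cr < h and 0 <= cc < w):
        raise InvalidArgumentError("target footprint outside canvas")

    if spec.kind == "fibre":
        half_len = _mm_to_px(5.0, pixel_size_um)
        sigma = max(_mm_to_px(spec.size_param, pixel_size_um) / 2.355, 0.6)
        angle = rng.uniform(0, math.pi)
        ext = int(half_len + 4 * sigma + 2)
        r0, r1 = max(0, int(cr) - ext), min(h, int(cr) + ext + 1)
        c0, c1 = max(0, int(cc) - ext), min(w, int(cc) + ext + 1)
        rr, cc2 = np.mgrid[r0:r1, c0:c1].astype(np.float64)
        dr, dc = rr - cr, cc2 - cc
        ur, uc = math.cos(angle), math.sin(angle)
        t = dr * ur + dc * uc  # along-fibre coordinate
        d = -dr * uc + dc * ur  # across-fibre distance
        profile = np.exp(-0.5 * (d / sigma) ** 2)
        # soft caps at fibre ends
        endcap = np.clip((half_len - np.abs(t)) / sigma + 1.0, 0.0, 1.0)
        out[r0:r1, c0:c1] += spec.contrast * profile * endcap
    elif spec.kind == "mass":
        radius = _mm_to_px(spec.size_param, pixel_size_um) / 2.0
        edge = max(radius * 0.18, 1.0)
        ext = int(radius + 4 * edge + 2)
        r0, r1 = max(0, int(cr) - ext), min(h, int(cr) + ext + 1)
        c0, c1 = max(0, int(cc) - ext), min(w, int(cc) + ext + 1)
        rr, cc2 = np.mgrid[r0:r1, c0:c1].astype(np.float64)
        rad = np.hypot(rr - cr, cc2 - cc)
        # flat top with a Gaussian-tapered rim
        taper = np.where(rad <= radius, 1.0,
                         np.exp(-0.5 * ((rad - radius) / edge) ** 2))
        out[r0:r1, c0:c1] += spec.contrast * taper
    elif spec.kind == "mc_group":
        sigma = max(_mm_to_px(spec.size_param, pixel_size_um) / 2.355, 0.8)
        spread = _mm_to_px(4.0, pixel_size_um)
        n = spec.specks_per_group
        angles = np.linspace(0, 2 * math.pi, n, endpoint=False) + rng.uniform(0, 2 * math.pi)
        radii = spread * (0.55 + 0.45 * rng.random(n))
        for k, amp in enumerate(_speck_amplitudes(spec, rng=None)):
            # snap speck centres to pixel centres so peaks equal amplitudes
            sr = round(cr + radii[k] * math.cos(angles[k]))
            sc = round(cc + radii[k] * math.sin(angles[k]))
            ext = int(4 * sigma + 2)
            r0, r1 = max(0, sr - ext), min(h, sr + ext + 1)
            c0, c1 = max(0, sc - ext), min(w, sc + ext + 1)
            if r0 >= r1 or c0 >= c1:
                raise InvalidArgumentError("speck footprint outside canvas")
            rr, cc2 = np.mgrid[r0:r1, c0:c1].astype(np.float64)
            blob = np.exp(-0.5 * ((rr - sr) ** 2 + (cc2 - sc) ** 2) / sigma**2)
            out[r0:r1, c0:c1] += amp * blob
    else:
        raise InvalidArgumentError(f"unknown target kind {spec.kind!r}")
    return out


def _speck_amplitudes(spec: TargetSpec, rng=None,
                      jitter: float = 0.18) -> np.ndarray:
    """Deterministic per-speck amplitudes: a fixed +-jitter pattern around
    the group contrast, so partially-visible groups can occur."""
    n = spec.specks_per_group
    pattern = np.linspace(1.0 + jitter, 1.0 - jitter, n)
    return spec.contrast * pattern


def _background_model(profile: DeviceProfile, layout: PhantomLayout):
    """Noise-free, target-free image plus bounding boxes (analysis geometry)."""
    px = profile.pixel_size_um
    h = int(round(_mm_to_px(layout.image_size_mm[0], px)))
    w = int(round(_mm_to_px(layout.image_size_mm[1], px)))
    img = np.full((h, w), layout.background_level, dtype=np.float64)

    pr0 = int(round(_mm_to_px(layout.phantom_origin_mm[0], px)))
    pc0 = int(round(_mm_to_px(layout.phantom_origin_mm[1], px)))
    pr1 = pr0 + int(round(_mm_to_px(layout.phantom_size_mm[0], px)))
    pc1 = pc0 + int(round(_mm_to_px(layout.phantom_size_mm[1], px)))
    img[pr0:pr1, pc0:pc1] = layout.phantom_level

    wr0 = int(round(_mm_to_px(layout.wax_origin_mm[0], px)))
    wc0 = int(round(_mm_to_px(layout.wax_origin_mm[1], px)))
    wr1 = wr0 + int(round(_mm_to_px(layout.wax_size_mm[0], px)))
    wc1 = wc0 + int(round(_mm_to_px(layout.wax_size_mm[1], px)))
    img[wr0:wr1, wc0:wc1] = layout.wax_level

    # smooth per-phantom wax texture + gentle plane gradient
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(profile.phantom_seed)
    wh, ww = wr1 - wr0, wc1 - wc0
    sig = _mm_to_px(layout.texture_sigma_mm, px)
    tex = rng.standard_normal((wh, ww))
    tex = gaussian_filter(tex, sig, mode="reflect")
    std = tex.std()
    if std > 0:
        tex *= layout.texture_amplitude / std
    rr = np.linspace(-0.5, 0.5, wh)[:, None]
    cc = np.linspace(-0.5, 0.5, ww)[None, :]
    grad = layout.gradient_amplitude * (0.7 * rr + 0.3 * cc)
    img[wr0:wr1, wc0:wc1] += tex + grad
    return img, (pr0, pc0, pr1, pc1), (wr0, wc0, wr1, wc1)


def noise_sigma(profile: DeviceProfile, dose_factor: float,
                layout: PhantomLayout = DEFAULT_LAYOUT) -> float:
    """Noise standard deviation at wax level for a relative dose."""
    quantum_var = 0.0 if math.isinf(dose_factor) else (
        profile.quantum_gain * layout.wax_level / dose_factor)
    return math.sqrt(profile.gaussian_sigma**2 + quantum_var)


def _ground_truth_points(profile, dose_factor, layout):
    sigma = noise_sigma(profile, dose_factor, layout)
    points: dict[int, float] = {}
    flags: dict[int, list[bool]] = {}
    amps: dict[int, float] = {}
    for pos, spec in zip(range(1, 17), layout.target_specs()):
        amps[pos] = spec.contrast
        if spec.kind == "mc_group":
            speck_amps = _speck_amplitudes(spec, jitter=layout.speck_jitter)
            vis = [bool(a / sigma >= layout.cnr_visible) if sigma > 0 else True
                   for a in speck_amps]
            flags[pos] = vis
            points[pos] = score_mc_group(sum(vis))
        else:
            cnr = math.inf if sigma == 0 else spec.contrast / sigma
            if cnr >= layout.cnr_visible:
                points[pos] = 1.0
            elif cnr >= layout.cnr_barely:
                points[pos] = 0.5
            else:
                points[pos] = 0.0
    return points, flags, amps, sigma


def generate_phantom(profile: DeviceProfile, dose_factor: float, seed: int,
                     layout: PhantomLayout = DEFAULT_LAYOUT,
                     with_noise: bool = True,
                     with_targets: bool = True) -> tuple[PhantomImage, GroundTruth]:
    """Render one phantom acquisition and its ground truth.

    ``dose_factor`` scales exposure relative to a standard QC acquisition;
    the quantum noise variance scales as 1/dose_factor (``math.inf`` gives
    the noiseless limit).  ``with_noise=False`` / ``with_targets=False``
    expose the pure background model for calibration and testing.
    """
    if not dose_factor > 0:
        raise InvalidArgumentError("dose_factor must be > 0")
    img, pbox, wbox = _background_model(profile, layout)
    wr0, wc0, wr1, wc1 = wbox
    px = profile.pixel_size_um

    centers_px: dict[int, tuple[float, float]] = {}
    pattern_rng = np.random.default_rng(profile.phantom_seed + 17)
    if with_targets:
        wax = img[wr0:wr1, wc0:wc1]
        # attach the layout fibre length to specs via closure default
        for pos, spec in zip(range(1, 17), layout.target_specs()):
            wax = _render_with_length(wax, spec, px, pattern_rng, layout)
            centers_px[pos] = (_mm_to_px(spec.center_mm[0], px),
                               _mm_to_px(spec.center_mm[1], px))
        img[wr0:wr1, wc0:wc1] = wax

    if profile.name_overlay is not None and with_targets:
        _render_name_overlay(img, wbox, profile.name_overlay,
                             layout.name_overlay_amplitude, profile.phantom_seed)

    if with_noise:
        sigma = noise_sigma(profile, dose_factor, layout)
        if sigma > 0:
            rng = np.random.default_rng(seed)
            img = img + rng.normal(0.0, sigma, img.shape)

    points, flags, amps, sigma_gt = _ground_truth_points(profile, dose_factor, layout)
    gt = GroundTruth(points=points, speck_flags=flags, dose_factor=dose_factor,
                     noise_sigma=sigma_gt,
                     phantom_bbox_px=pbox, wax_bbox_px=wbox,
                     target_centers_px=centers_px, target_amplitudes=amps)
    image = PhantomImage(pixels=img, pixel_size_um=px, device_id=profile.device_id,
                         dose_factor=dose_factor)
    return image, gt


def _render_with_length(wax, spec, px, pattern_rng, layout):
    if spec.kind == "fibre":
        # reuse render_target with the layout's fibre half-length
        contrast = spec.contrast
        if contrast == 0:
            return wax
        out = wax.astype(np.float64, copy=True)
        h, w = out.shape
        cr = _mm_to_px(spec.center_mm[0], px)
        cc = _mm_to_px(spec.center_mm[1], px)
        if not (0 <= cr < h and 0 <= cc < w):
            raise InvalidArgumentError("target footprint outside canvas")
        half_len = _mm_to_px(layout.fibre_length_mm, px) / 2.0
        sigma = max(_mm_to_px(spec.size_param, px) / 2.355, 0.6)
        angle = pattern_rng.uniform(0, math.pi)
        ext = int(half_len + 4 * sigma + 2)
        r0, r1 = max(0, int(cr) - ext), min(h, int(cr) + ext + 1)
        c0, c1 = max(0, int(cc) - ext), min(w, int(cc) + ext + 1)
        rr, cc2 = np.mgrid[r0:r1, c0:c1].astype(np.float64)
        dr, dc = rr - cr, cc2 - cc
        ur, uc = math.cos(angle), math.sin(angle)
        t = dr * ur + dc * uc
        d = -dr * uc + dc * ur
        profile = np.exp(-0.5 * (d / sigma) ** 2)
        endcap = np.clip((half_len - np.abs(t)) / sigma + 1.0, 0.0, 1.0)
        out[r0:r1, c0:c1] += contrast * profile * endcap
        return out
    return render_target(wax, spec, px, pattern_rng=pattern_rng)


def _render_name_overlay(img, wbox, region, amplitude, seed):
    """Burn a blocky text-like pattern into the wax (the phantom model name)."""
    wr0, wc0, wr1, wc1 = wbox
    wh, ww = wr1 - wr0, wc1 - wc0
    r0 = wr0 + int(region[0] * wh)
    c0 = wc0 + int(region[1] * ww)
    r1 = r0 + max(int(region[2] * wh), 1)
    c1 = c0 + max(int(region[3] * ww), 1)
    rng = np.random.default_rng(seed + 99)
    glyphs = rng.random((4, 24)) > 0.45
    from scipy.ndimage import zoom as _zoom

    block = _zoom(glyphs.astype(float), ((r1 - r0) / 4.0, (c1 - c0) / 24.0), order=0)
    img[r0:r1, c0:c1] += amplitude * block[: r1 - r0, : c1 - c0]


def save_phantom(image: PhantomImage, gt: GroundTruth, path: str | Path) -> None:
    """Write a 16-bit TIFF plus a JSON ground-truth sidecar (``.json``)."""
    import tifffile

    path = Path(path)
    arr = np.clip(image.pixels, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr, metadata=None)
    sidecar = {
        "pixel_size_um": image.pixel_size_um,
        "device_id": image.device_id,
        "dose_factor": image.dose_factor,
        "ground_truth": json.loads(gt.to_json()),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def save_phantom_dicom(image: PhantomImage, path: str | Path) -> None:
    """Write a secondary-capture DICOM with pixel spacing metadata."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.StationName = image.device_id
    ds.PresentationIntentType = ("FOR PRESENTATION"
                                 if image.intent == "for_presentation"
                                 else "FOR PROCESSING")
    arr = np.clip(image.pixels, 0, 65535).astype(np.uint16)
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    spacing_mm = image.pixel_size_um / 1000.0
    ds.PixelSpacing = [f"{spacing_mm:.6f}", f"{spacing_mm:.6f}"]
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def _load_dicom(path: Path) -> PhantomImage:
    import pydicom

    ds = pydicom.dcmread(str(path))
    spacing = getattr(ds, "PixelSpacing", None)
    pixel_um = float(spacing[0]) * 1000.0 if spacing else 100.0
    intent = getattr(ds, "PresentationIntentType", "FOR PRESENTATION")
    return PhantomImage(
        pixels=ds.pixel_array.astype(np.float64),
        pixel_size_um=pixel_um,
        device_id=str(getattr(ds, "StationName", "unknown")),
        intent=("for_presentation" if "PRESENTATION" in str(intent).upper()
                else "for_processing"),
    )


def load_phantom(path: str | Path) -> tuple[PhantomImage, GroundTruth | None]:
    """Read a phantom image (TIFF or DICOM) and, if present, the JSON
    ground-truth sidecar written by :func:`save_phantom`."""
    path = Path(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    gt = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        gt = GroundTruth.from_json(json.dumps(meta["ground_truth"]))
    if path.suffix.lower() in (".dcm", ".dicom"):
        image = _load_dicom(path)
        if "dose_factor" in meta:
            image.dose_factor = float(meta["dose_factor"])
        return image, gt
    import tifffile

    pixels = tifffile.imread(path).astype(np.float64)
    image = PhantomImage(
        pixels=pixels,
        pixel_size_um=float(meta.get("pixel_size_um", 100.0)),
        device_id=str(meta.get("device_id", "unknown")),
        dose_factor=float(meta.get("dose_factor", 1.0)),
    )
    return image, gt
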