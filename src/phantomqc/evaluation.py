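"""Noise power spectra and agreement statistics.

The NPS characterises image noise as variance per spatial-frequency band
(pixel-value^2 * mm^2): per-ROI 2-D periodograms scaled by
pixel_area / N_pixels, ensemble-averaged, radially binned to 1-D and
smoothed with a 5-point moving average.  The binning satisfies Parseval:
summing the 2-D NPS times the frequency-bin area recovers the ROI
variance.

Agreement machinery: multi-class accuracy, per-class sensitivity from a
17x17 confusion table, the Wilcoxon signed-rank test (exact null for
small samples, midranked ties, zero differences discarded) and Fleiss'
kappa for fixed-size rater panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classes import CLASS_NAMES
from .errors import InvalidArgumentError


# ---------------------------------------------------------------- NPS

@dataclass
class NPSCurve:
    frequencies: np.ndarray  # 1/mm, ascending
    power: np.ndarray  # pixel-value^2 * mm^2
    smoothing_window: int = 5


def compute_nps_2d(rois: list[np.ndarray], pixel_size_um: float) -> np.ndarray:
    """Ensemble-averaged 2-D noise power spectrum of mean-detrended ROIs.

    NPS(u, v) = |DFT(roi - mean)|^2 * a^2 / (Nx * Ny) with ``a`` the pixel
    size in mm, so that sum(NPS) * dfx * dfy equals the ROI variance.
    """
    if not rois:
        raise InvalidArgumentError("need at least one ROI")
    shape = np.asarray(rois[0]).shape
    if min(shape) < 32:
        raise InvalidArgumentError("ROIs must be at least 32x32")
    a_mm = pixel_size_um / 1000.0
    acc = np.zeros(shape)
    for roi in rois:
        r = np.asarray(roi, dtype=np.float64)
        if r.shape != shape:
            raise InvalidArgumentError("ROIs must share a shape")
        r = r - r.mean()
        acc += np.abs(np.fft.fft2(r)) ** 2
    return acc / len(rois) * (a_mm ** 2) / (shape[0] * shape[1])


def compute_nps(rois: list[np.ndarray], pixel_size_um: float,
                smoothing_window: int = 5) -> NPSCurve:
    """Radially binned 1-D NPS, smoothed with a moving average."""
    nps2d = compute_nps_2d(rois, pixel_size_um)
    ny, nx = nps2d.shape
    a_mm = pixel_size_um / 1000.0
    fy = np.fft.fftfreq(ny, d=a_mm)
    fx = np.fft.fftfreq(nx, d=a_mm)
    fr = np.hypot(fy[:, None], fx[None, :])
    df = 1.0 / (min(nx, ny) * a_mm)  # bin width = one frequency sample
    bins = np.round(fr / df).astype(int)
    n_bins = bins.max() + 1
    power = np.bincount(bins.ravel(), weights=nps2d.ravel(), minlength=n_bins)
    counts = np.bincount(bins.ravel(), minlength=n_bins)
    power = power / np.maximum(counts, 1)
    freqs = np.arange(n_bins) * df
    # keep the unambiguous radial range (up to the axis Nyquist)
    nyq = 0.5 / a_mm
    keep = freqs <= nyq
    freqs, power = freqs[keep], power[keep]
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        power = np.convolve(power, kernel, mode="same")
    return NPSCurve(frequencies=freqs, power=power,
                    smoothing_window=smoothing_window)


def harvest_rois(wax_pixels: np.ndarray, region: tuple[int, int, int, int],
                 roi_size: int = 64) -> list[np.ndarray]:
    """Non-overlapping square tiles from a target-free wax region."""
    r0, c0, r1, c1 = region
    crop = wax_pixels[r0:r1, c0:c1]
    rois = []
    for i in range(0, crop.shape[0] - roi_size + 1, roi_size):
        for j in range(0, crop.shape[1] - roi_size + 1, roi_size):
            rois.append(crop[i:i + roi_size, j:j + roi_size].copy())
    return rois


# ------------------------------------------------- classification metrics

def multiclass_accuracy(true, predicted) -> float:
    """Fraction of samples whose predicted class matches the truth."""
    t = np.asarray(true)
    p = np.asarray(predicted)
    if t.shape != p.shape or t.size == 0:
        raise InvalidArgumentError("label vectors must be equal-length, non-empty")
    return float((t == p).mean())


def confusion_table(true, predicted, classes=CLASS_NAMES) -> np.ndarray:
    """Counts with rows = true (consensus) class, columns = predicted."""
    idx = {c: i for i, c in enumerate(classes)}
    table = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, predicted, strict=True):
        table[idx[t], idx[p]] += 1
    return table


def per_class_sensitivity(confusion: np.ndarray) -> np.ndarray:
    """Diagonal over row sums; classes with empty rows are NaN-marked."""
    confusion = np.asarray(confusion, dtype=np.float64)
    rows = confusion.sum(axis=1)
    out = np.full(confusion.shape[0], np.nan)
    nonzero = rows > 0
    out[nonzero] = np.diag(confusion)[nonzero] / rows[nonzero]
    return out


# --------------------------------------------------- agreement statistics

@dataclass
class AgreementResult:
    statistic: float
    p_value: float | None
    n: int
    method: str
    flags: list[str] = field(default_factory=list)


def _signed_rank_exact_sf(ranks: np.ndarray, w: float) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under the exact sign-flip null.

    Ranks may be midranks (multiples of 1/2); the distribution is built by
    convolution over 2x-scaled integer ranks.
    """
    scaled = np.round(ranks * 2).astype(int)
    total = scaled.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:len(dist) - r]
        dist = 0.5 * (dist + shifted)
    w2 = w * 2
    lo = float(dist[:int(math.floor(w2 + 1e-9)) + 1].sum())
    hi = float(dist[int(math.ceil(w2 - 1e-9)):].sum())
    return lo, hi


def wilcoxon_signed_rank(paired_a, paired_b, exact_limit: int = 25,
                         ) -> AgreementResult:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are discarded (classic Wilcoxon treatment), ties are
    midranked, and the null distribution is exact for n <= ``exact_limit``
    else a normal approximation with tie correction.
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape or a.size == 0:
        raise InvalidArgumentError("paired scores must be equal-length, non-empty")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return AgreementResult(statistic=0.0, p_value=1.0, n=0,
                               method="wilcoxon-signed-rank",
                               flags=["all-differences-zero"])
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        lo, hi = _signed_rank_exact_sf(ranks, w_plus)
        p = min(1.0, 2.0 * min(lo, hi))
        method = "wilcoxon-signed-rank-exact"
    else:
        mean = n * (n + 1) / 4.0
        # variance with midrank tie correction
        var = float((ranks ** 2).sum()) / 4.0
        z = (w_plus - mean) / math.sqrt(var)
        from scipy.stats import norm

        p = float(2.0 * norm.sf(abs(z)))
        method = "wilcoxon-signed-rank-normal"
    return AgreementResult(statistic=w_plus, p_value=min(p, 1.0), n=n,
                           method=method)


def fleiss_kappa(ratings: np.ndarray) -> AgreementResult:
    """Fleiss' kappa for a subjects x categories count table.

    Every subject must be rated by the same number (>= 2) of raters.
    Perfect agreement gives 1; chance-level agreement gives ~0.  When a
    single category absorbs all ratings the statistic is undefined
    (expected agreement is 1) and NaN is returned with a flag.
    """
    table = np.asarray(ratings, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] < 1:
        raise InvalidArgumentError("ratings must be a subjects x categories table")
    raters = table.sum(axis=1)
    m = raters[0]
    if m < 2 or not np.all(raters == m):
        raise InvalidArgumentError("every subject needs the same rater count >= 2")
    n_subjects = table.shape[0]
    p_i = (np.sum(table * (table - 1), axis=1)) / (m * (m - 1))
    p_bar = float(p_i.mean())
    p_j = table.sum(axis=0) / (n_subjects * m)
    p_e = float(np.sum(p_j ** 2))
    if p_e >= 1.0 - 1e-12:
        return AgreementResult(statistic=float("nan"), p_value=None,
                               n=n_subjects, method="fleiss-kappa",
                               flags=["degenerate-single-category"])
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return AgreementResult(statistic=float(kappa), p_value=None, n=n_subjects,
                           method="fleiss-kappa")


def ratings_from_raw(raw: np.ndarray, categories: list) -> np.ndarray:
    """Convert subjects x raters categorical data to a count table."""
    raw = np.asarray(raw)
    table = np.zeros((raw.shape[0], len(categories)), dtype=int)
    lookup = {c: i for i, c in enumerate(categories)}
    for i, row in enumerate(raw):
        for v in row:
            table[i, lookup[v]] += 1
    return table


# ---------------------------------------------------- score agreement

def score_agreement_report(reviewer_sheets: dict, model_sheets: dict) -> dict:
    """Compare consensus reviewer sheets with model sheets, per target family.

    Both arguments map image id -> ScoreSheet.  For each family the report
    carries mean +- sd of the totals, the fraction of images scored exactly
    equal, the fraction within +-1 point, the signed-rank p-value, and a
    consensus-vs-model count table of total scores.
    """
    if set(reviewer_sheets) != set(model_sheets):
        raise InvalidArgumentError("reviewer and model image ids must match")
    ids = sorted(reviewer_sheets)
    families = {"fibres": ("fibre_total", 6), "microcalcifications": ("mc_total", 5),
                "masses": ("mass_total", 5)}
    report = {}
    for family, (attr, max_total) in families.items():
        rev = np.array([getattr(reviewer_sheets[i], attr) for i in ids])
        mod = np.array([getattr(model_sheets[i], attr) for i in ids])
        diff = mod - rev
        wil = wilcoxon_signed_rank(mod, rev)
        # scatter table over half-point-resolved totals
        levels = np.arange(0, max_total + 0.5, 0.5)
        scatter = np.zeros((len(levels), len(levels)), dtype=int)
        li = {v: i for i, v in enumerate(levels)}
        for r, m in zip(rev, mod):
            scatter[li[float(r)], li[float(m)]] += 1
        report[family] = {
            "reviewer_mean": float(rev.mean()), "reviewer_sd": float(rev.std()),
            "model_mean": float(mod.mean()), "model_sd": float(mod.std()),
            "fraction_equal": float((diff == 0).mean()),
            "fraction_within_1": float((np.abs(diff) <= 1).mean()),
            "signed_rank_p": wil.p_value,
            "scatter_levels": levels.tolist(),
            "scatter": scatter.tolist(),
            "n_images": len(ids),
        }
    return report
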