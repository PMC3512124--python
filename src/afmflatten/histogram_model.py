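"""Height histograms, Gaussian peak models, thresholds and the improvement check.

The flatness of an AFM image is judged through its height histogram: every
flat level in the sample appears as a (noise-broadened) Gaussian peak, and
every uncorrected distortion broadens those peaks.  This module builds the
histogram, detects topographic levels, fits a sum of up to ``m`` Gaussians,
derives the background threshold interval ``z_j ± n·σ_j`` (narrowed at the
crossing with a neighbouring peak), and implements the weighted improvement
check that gates every data-touching step of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy import ndimage, optimize, signal

from .image import DegenerateMaskError, HeightImage

#: Default maximum number of Gaussian components fitted to a histogram.
DEFAULT_MAX_PEAKS = 8

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class HeightHistogram:
    """Histogram of heights over an image or a masked subset of it."""

    bin_edges: np.ndarray
    counts: np.ndarray
    total_pixels: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("bin_edges must have len(counts)+1 entries")
        if int(self.counts.sum()) != int(self.total_pixels):
            raise ValueError("sum(counts) must equal total_pixels")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def mean(self) -> float:
        return float(np.average(self.centers, weights=self.counts))

    def std(self) -> float:
        m = self.mean()
        var = np.average((self.centers - m) ** 2, weights=self.counts)
        return float(np.sqrt(var))


@dataclass
class GaussianPeak:
    """One fitted histogram component: center z (nm), width sigma (nm), area
    A in pixel-equivalents (integral of the component / bin width)."""

    center: float
    sigma: float
    area: float

    @property
    def height(self) -> float:
        """Peak density height A/(sigma*sqrt(2*pi)) in pixels per nm."""
        return self.area / (self.sigma * _SQRT2PI)


@dataclass
class HistogramModel:
    """Sum-of-Gaussians model of a height histogram, peaks sorted by center."""

    peaks: List[GaussianPeak]
    residual: float
    bin_width: float
    converged: bool = True

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.center)
        for p in self.peaks:
            if not (p.sigma > 0 and p.area > 0):
                raise ValueError("all fitted sigmas and areas must be positive")

    @property
    def total_area(self) -> float:
        return float(sum(p.area for p in self.peaks))

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Model counts per bin at bin centers ``x``."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for p in self.peaks:
            out += (
                p.area
                * self.bin_width
                / (p.sigma * _SQRT2PI)
                * np.exp(-0.5 * ((x - p.center) / p.sigma) ** 2)
            )
        return out


@dataclass
class ThresholdInterval:
    """Background acceptance band [low, high] around peak ``peak_index``."""

    low: float
    high: float
    peak_index: int
    n: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("threshold interval must satisfy low < high")


@dataclass
class ImprovementVerdict:
    """Outcome of the weighted improvement check for one processing step."""

    accepted: bool
    area_before: float
    area_after: float
    sigma_w_before: float
    sigma_w_after: float
    reason: str = ""


def build_histogram(
    image: Union[HeightImage, np.ndarray], mask: Optional[np.ndarray] = None
) -> HeightHistogram:
    """Histogram of (optionally masked) heights.

    Bin rule: Freedman-Diaconis width, with the bin count clipped to
    [128, 1024] so histograms stay comparable across image sizes.  A
    constant field collapses to a single bin.
    """
    h = image.heights if isinstance(image, HeightImage) else np.asarray(image, float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != h.shape:
            raise ValueError("mask shape must match image shape")
        data = h[mask]
        if data.size < 16:
            raise DegenerateMaskError(
                f"mask keeps only {data.size} pixels (need >= 16)"
            )
    else:
        data = h.ravel()
    if not np.all(np.isfinite(data)):
        raise ValueError("image contains non-finite heights")
    n = data.size
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        edges = np.array([lo - 0.5, lo + 0.5])
        return HeightHistogram(edges, np.array([n]), n)
    q75, q25 = np.percentile(data, [75.0, 25.0])
    iqr = q75 - q25
    if iqr > 0:
        width = 2.0 * iqr / n ** (1.0 / 3.0)
        nbins = int(np.ceil((hi - lo) / width))
    else:
        nbins = 128
    nbins = int(np.clip(nbins, 128, 1024))
    counts, edges = np.histogram(data, bins=nbins, range=(lo, hi))
    return HeightHistogram(edges, counts, n)


def _segment_bounds(counts: np.ndarray, peak_idx: np.ndarray) -> List[tuple]:
    """Watershed segments: split at the deepest valley between adjacent peaks."""
    bounds = [0]
    for a, b in zip(peak_idx[:-1], peak_idx[1:]):
        bounds.append(a + int(np.argmin(counts[a : b + 1])))
    bounds.append(counts.size)
    return [(bounds[i], bounds[i + 1]) for i in range(len(peak_idx))]


def _segment_areas(counts: np.ndarray, peak_idx: np.ndarray) -> np.ndarray:
    return np.array([counts[a:b].sum() for a, b in _segment_bounds(counts, peak_idx)], float)


def detect_peaks(
    hist: HeightHistogram,
    max_peaks: int = DEFAULT_MAX_PEAKS,
    prominence_frac: float = 0.01,
    min_separation: int = 3,
    smooth_bins: float = 1.5,
    min_area_frac: float = 0.005,
) -> List[float]:
    """Candidate peak centers (nm) for the discrete topographic levels.

    Local maxima of the (lightly smoothed) histogram with prominence
    >= ``prominence_frac`` of the tallest bin and at least
    ``min_separation`` bins apart.  Candidates whose watershed segment
    covers less than ``min_area_frac`` of all pixels are discarded -- a
    bump covering a fraction of a percent of the image is bin noise, not a
    topographic level.  At least one candidate is always returned (the
    histogram mode); if more than ``max_peaks`` survive, those covering the
    greatest area are kept.
    """
    counts = hist.counts.astype(float)
    centers = hist.centers
    if counts.size == 1:
        return [float(centers[0])]
    smooth = (
        ndimage.gaussian_filter1d(counts, smooth_bins) if smooth_bins > 0 else counts
    )
    # pad so peaks sitting in the first/last bin are detectable
    padded = np.concatenate([[0.0], smooth, [0.0]])
    idx, _ = signal.find_peaks(
        padded,
        prominence=prominence_frac * smooth.max(),
        distance=min_separation,
    )
    idx = idx - 1
    if idx.size > 1 and min_area_frac > 0:
        areas = _segment_areas(counts, idx)
        big = areas >= min_area_frac * hist.total_pixels
        if big.any():
            idx = idx[big]
        else:
            idx = idx[[int(np.argmax(areas))]]
    if idx.size == 0:
        idx = np.array([int(np.argmax(counts))])
    if idx.size > max_peaks:
        areas = _segment_areas(counts, idx)
        keep = np.sort(np.argsort(areas)[::-1][:max_peaks])
        idx = idx[keep]
    return [float(centers[i]) for i in idx]


def _initial_guesses(hist: HeightHistogram, idx: np.ndarray):
    counts = hist.counts.astype(float)
    centers = hist.centers
    w = hist.bin_width
    p0 = []
    for (a, b), i in zip(_segment_bounds(counts, idx), idx):
        seg_c = centers[a:b]
        seg_n = counts[a:b]
        area = float(seg_n.sum())
        if area <= 0:
            area = max(float(counts[i]), 1.0)
            mu, sd = float(centers[i]), w
        else:
            mu = float(np.average(seg_c, weights=seg_n))
            sd = float(np.sqrt(np.average((seg_c - mu) ** 2, weights=seg_n)))
        sd = max(sd, w / 2.0)
        p0.extend([float(centers[i]), sd, area])
    return np.asarray(p0)


def _moment_model(hist: HeightHistogram, idx: np.ndarray) -> HistogramModel:
    """Per-segment moment estimates; the fallback when least squares fails."""
    p0 = _initial_guesses(hist, idx)
    peaks = [
        GaussianPeak(p0[3 * i], p0[3 * i + 1], max(p0[3 * i + 2], 1e-9))
        for i in range(p0.size // 3)
    ]
    model = HistogramModel(peaks, residual=np.nan, bin_width=hist.bin_width, converged=False)
    resid = model.evaluate(hist.centers) - hist.counts
    norm = max(float(np.linalg.norm(hist.counts)), 1.0)
    model.residual = float(np.linalg.norm(resid)) / norm
    return model


def fit_gaussian_mixture(
    hist: HeightHistogram,
    centers: Sequence[float],
    max_peaks: int = DEFAULT_MAX_PEAKS,
) -> HistogramModel:
    """Least-squares fit of a sum of Gaussians to the histogram counts.

    Seeded at the candidate ``centers`` (at most ``max_peaks``; if more are
    supplied, the candidates covering the greatest area are kept).  On
    non-convergence the fit falls back to per-segment moment estimates,
    flagged by ``converged=False``.
    """
    if len(centers) == 0:
        raise ValueError("need at least one candidate center")
    x = hist.centers
    counts = hist.counts.astype(float)
    w = hist.bin_width
    idx = np.array(sorted({int(np.argmin(np.abs(x - c))) for c in centers}))
    if idx.size > max_peaks:
        areas = _segment_areas(counts, idx)
        idx = idx[np.sort(np.argsort(areas)[::-1][:max_peaks])]

    if x.size <= 3 * idx.size:
        return _moment_model(hist, idx)

    p0 = _initial_guesses(hist, idx)
    m = idx.size
    lo_e, hi_e = hist.bin_edges[0], hist.bin_edges[-1]
    span = hi_e - lo_e
    n_tot = float(counts.sum())
    lower = np.tile([lo_e, w / 10.0, 1e-9], m)
    upper = np.tile([hi_e, 2.0 * span, 10.0 * n_tot], m)
    p0 = np.clip(p0, lower + 1e-12, upper - 1e-12)

    def residuals(p):
        out = -counts.copy()
        for i in range(m):
            z, s, a = p[3 * i], p[3 * i + 1], p[3 * i + 2]
            out += a * w / (s * _SQRT2PI) * np.exp(-0.5 * ((x - z) / s) ** 2)
        return out

    try:
        res = optimize.least_squares(
            residuals,
            p0,
            bounds=(lower, upper),
            method="trf",
            max_nfev=300 * (3 * m),
        )
    except Exception:
        return _moment_model(hist, idx)
    if not res.success or not np.all(np.isfinite(res.x)):
        return _moment_model(hist, idx)
    peaks = [
        GaussianPeak(float(res.x[3 * i]), float(res.x[3 * i + 1]), float(res.x[3 * i + 2]))
        for i in range(m)
    ]
    norm = max(float(np.linalg.norm(counts)), 1.0)
    residual = float(np.linalg.norm(res.fun)) / norm
    return HistogramModel(peaks, residual=residual, bin_width=w, converged=True)


def fit_model(
    image: Union[HeightImage, np.ndarray],
    mask: Optional[np.ndarray] = None,
    max_peaks: int = DEFAULT_MAX_PEAKS,
) -> HistogramModel:
    """Convenience: histogram -> peak detection -> mixture fit."""
    hist = build_histogram(image, mask)
    centers = detect_peaks(hist, max_peaks=max_peaks)
    return fit_gaussian_mixture(hist, centers, max_peaks=max_peaks)


def _gaussian_crossing(p1: GaussianPeak, p2: GaussianPeak) -> Optional[float]:
    """Height where the two scaled Gaussian curves cross, strictly between
    the two centers; None if they do not cross there.

    Equating ``A1*phi(x; z1, s1) = A2*phi(x; z2, s2)`` and taking logs gives
    a quadratic in x, solved in closed form.
    """
    z1, s1, a1 = p1.center, p1.sigma, p1.area
    z2, s2, a2 = p2.center, p2.sigma, p2.area
    if z1 == z2:
        return None
    alpha = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    beta = z1 / s1**2 - z2 / s2**2
    gamma = z2**2 / (2 * s2**2) - z1**2 / (2 * s1**2) + math.log((a1 * s2) / (a2 * s1))
    lo, hi = min(z1, z2), max(z1, z2)
    if abs(alpha) < 1e-300:
        if beta == 0:
            return None
        roots = [-gamma / beta]
    else:
        disc = beta**2 - 4 * alpha * gamma
        if disc < 0:
            return None
        sq = math.sqrt(disc)
        roots = [(-beta - sq) / (2 * alpha), (-beta + sq) / (2 * alpha)]
    inside = [r for r in roots if lo < r < hi]
    if not inside:
        return None
    return min(inside, key=lambda r: abs(r - z1))


def select_peak(model: HistogramModel, j: Union[int, str] = "auto") -> int:
    """Resolve a peak selector: 'auto' picks the highest fitted peak."""
    if j == "auto":
        return int(np.argmax([p.height for p in model.peaks]))
    j = int(j)
    if not 0 <= j < len(model.peaks):
        raise ValueError(f"peak index {j} out of range (model has {len(model.peaks)} peaks)")
    return j


def compute_threshold(
    model: HistogramModel, j: Union[int, str] = "auto", n: float = 2.0
) -> ThresholdInterval:
    """Background threshold band ``z_j ± n·σ_j``.

    Each side is narrowed to the crossing point with the neighbouring
    Gaussian component when that crossing lies inside the nominal band, so
    the band never swallows a neighbouring level.  The interval always
    contains ``z_j``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    jj = select_peak(model, j)
    pk = model.peaks[jj]
    low = pk.center - n * pk.sigma
    high = pk.center + n * pk.sigma
    lefts = [p for p in model.peaks if p.center < pk.center]
    rights = [p for p in model.peaks if p.center > pk.center]
    if lefts:
        neighbor = max(lefts, key=lambda p: p.center)
        c = _gaussian_crossing(pk, neighbor)
        if c is not None and c > low:
            low = c
    if rights:
        neighbor = min(rights, key=lambda p: p.center)
        c = _gaussian_crossing(pk, neighbor)
        if c is not None and c < high:
            high = c
    return ThresholdInterval(low=float(low), high=float(high), peak_index=jj, n=float(n))


def top_levels(model: HistogramModel, n_levels: Optional[int]) -> List[int]:
    """Indices of the ``n_levels`` most prominent peaks (all if None).

    Prominence is ranked by fitted peak height rather than area: a sharp
    peak is a topographic level, whereas a broad low component is usually
    the model's catch-all for smeared or continuum heights.
    """
    if n_levels is None or n_levels >= len(model.peaks):
        return list(range(len(model.peaks)))
    order = np.argsort([p.height for p in model.peaks])[::-1]
    return sorted(int(i) for i in order[: int(n_levels)])


def weighted_sigma(model: HistogramModel, level_indices: Optional[Sequence[int]] = None) -> float:
    """Area-weighted average peak width  sigma_w = sum(A_i s_i)/sum(A_i)."""
    if level_indices is None:
        level_indices = range(len(model.peaks))
    level_indices = list(level_indices)
    if not level_indices:
        raise ValueError("level_indices must be non-empty")
    sel = [model.peaks[i] for i in level_indices]
    total = sum(p.area for p in sel)
    return float(sum(p.area * p.sigma for p in sel) / total)


def area_covered(
    heights: np.ndarray,
    centers: Sequence[float],
    sigmas: Sequence[float],
    n: float = 2.0,
) -> int:
    """Pixels covered by the given levels: count of pixels inside the union
    of the bands ``center_i ± n·sigma_i``."""
    h = np.asarray(heights).ravel()
    inside = np.zeros(h.size, dtype=bool)
    for z, s in zip(centers, sigmas):
        inside |= (h >= z - n * s) & (h <= z + n * s)
    return int(inside.sum())


def improvement_check(
    before: HistogramModel,
    after: HistogramModel,
    levels: Optional[int] = None,
    tol_area: float = 0.05,
    tol_sigma: float = 0.02,
    before_heights: Optional[np.ndarray] = None,
    after_heights: Optional[np.ndarray] = None,
    band_width: Optional[float] = None,
) -> ImprovementVerdict:
    """Did a processing step improve the image?

    Accepted iff the area covered by the modelled levels did not decrease by
    more than ``tol_area`` (no pixels escaped the levels), the weighted
    average width did not increase by more than ``tol_sigma`` (no peak
    broadened), and no monitored level disappeared.  ``levels`` restricts
    both models to their ``levels`` most prominent peaks; None uses every
    fitted peak (the rule before the first background removal).

    When the height fields and a ``band_width`` (typically twice the pixel
    noise) are supplied, the area criterion counts the pixels within
    fixed-width bands around each model's own level centers -- a measuring
    stick immune to how either mixture fit apportions widths.  An improving
    step concentrates level mass into the bands; a corrupting one smears it
    out, and collapsing two real levels into one trips the level-count
    guard.  Without the fields the criterion falls back to comparing the
    fitted Gaussian areas (meaningful only for samples whose pixels all
    belong to discrete levels).
    """
    bi = top_levels(before, levels)
    ai = top_levels(after, levels)
    ok_levels = len(ai) >= len(bi)
    if before_heights is not None and after_heights is not None and band_width:
        area_b = float(
            area_covered(
                before_heights,
                [before.peaks[i].center for i in bi],
                [band_width] * len(bi),
                n=1.0,
            )
        )
        area_a = float(
            area_covered(
                after_heights,
                [after.peaks[i].center for i in ai],
                [band_width] * len(ai),
                n=1.0,
            )
        )
    else:
        area_b = float(sum(before.peaks[i].area for i in bi))
        area_a = float(sum(after.peaks[i].area for i in ai))
    sw_b = weighted_sigma(before, bi)
    sw_a = weighted_sigma(after, ai)
    ok_area = area_a >= area_b * (1.0 - tol_area)
    ok_sigma = sw_a <= sw_b * (1.0 + tol_sigma)
    reasons = []
    if not ok_area:
        reasons.append(
            f"area covered by the levels decreased {area_b:.4g} -> {area_a:.4g} "
            f"(more than tol_area={tol_area})"
        )
    if not ok_sigma:
        reasons.append(
            f"weighted sigma increased {sw_b:.4g} -> {sw_a:.4g} "
            f"(more than tol_sigma={tol_sigma})"
        )
    if not ok_levels:
        reasons.append(f"monitored levels decreased {len(bi)} -> {len(ai)}")
    return ImprovementVerdict(
        accepted=ok_area and ok_sigma and ok_levels,
        area_before=area_b,
        area_after=area_a,
        sigma_w_before=sw_b,
        sigma_w_after=sw_a,
        reason="; ".join(reasons) if reasons else "criteria satisfied",
    )
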