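"""Per-scan-line (1-D) corrections.

All z-distortions that vary line to line -- laser mode hops, tip-sample
changes, line skips -- appear as additive constants on whole scan lines.
Accordingly every operation here subtracts *only* a constant per line (or
per column for the perpendicular variant), never a slope or curvature:
higher-order per-line fits destroy interline relationships and create
artifacts that cannot be undone later.

Each operation returns a new image together with the per-line constants it
subtracted, so corrections remain invertible bookkeeping.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .image import DegenerateMaskError, HeightImage, LineOffsets

#: Fraction of flagged pixels above which a whole line counts as a scar line.
DEFAULT_SCAR_LINE_FRACTION = 0.25


def estimate_noise_sigma(image: HeightImage) -> float:
    """Robust pixel-noise estimate from adjacent-line differences.

    The median difference of each line pair (the legitimate line offset) is
    removed; the MAD of what remains estimates ``sqrt(2)`` times the pixel
    noise.  Immune to smooth surfaces, tilt and per-line offsets, so it is
    stable at every pipeline stage.
    """
    H = image.heights
    d = np.diff(H, axis=0)
    d = d - np.median(d, axis=1, keepdims=True)
    mad = float(np.median(np.abs(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def detect_scars(image: HeightImage, nsig: float = 2.0) -> np.ndarray:
    """Flag scar pixels: sections of a line offset from both neighbours.

    For each pair of adjacent lines the median difference (the legitimate
    line offset) is removed; the remaining per-pixel differences are
    compared against ``nsig`` times their robust (MAD-based) standard
    deviation.  A pixel is a scar when it deviates beyond that threshold
    from the preceding *and* the following line, with consistent sign --
    requiring agreement of both neighbours avoids flagging real topographic
    edges.  Edge lines are compared against their two nearest lines.
    """
    H = image.heights
    rows, cols = H.shape
    if rows < 3:
        raise ValueError("scar detection needs at least 3 scan lines")
    d = np.diff(H, axis=0)
    med = np.median(d, axis=1, keepdims=True)
    resid = d - med
    mad = float(np.median(np.abs(resid)))
    sigma = 1.4826 * mad
    if sigma == 0.0:
        sigma = float(resid.std())
    thr = nsig * sigma
    mask = np.zeros((rows, cols), dtype=bool)
    up = resid[:-1]      # line n minus line n-1, offset-centred (n = 1..rows-2)
    down = -resid[1:]    # line n minus line n+1, offset-centred
    mask[1:-1] = ((up > thr) & (down > thr)) | ((up < -thr) & (down < -thr))
    # edge lines: compare against the two nearest lines in one direction
    for n, n1, n2 in ((0, 1, 2), (rows - 1, rows - 2, rows - 3)):
        d1 = H[n] - H[n1]
        d1 -= np.median(d1)
        d2 = H[n] - H[n2]
        d2 -= np.median(d2)
        mask[n] = ((d1 > thr) & (d2 > thr)) | ((d1 < -thr) & (d2 < -thr))
    return mask


def repair_scars(image: HeightImage, scars: np.ndarray) -> HeightImage:
    """Replace each scar pixel by the median of five neighbouring points in
    the nearest preceding scar-free line (nearest following line when the
    scar touches the top of the image).  Non-scar pixels are unchanged."""
    scars = np.asarray(scars, dtype=bool)
    H = image.heights
    if scars.shape != H.shape:
        raise ValueError("scar mask shape must match image shape")
    out = H.copy()
    if not scars.any():
        return image.with_heights(out)
    rows, cols = H.shape
    prev_clean = np.full((rows, cols), -1, dtype=int)
    last = np.full(cols, -1, dtype=int)
    for n in range(rows):
        prev_clean[n] = last
        last = np.where(scars[n], last, n)
    next_clean = np.full((rows, cols), -1, dtype=int)
    nxt = np.full(cols, -1, dtype=int)
    for n in range(rows - 1, -1, -1):
        next_clean[n] = nxt
        nxt = np.where(scars[n], nxt, n)
    for n, i in np.argwhere(scars):
        src = prev_clean[n, i]
        if src < 0:
            src = next_clean[n, i]
        if src < 0:
            continue  # entire column is scar; nothing usable
        lo, hi = max(i - 2, 0), min(i + 3, cols)
        out[n, i] = np.median(H[src, lo:hi])
    return image.with_heights(out)


def scar_line_flags(
    scars: np.ndarray, line_fraction: float = DEFAULT_SCAR_LINE_FRACTION
) -> np.ndarray:
    """A line counts as 'identified as a scar' when more than
    ``line_fraction`` of its pixels are scar-flagged."""
    return np.asarray(scars, bool).mean(axis=1) > line_fraction


def median_offset_correction(image: HeightImage) -> Tuple[HeightImage, LineOffsets]:
    """Subtract each scan line's median from that line; every output line
    then has median zero."""
    H = image.heights
    med = np.median(H, axis=1)
    out = H - med[:, None]
    return image.with_heights(out), LineOffsets(med, ["median_offset"])


def _excluded_median(d: np.ndarray, nsig: float) -> Optional[float]:
    """Median of ``d`` after excluding entries deviating more than
    ``nsig``*std from the median; None when everything is excluded."""
    s = float(d.std())
    if s == 0.0:
        return float(np.median(d))
    keep = np.abs(d - np.median(d)) <= nsig * s
    if not keep.any():
        return None
    return float(np.median(d[keep]))


def median_difference_correction(
    image: HeightImage,
    scars: Optional[np.ndarray] = None,
    nsig: float = 2.0,
    scar_line_fraction: float = DEFAULT_SCAR_LINE_FRACTION,
) -> Tuple[HeightImage, LineOffsets]:
    """Align each line to its predecessor via the outlier-excluded median of
    the column-wise differences.

    For each line n >= 1, the differences to the (already corrected) line
    n-1 are computed; columns whose difference deviates from the pair's
    median by more than ``nsig`` times the std of the differences are
    excluded (this removes the influence of topographic edges), and the
    median of the remainder is subtracted from line n.  Lines classified as
    scars are skipped.  Corrections accumulate down the image.
    """
    H = image.heights.copy()
    rows = H.shape[0]
    if rows < 2:
        raise ValueError("need at least 2 scan lines")
    offsets = np.zeros(rows)
    skip = (
        scar_line_flags(scars, scar_line_fraction)
        if scars is not None
        else np.zeros(rows, dtype=bool)
    )
    for n in range(1, rows):
        if skip[n]:
            continue
        m = _excluded_median(H[n] - H[n - 1], nsig)
        if m is None:
            continue  # all columns excluded; leave the line untouched
        H[n] -= m
        offsets[n] = m
    return image.with_heights(H), LineOffsets(offsets, ["median_difference"])


def running_average_refinement(
    image: HeightImage,
    k: int = 15,
    iterations: int = 4,
    nsig: float = 2.0,
    height_threshold_sigmas: float = 3.0,
    noise_sigma: Optional[float] = None,
) -> Tuple[HeightImage, LineOffsets]:
    """Iterative refinement: subtract a running average of median differences.

    For every line the outlier-excluded median difference to each of up to
    ``k`` preceding lines is computed and their average subtracted.  Only
    data within a defined threshold participates: columns whose heights sit
    within ``height_threshold_sigmas`` times the pixel-noise estimate of
    their own line's median -- this excludes topography along scan-line
    contours, so feature-crossing lines are aligned on their background
    pixels rather than dragged by the features.  Window lines whose median
    difference deviates more than ``nsig``*std from the rest of the window
    are excluded as well.  The direction of "preceding" alternates per
    iteration (top-down, bottom-up, ...), which maintains continuity over
    long distances and prevents the build-up of high-frequency line-to-line
    error.  Offsets accumulate across iterations.
    """
    if k < 1 or iterations < 1:
        raise ValueError("k and iterations must be >= 1")
    H = image.heights.copy()
    rows, cols = H.shape
    offsets = np.zeros(rows)
    if noise_sigma is None:
        noise_sigma = estimate_noise_sigma(image)
    T = height_threshold_sigmas * noise_sigma
    min_cols = max(8, cols // 16)
    # near-background columns: within T of the line's smooth trend (a wide
    # running median per line, which follows tilt/bow but rides over
    # features narrower than half its window).  The trend is invariant
    # under the per-line constants this refinement subtracts, so the
    # selection is computed once.
    win = min(cols, cols // 2 * 2 + 1)
    trend = ndimage.median_filter(H, size=(1, win), mode="nearest")
    near_bg_all = np.abs(H - trend) <= T
    for it in range(iterations):
        top_down = it % 2 == 0
        line_order = range(1, rows) if top_down else range(rows - 2, -1, -1)
        for n in line_order:
            if top_down:
                window = np.arange(max(0, n - k), n)
            else:
                window = np.arange(n + 1, min(rows, n + 1 + k))
            valid = near_bg_all[n][None, :] & near_bg_all[window]
            enough = valid.sum(axis=1) >= min_cols
            valid[~enough] = True  # fall back to all columns for that pair
            diffs = H[n][None, :] - H[window]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                masked = np.where(valid, diffs, np.nan)
                med = np.nanmedian(masked, axis=1, keepdims=True)
                s = np.nanstd(masked, axis=1, keepdims=True)
                keep = valid & (np.abs(diffs - med) <= nsig * s)
                m_p = np.nanmedian(np.where(keep, diffs, np.nan), axis=1)
            m_p = m_p[np.isfinite(m_p)]
            if m_p.size == 0:
                continue
            if m_p.size > 1:
                sm = m_p.std()
                if sm > 0:
                    keep2 = np.abs(m_p - np.median(m_p)) <= nsig * sm
                    if keep2.any():
                        m_p = m_p[keep2]
            off = float(m_p.mean())
            H[n] -= off
            offsets[n] += off
    return image.with_heights(H), LineOffsets(offsets, ["running_average"])


def masked_median_correction(
    image: HeightImage,
    mask: np.ndarray,
    fallback: Optional[LineOffsets] = None,
    min_pixels: int = 1,
) -> Tuple[HeightImage, LineOffsets]:
    """Subtract, per line, the median of the pixels inside the background
    mask (the subtraction applies to the whole line).

    Lines with fewer than ``min_pixels`` masked pixels take the
    ``fallback`` offset for that line (zero when no fallback is given);
    they are listed in the returned offsets' ``fallback_lines``.  A mask
    empty on every line is degenerate.  With a full mask this reduces
    exactly to :func:`median_offset_correction`.
    """
    mask = np.asarray(mask, dtype=bool)
    H = image.heights
    if mask.shape != H.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise DegenerateMaskError("mask contains no pixels on any line")
    if fallback is not None and len(fallback) != H.shape[0]:
        raise ValueError("fallback offsets length must equal row count")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(np.where(mask, H, np.nan), axis=1)
    empty = ~np.isfinite(med) | (mask.sum(axis=1) < min_pixels)
    if empty.any():
        med[empty] = fallback.values[empty] if fallback is not None else 0.0
    out = H - med[:, None]
    return image.with_heights(out), LineOffsets(
        med, ["masked_median"], fallback_lines=tuple(int(i) for i in np.where(empty)[0])
    )


def vertical_median_correction(
    image: HeightImage, mask: np.ndarray, min_fraction: float = 0.5
) -> Tuple[HeightImage, np.ndarray]:
    """Masked median correction run in the perpendicular direction: subtract
    per *column* the median of the masked pixels in that column.

    A strong turn-around ripple can push much of a column's background
    outside the threshold band, leaving a biased tail of masked pixels;
    the masked median is therefore trusted only where the mask sees a
    majority of the column (``min_fraction``), and other columns fall back
    to the plain median of the whole column (the perpendicular analogue of
    the maskless-line fallback).

    Intended solely for high-speed AFM data with residual turn-around
    ripple; on ordinary images it should stay disabled.  Returns the
    corrected image and the per-column offsets.
    """
    mask = np.asarray(mask, dtype=bool)
    rows = image.heights.shape[0]
    timg = HeightImage(image.heights.T.copy(), pixel_size=image.pixel_size)
    fallback = LineOffsets(np.median(image.heights, axis=0), ["column_median"])
    out_t, offs = masked_median_correction(
        timg, mask.T, fallback=fallback, min_pixels=max(1, int(min_fraction * rows))
    )
    return image.with_heights(out_t.heights.T), offs.values
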