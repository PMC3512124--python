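"""Synthetic AFM scenes with known ground truth.

The generator builds the classic test construction for flattening
algorithms: randomly placed and sized half-spheres on a perfectly flat
background, then stacks the distortions that real instruments impose on the
z-channel -- additive Gaussian noise, sample tilt, second-order scanner bow,
random per-line offsets (line skips), scar segments, and, for high-speed
instruments, a decaying turn-around ripple along the fast axis.

Every applied distortion is recorded in a :class:`DistortionRecord`, so each
pipeline stage can be tested against an exact known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .image import HeightImage

#: Apex height per pixel of sphere radius (nm/px).  Radii of 5-30 px give
#: features 2.5-15 nm tall, typical of adsorbed vesicles or particles on a
#: flat substrate such as mica, and comfortably taller than the default
#: noise floor so that background/feature separation is a meaningful task.
DEFAULT_HEIGHT_SCALE = 0.5

#: Default z-noise standard deviation in nm.  Real instruments in fluid
#: typically sit in the 0.1-1 nm range; 0.5 nm is a deliberately harsh choice.
DEFAULT_NOISE_SIGMA = 0.5


@dataclass
class Topography:
    """Pure sample topography: half-spheres on an exactly-zero background."""

    heights: np.ndarray
    pixel_size: float = 1.0
    feature_mask: np.ndarray = None  # True exactly where heights > 0

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.feature_mask is None:
            self.feature_mask = self.heights > 0
        self.feature_mask = np.asarray(self.feature_mask, dtype=bool)

    @property
    def background_mask(self) -> np.ndarray:
        return ~self.feature_mask


@dataclass
class DistortionRecord:
    """Exact bookkeeping of every distortion applied to a topography.

    All fields are optional; a field left at its empty default is simply not
    applied, so an empty record is the identity.

    Fields
    ------
    noise_sigma:
        Std of additive Gaussian z-noise (nm).
    tilt_coeffs:
        ``(a_x, a_y)`` -- tilt in nm per full image span along the fast (x)
        and slow (y) axis.
    bow_coeffs:
        ``(b_x, b_y)`` -- peak-to-edge amplitude (nm) of a second-order bow
        ``b_x*(2u-1)^2 + b_y*(2v-1)^2`` with u, v in [0, 1].
    line_offsets_true:
        Additive constant per scan line (nm).
    scar_lines:
        Sequence of ``(line_index, (col_start, col_stop), amplitude_nm)``.
    ripple:
        ``(amplitude_nm, frequency_per_px, decay_px)`` -- turn-around ripple
        ``A * exp(-c/decay) * sin(2*pi*f*c)`` added per column, with ``c``
        the column distance from the turn-around edge (column 0).
    """

    noise_sigma: float = 0.0
    tilt_coeffs: Optional[tuple] = None
    bow_coeffs: Optional[tuple] = None
    line_offsets_true: Optional[np.ndarray] = None
    scar_lines: Sequence[tuple] = field(default_factory=list)
    ripple: Optional[tuple] = None

    def __post_init__(self):
        if self.line_offsets_true is not None:
            self.line_offsets_true = np.asarray(self.line_offsets_true, dtype=float)
        self.scar_lines = [
            (int(n), (int(c0), int(c1)), float(a)) for n, (c0, c1), a in self.scar_lines
        ]

    def to_dict(self) -> dict:
        return {
            "noise_sigma": float(self.noise_sigma),
            "tilt_coeffs": list(self.tilt_coeffs) if self.tilt_coeffs is not None else None,
            "bow_coeffs": list(self.bow_coeffs) if self.bow_coeffs is not None else None,
            "line_offsets_true": (
                self.line_offsets_true.tolist()
                if self.line_offsets_true is not None
                else None
            ),
            "scar_lines": [[n, [c0, c1], a] for n, (c0, c1), a in self.scar_lines],
            "ripple": list(self.ripple) if self.ripple is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistortionRecord":
        return cls(
            noise_sigma=d.get("noise_sigma", 0.0) or 0.0,
            tilt_coeffs=tuple(d["tilt_coeffs"]) if d.get("tilt_coeffs") else None,
            bow_coeffs=tuple(d["bow_coeffs"]) if d.get("bow_coeffs") else None,
            line_offsets_true=(
                np.asarray(d["line_offsets_true"], dtype=float)
                if d.get("line_offsets_true") is not None
                else None
            ),
            scar_lines=[(n, (c0, c1), a) for n, (c0, c1), a in d.get("scar_lines", [])],
            ripple=tuple(d["ripple"]) if d.get("ripple") else None,
        )


def generate_topography(
    rows: int,
    cols: int,
    n_spheres: int,
    radius_range=(5, 30),
    seed: int = 0,
    height_scale: float = DEFAULT_HEIGHT_SCALE,
    pixel_size: float = 1.0,
) -> Topography:
    """Half-spheres of random position and radius on a flat zero background.

    Each sphere of radius ``R`` (px) contributes
    ``h(r) = height_scale * sqrt(R^2 - r^2)`` for ``r < R``, i.e. a spherical
    cap with apex height ``height_scale * R`` nm.  Overlapping spheres merge
    by taking the pointwise maximum (caps sitting on the same substrate).

    Deterministic under a fixed ``seed``.
    """
    if rows < 8 or cols < 8:
        raise ValueError("image must be at least 8x8 pixels")
    r_lo, r_hi = float(radius_range[0]), float(radius_range[1])
    if not (0 < r_lo <= r_hi):
        raise ValueError("radius_range must be positive and ordered")
    if 2 * r_hi > min(rows, cols):
        raise ValueError(
            f"radius_range {radius_range} does not fit inside a {rows}x{cols} image"
        )
    rng = np.random.default_rng(seed)
    heights = np.zeros((rows, cols))
    yy, xx = np.mgrid[0:rows, 0:cols]
    for _ in range(int(n_spheres)):
        R = rng.uniform(r_lo, r_hi)
        cy = rng.uniform(R, rows - 1 - R)
        cx = rng.uniform(R, cols - 1 - R)
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        inside = r2 < R**2
        cap = np.zeros_like(heights)
        cap[inside] = height_scale * np.sqrt(R**2 - r2[inside])
        np.maximum(heights, cap, out=heights)
    return Topography(heights, pixel_size=pixel_size)


def apply_distortions(
    topo: Topography, record: DistortionRecord, seed: int = 0
) -> HeightImage:
    """Apply a distortion record to a topography.

    Order of application: noise, tilt plane, bow surface, per-line constants,
    scar segments, ripple (all additive, so the order only matters for the
    bookkeeping).  The returned image carries the record under
    ``metadata["ground_truth"]``.  An empty record is the identity.
    """
    rows, cols = topo.heights.shape
    out = topo.heights.copy()
    if record.noise_sigma and record.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out += rng.normal(0.0, record.noise_sigma, size=(rows, cols))
    u = np.linspace(0.0, 1.0, cols)[None, :] if cols > 1 else np.zeros((1, cols))
    v = np.linspace(0.0, 1.0, rows)[:, None] if rows > 1 else np.zeros((rows, 1))
    if record.tilt_coeffs is not None:
        a_x, a_y = record.tilt_coeffs
        out += a_x * u + a_y * v
    if record.bow_coeffs is not None:
        b_x, b_y = record.bow_coeffs
        out += b_x * (2 * u - 1) ** 2 + b_y * (2 * v - 1) ** 2
    if record.line_offsets_true is not None:
        if record.line_offsets_true.size != rows:
            raise ValueError("line_offsets_true length must equal row count")
        out += record.line_offsets_true[:, None]
    for n, (c0, c1), amp in record.scar_lines:
        out[n, c0:c1] += amp
    if record.ripple is not None:
        amp, freq, decay = record.ripple
        c = np.arange(cols, dtype=float)
        out += (amp * np.exp(-c / decay) * np.sin(2 * np.pi * freq * c))[None, :]
    return HeightImage(
        out, pixel_size=topo.pixel_size, metadata={"ground_truth": record}
    )


def standard_distortions(
    rows: int,
    cols: int,
    seed: int = 0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    tilt_max: float = 10.0,
    bow_max: float = 10.0,
    line_offset_max: float = 5.0,
    n_scars: int = 2,
    scar_amp_factor: float = 10.0,
    ripple: Optional[tuple] = None,
) -> DistortionRecord:
    """Draw a distortion record in the standard difficulty regime.

    Tilt and bow amplitudes are drawn uniformly within ±10 nm over the scan
    span (a realistic worst case for well-aligned samples), per-line offsets
    uniformly within ±5 nm, and scars as short raised segments of amplitude
    ``scar_amp_factor`` times the noise sigma.
    """
    rng = np.random.default_rng(seed)
    tilt = (rng.uniform(-tilt_max, tilt_max), rng.uniform(-tilt_max, tilt_max))
    bow = (rng.uniform(-bow_max, bow_max), rng.uniform(-bow_max, bow_max))
    offsets = rng.uniform(-line_offset_max, line_offset_max, size=rows)
    scars = []
    scar_amp = scar_amp_factor * (noise_sigma if noise_sigma > 0 else 0.1)
    for _ in range(int(n_scars)):
        n = int(rng.integers(1, rows - 1))
        length = int(rng.integers(15, 41))
        c0 = int(rng.integers(0, max(1, cols - length)))
        scars.append((n, (c0, c0 + length), scar_amp))
    return DistortionRecord(
        noise_sigma=noise_sigma,
        tilt_coeffs=tilt,
        bow_coeffs=bow,
        line_offsets_true=offsets,
        scar_lines=scars,
        ripple=ripple,
    )


@dataclass
class SyntheticScene:
    """A topography, the distortions applied to it, and the distorted image."""

    topography: Topography
    record: DistortionRecord
    image: HeightImage


def standard_scene(
    seed: int = 0,
    rows: int = 256,
    cols: int = 256,
    n_spheres: int = 20,
    radius_range=(5, 30),
    height_scale: float = DEFAULT_HEIGHT_SCALE,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    **distortion_kwargs,
) -> SyntheticScene:
    """The standard fully-distorted test scene.

    Half-spheres covering roughly 30% of a 256x256 field (so ~70% flat
    background), noise sigma 0.5 nm, tilt and bow within ±10 nm over the
    span, per-line offsets within ±5 nm and two scar segments.
    """
    rng = np.random.default_rng(seed)
    s_topo, s_dist, s_noise = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))
    topo = generate_topography(
        rows, cols, n_spheres, radius_range, seed=s_topo, height_scale=height_scale
    )
    record = standard_distortions(
        rows, cols, seed=s_dist, noise_sigma=noise_sigma, **distortion_kwargs
    )
    image = apply_distortions(topo, record, seed=s_noise)
    return SyntheticScene(topo, record, image)


def generate_sequence(
    n_frames: int,
    seed: int = 0,
    rows: int = 256,
    cols: int = 256,
    n_spheres: int = 20,
    radius_range=(5, 30),
    height_scale: float = DEFAULT_HEIGHT_SCALE,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    **distortion_kwargs,
) -> tuple:
    """A movie: one fixed topography, per-frame random distortions.

    Returns ``(topography, frames)`` where each frame is a
    :class:`HeightImage` with its own ground-truth record and
    ``frame_index`` set.  Emulates an HS-AFM sequence where the sample is
    static but tilt, offsets and noise vary frame to frame.
    """
    rng = np.random.default_rng(seed)
    s_topo = int(rng.integers(0, 2**31 - 1))
    topo = generate_topography(
        rows, cols, n_spheres, radius_range, seed=s_topo, height_scale=height_scale
    )
    frames = []
    for i in range(int(n_frames)):
        s_dist, s_noise = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
        record = standard_distortions(
            rows, cols, seed=s_dist, noise_sigma=noise_sigma, **distortion_kwargs
        )
        frame = apply_distortions(topo, record, seed=s_noise)
        frame.frame_index = i
        frames.append(frame)
    return topo, frames
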