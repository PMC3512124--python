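"""2-D polynomial background estimation and subtraction.

The smooth distortions of an AFM image -- sample tilt and piezo-scanner
bow -- are modelled as a 2-D polynomial of total degree up to five, fitted
by plain least squares over the pixels of a background mask only, then
subtracted from the *whole* image.  Coordinates are normalised to [-1, 1]
per axis before fitting: raw pixel indices at order 5 on 512^2 images make
the monomial design numerically hostile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .image import HeightImage, IllConditionedFitError

MAX_ORDER = 5


def monomial_exponents(order: int):
    """Exponent pairs (p, q) for x^p * y^q with p+q <= order, in a fixed
    deterministic order (by total degree, then descending x power):
    1, x, y, x^2, xy, y^2, ..."""
    return [(t - q, q) for t in range(order + 1) for q in range(t + 1)]


def n_coefficients(order: int) -> int:
    return (order + 1) * (order + 2) // 2


def _axis_coords(n: int) -> np.ndarray:
    return np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n)


def _design(shape: Tuple[int, int], order: int, mask: Optional[np.ndarray] = None):
    rows, cols = shape
    y = _axis_coords(rows)[:, None]
    x = _axis_coords(cols)[None, :]
    if mask is None:
        xs = np.broadcast_to(x, shape).ravel()
        ys = np.broadcast_to(y, shape).ravel()
    else:
        ys_i, xs_i = np.nonzero(mask)
        xs = _axis_coords(cols)[xs_i]
        ys = _axis_coords(rows)[ys_i]
    cols_list = [xs**p * ys**q for p, q in monomial_exponents(order)]
    return np.stack(cols_list, axis=1)


@dataclass
class PolynomialSurface:
    """A fitted 2-D polynomial background.

    Coefficients (nm) are over normalised [-1, 1] coordinates, ordered as
    :func:`monomial_exponents`; ``shape`` is the image shape the surface was
    fitted on and evaluates over.
    """

    order: int
    coefficients: np.ndarray
    shape: Tuple[int, int]

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != n_coefficients(self.order):
            raise ValueError(
                f"order {self.order} needs {n_coefficients(self.order)} coefficients, "
                f"got {self.coefficients.size}"
            )

    def evaluate(self) -> np.ndarray:
        """The surface as a full height field over its domain."""
        A = _design(self.shape, self.order)
        return (A @ self.coefficients).reshape(self.shape)

    def to_dict(self) -> dict:
        return {
            "order": int(self.order),
            "coefficients": self.coefficients.tolist(),
            "shape": [int(s) for s in self.shape],
            "coordinates": "normalized [-1,1] per axis, x=fast (columns), y=slow (rows)",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialSurface":
        return cls(int(d["order"]), np.asarray(d["coefficients"], float), tuple(d["shape"]))


def fit_polynomial_surface(
    image: HeightImage,
    mask: Optional[np.ndarray] = None,
    order: int = 2,
) -> PolynomialSurface:
    """Least-squares polynomial surface over the masked pixels only.

    The fit sees nothing outside the mask, so arbitrary feature pixels
    cannot bias it.  Raises :class:`IllConditionedFitError` when the mask
    geometry leaves the design rank deficient (e.g. a mask confined to one
    scan line) or keeps fewer pixels than coefficients.
    """
    if not 0 <= order <= MAX_ORDER:
        raise ValueError(f"order must be in [0, {MAX_ORDER}]")
    H = image.heights
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != H.shape:
            raise ValueError("mask shape must match image shape")
    ncoef = n_coefficients(order)
    npix = int(mask.sum()) if mask is not None else H.size
    if npix < ncoef:
        raise IllConditionedFitError(
            f"mask keeps {npix} pixels but an order-{order} surface has {ncoef} coefficients"
        )
    A = _design(H.shape, order, mask)
    b = H[mask] if mask is not None else H.ravel()
    coeffs, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < ncoef:
        if mask is not None:
            ys, xs = np.nonzero(mask)
            geom = (
                f"mask spans rows {ys.min()}..{ys.max()}, cols {xs.min()}..{xs.max()}"
            )
        else:
            geom = f"image shape {H.shape}"
        raise IllConditionedFitError(
            f"rank-deficient order-{order} fit (rank {rank} < {ncoef}); {geom}"
        )
    return PolynomialSurface(order=order, coefficients=coeffs, shape=H.shape)


def subtract_surface(image: HeightImage, surface: PolynomialSurface) -> HeightImage:
    """Subtract the surface from every pixel, masked or not."""
    if tuple(surface.shape) != image.heights.shape:
        raise ValueError(
            f"surface domain {surface.shape} does not match image shape {image.heights.shape}"
        )
    return image.with_heights(image.heights - surface.evaluate())


def global_tilt_removal(
    image: HeightImage,
    sigma_ref: Optional[float] = None,
    tol: float = 0.0,
    tie_break: float = 1e-3,
) -> Tuple[HeightImage, int, dict]:
    """Unthresholded first- vs second-order background removal.

    Both candidate removals are computed with a full-image mask; the one
    with the lower resulting standard deviation progresses, provided it does
    not exceed ``sigma_ref`` (the std after the preceding median
    correction).  Otherwise the input passes through unchanged.  Because the
    two fits are nested, the order-2 residual is never larger in-sample;
    order 2 is chosen only when it wins by more than the relative
    ``tie_break`` (otherwise it is merely absorbing noise).  Returns
    ``(image, chosen_order, verdict)`` with chosen_order 0 on pass-through;
    the verdict records both candidate sigmas, the margin against
    ``sigma_ref`` and (when accepted) the subtracted surface.
    """
    if sigma_ref is None:
        sigma_ref = image.std()
    candidates = {}
    for order in (1, 2):
        surf = fit_polynomial_surface(image, None, order)
        cand = subtract_surface(image, surf)
        candidates[order] = (cand, surf, cand.std())
    best_order = 2 if candidates[2][2] < candidates[1][2] * (1.0 - tie_break) else 1
    cand, surf, sigma_best = candidates[best_order]
    accepted = sigma_best <= sigma_ref * (1.0 + tol)
    verdict = {
        "sigma_ref": float(sigma_ref),
        "sigma_order1": float(candidates[1][2]),
        "sigma_order2": float(candidates[2][2]),
        "chosen_order": int(best_order) if accepted else 0,
        "accepted": bool(accepted),
        "margin": float(sigma_ref - sigma_best),
        "surface": surf if accepted else None,
    }
    if accepted:
        return cand, best_order, verdict
    return image, 0, verdict
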