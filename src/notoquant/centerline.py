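"""Polynomial centerline fitting and curved-path intensity profiling.

The notochord axis is modelled as a degree-6 polynomial ``y(x)`` fitted by
ordinary least squares to every mask pixel (one term per pixel, unweighted).
The intensity profile is then sampled along that curve at uniform arc-length
spacing — a profile line generalised from a straight segment to a polynomial
path — using bilinear interpolation, optionally averaged over ``linewidth``
parallel samples along the local normal.  Samples falling outside the image
are dropped, not clamped, and their count is reported.

Fitting is performed on x rescaled to [-1, 1] for conditioning; the reported
coefficients are in pixel units (ascending powers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
from numpy.polynomial import Polynomial
from numpy.polynomial.polynomial import polyval as _polyval
from scipy.ndimage import map_coordinates

from .errors import CenterlineFitError, ProfileError
from .segmentation import NotochordMask

#: subdivisions per pixel of x used for the dense arc-length table
ARC_SUBDIV = 16


@dataclass(frozen=True)
class PolynomialCenterline:
    """Fitted curve y = sum c_i x^i over the mask's x extent."""

    degree: int
    coefficients: tuple[float, ...]  # ascending powers, pixel units
    x_domain: tuple[float, float]

    def __post_init__(self):
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )
        if not all(np.isfinite(self.coefficients)):
            raise CenterlineFitError("non-finite centerline coefficients")
        if not self.x_domain[1] > self.x_domain[0]:
            raise CenterlineFitError("degenerate x domain")

    def y(self, x) -> np.ndarray:
        return _polyval(np.asarray(x, dtype=float), np.asarray(self.coefficients))

    def dy_dx(self, x) -> np.ndarray:
        c = np.asarray(self.coefficients)
        dc = c[1:] * np.arange(1, len(c))
        if len(dc) == 0:
            return np.zeros_like(np.asarray(x, dtype=float))
        return _polyval(np.asarray(x, dtype=float), dc)

    def to_json(self) -> str:
        return json.dumps(
            {
                "degree": self.degree,
                "coefficients": list(self.coefficients),
                "x_domain": list(self.x_domain),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PolynomialCenterline":
        d = json.loads(s)
        return cls(d["degree"], tuple(d["coefficients"]), tuple(d["x_domain"]))


@dataclass(frozen=True)
class IntensityProfile:
    """Arc-length-ordered intensity samples along a centerline.

    ``arc_positions`` are the arc-length coordinates (pixels) of the retained
    samples; dropped (out-of-bounds) samples are counted in ``n_dropped``.
    """

    arc_positions: np.ndarray
    intensities: np.ndarray
    sampling_step: float
    linewidth: int = 1
    n_dropped: int = 0

    def __post_init__(self):
        a = np.asarray(self.arc_positions, dtype=float)
        v = np.asarray(self.intensities, dtype=float)
        if a.shape != v.shape or a.ndim != 1:
            raise ProfileError("arc_positions and intensities must be 1D and equal length")
        if len(a) > 1 and not np.all(np.diff(a) > 0):
            raise ProfileError("arc positions must be strictly increasing")
        object.__setattr__(self, "arc_positions", a)
        object.__setattr__(self, "intensities", v)

    def __len__(self) -> int:
        return len(self.arc_positions)


def fit_polynomial_centerline(
    mask: NotochordMask, degree: int = 6
) -> PolynomialCenterline:
    """Unweighted OLS fit of y on powers of x over every mask pixel.

    Requires at least ``degree + 1`` distinct x values; the x domain is the
    mask's [min x, max x].
    """
    xs, ys = mask.coords()
    n_distinct = len(np.unique(xs))
    if n_distinct < degree + 1:
        raise CenterlineFitError(
            f"degree-{degree} fit needs {degree + 1} distinct x values, "
            f"mask has {n_distinct}"
        )
    # Polynomial.fit maps x onto [-1, 1] internally (conditioning), then the
    # series is converted back to pixel-unit power coefficients.
    fitted = Polynomial.fit(xs.astype(float), ys.astype(float), deg=degree)
    poly = fitted.convert()
    coeffs = np.zeros(degree + 1)
    coeffs[: len(poly.coef)] = poly.coef
    return PolynomialCenterline(
        degree=degree,
        coefficients=tuple(coeffs),
        x_domain=(float(xs.min()), float(xs.max())),
    )


def fit_residual_rms(mask: NotochordMask, curve: PolynomialCenterline) -> float:
    """RMS of y residuals of the mask pixels about the fitted curve (QC)."""
    xs, ys = mask.coords()
    r = ys - curve.y(xs)
    return float(np.sqrt(np.mean(r ** 2)))


def arc_length_samples(
    curve: PolynomialCenterline, step: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Points along the curve at uniform arc-length spacing.

    Returns ``(positions, points, tangents)``: arc-length coordinates starting
    at 0 and spaced by ``step`` (the curve endpoint is appended as a final,
    possibly shorter, sample), the ``(M, 2)`` array of (x, y) points, and the
    ``(M, 2)`` unit tangents from the analytic derivative.

    The arc-length map is computed from cumulative chord length over a dense
    parameter table (:data:`ARC_SUBDIV` subdivisions per pixel of x) and
    inverted by linear interpolation.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    x0, x1 = curve.x_domain
    n_dense = max(2, int(np.ceil((x1 - x0) * ARC_SUBDIV)) + 1)
    xd = np.linspace(x0, x1, n_dense)
    yd = curve.y(xd)
    seg = np.hypot(np.diff(xd), np.diff(yd))
    s_cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_cum[-1]
    positions = np.arange(0.0, total + step * 1e-9, step)
    if total - positions[-1] > 1e-6:
        positions = np.append(positions, total)
    xs = np.interp(positions, s_cum, xd)
    ys = curve.y(xs)
    d = curve.dy_dx(xs)
    norm = np.hypot(1.0, d)
    tangents = np.stack([1.0 / norm, d / norm], axis=1)
    points = np.stack([xs, ys], axis=1)
    return positions, points, tangents


def _bilinear(image: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact bilinear interpolation at (x, y); caller guarantees in-bounds."""
    return map_coordinates(
        image.astype(np.float64), np.stack([y, x]), order=1, mode="nearest"
    )


def extract_profile(
    image: np.ndarray,
    curve: PolynomialCenterline,
    step: float = 1.0,
    linewidth: int = 1,
) -> IntensityProfile:
    """Intensity profile along the polynomial centerline.

    At every arc-length sample the intensity is the bilinear interpolation at
    the curve point (``linewidth=1``), or the mean of ``linewidth`` bilinear
    samples spaced 1 px along the local normal, centred on the curve
    (``linewidth`` must be odd).  Sample points outside the grid of pixel
    centres are excluded; an arc position with no in-bounds point is dropped
    and counted in ``n_dropped``.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ProfileError("expected a 2D grayscale image")
    if linewidth < 1 or linewidth % 2 == 0:
        raise ProfileError("linewidth must be a positive odd integer")
    h, w = image.shape
    positions, points, tangents = arc_length_samples(curve, step)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    offsets = np.arange(linewidth) - linewidth // 2  # e.g. [-1, 0, 1]
    # (linewidth, M, 2) sampling points
    pts = points[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    xf, yf = pts[..., 0], pts[..., 1]
    inb = (xf >= 0) & (xf <= w - 1) & (yf >= 0) & (yf <= h - 1)
    values = np.full(xf.shape, np.nan)
    if inb.any():
        values[inb] = _bilinear(image, xf[inb], yf[inb])
    with np.errstate(invalid="ignore"):
        counts = inb.sum(axis=0)
        means = np.where(counts > 0, np.nansum(values, axis=0) / np.maximum(counts, 1), np.nan)
    keep = counts > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ProfileError("every profile sample falls outside the image")
    return IntensityProfile(
        arc_positions=positions[keep],
        intensities=means[keep],
        sampling_step=float(step),
        linewidth=int(linewidth),
        n_dropped=n_dropped,
    )
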