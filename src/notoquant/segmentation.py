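"""Notochord detection by intensity thresholding.

Step one of the lesion pipeline: pixels at or above a user-chosen grey
threshold are the notochord.  The published procedure used a manually set
threshold; an Otsu fallback is available but never the default.  Inclusion is
``I >= threshold`` (the boundary pixel is in), a convention fixed here and
relied on by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

from .errors import SegmentationError


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold configuration.  ``auto_mode`` enables the Otsu fallback when
    no manual threshold is supplied."""

    threshold: float | None = None
    auto_mode: bool = False


@dataclass(frozen=True)
class NotochordMask:
    """Set of detected notochord pixels over a known image shape."""

    pixels: np.ndarray  # bool (H, W)

    def __post_init__(self):
        if self.pixels.ndim != 2 or self.pixels.dtype != bool:
            raise ValueError("mask must be a 2D boolean array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def size(self) -> int:
        return int(self.pixels.sum())

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) integer coordinates of mask pixels (x = column, y = row)."""
        ys, xs = np.nonzero(self.pixels)
        return xs, ys

    def bbox(self) -> tuple[int, int, int, int]:
        """(x_min, x_max, y_min, y_max) inclusive bounds of the mask."""
        xs, ys = self.coords()
        return int(xs.min()), int(xs.max()), int(ys.min()), int(ys.max())

    def is_vertical(self) -> bool:
        """True when the bounding box is taller than wide (needs transpose)."""
        x0, x1, y0, y1 = self.bbox()
        return (y1 - y0) > (x1 - x0)

    def transposed(self) -> "NotochordMask":
        return NotochordMask(self.pixels.T.copy())


def threshold_mask(
    image: np.ndarray, params: SegmentationParams | float
) -> NotochordMask:
    """Pixels with ``I >= threshold``.

    Raises :class:`SegmentationError` (carrying the threshold used) when no
    pixel qualifies, so the caller can report "no notochord detected".
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise SegmentationError("expected a non-empty 2D grayscale image")
    if isinstance(params, SegmentationParams):
        thr = params.threshold
        if thr is None:
            if not params.auto_mode:
                raise SegmentationError("no threshold given and auto_mode is off")
            thr = auto_threshold(image)
    else:
        thr = float(params)
    mask = image >= thr
    if not mask.any():
        raise SegmentationError(
            f"no notochord detected at threshold {thr}", threshold=float(thr)
        )
    return NotochordMask(mask)


def largest_component(mask: NotochordMask) -> NotochordMask:
    """Largest 8-connected component of the mask.

    Suppresses off-notochord bright debris before centerline fitting.  Size
    ties are broken by the smallest minimum x, then smallest minimum y.
    """
    if mask.size == 0:
        raise SegmentationError("cannot take largest component of an empty mask")
    labels = _cc_label(mask.pixels, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0  # background
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) > 1:
        # deterministic tie-break: smallest min-x, then smallest min-y
        def key(lab: int) -> tuple[int, int]:
            ys, xs = np.nonzero(labels == lab)
            return int(xs.min()), int(ys.min())

        winner = min(candidates, key=key)
    else:
        winner = candidates[0]
    return NotochordMask(labels == winner)


def auto_threshold(image: np.ndarray) -> float:
    """Otsu's threshold: the grey value maximising between-class variance.

    Optional fallback for when no manual threshold is available; combined
    with the ``>=`` convention of :func:`threshold_mask`.
    """
    image = np.asarray(image)
    if image.size == 0 or np.all(image == image.flat[0]):
        raise SegmentationError("auto threshold needs at least two distinct grey values")
    t = float(threshold_otsu(image))
    # threshold_otsu assumes a ``>`` convention; with our ``>=`` inclusion the
    # returned value is shifted to the middle of the gap between the classes,
    # which yields the identical (variance-maximising) split.
    vals = np.unique(image)
    lo = float(vals[vals <= t].max())
    above = vals[vals > t]
    if len(above) == 0:
        return t
    return (lo + float(above.min())) / 2.0
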