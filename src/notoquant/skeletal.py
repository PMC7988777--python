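"""Skeletal and histological quantifications.

Three independent utilities used alongside the image pipeline:

* the vertebral-column severity rubric — an ordinal 0–3 score from a count
  of abnormalities (fusions or clefts), scored per category;
* two-phantom tissue-mineral-density (TMD) calibration — an affine map from
  µCT grey values to g/cm³ hydroxyapatite anchored at phantoms of known
  density (0.25 and 0.75 g/cm³ HA by default);
* per-channel mean intensities over a region of interest in an RGB stain
  image (Picro-Sirius Red collagen tones, TRAP red signal).

The rubric intervals, printed for a count n, are: score 0 for n = 0, score 1
for 1 <= n <= 3, score 2 for n = 4 (the only integer with 3 < n < 5) and
score 3 for n >= 5.  Counts are integers, which makes the intervals
exhaustive and non-overlapping (n = 0 takes precedence over n <= 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SeverityScore:
    score: int  # 0..3
    basis: int  # the count that produced it


@dataclass(frozen=True)
class TmdCalibration:
    """Affine grey→density map anchored at two phantoms.

    d(g) = density_lo + (g − grey_lo) · (density_hi − density_lo)
                                        / (grey_hi − grey_lo)
    """

    grey_lo: float
    grey_hi: float
    density_lo: float = 0.25  # g/cm³ HA
    density_hi: float = 0.75

    def __post_init__(self):
        if not self.grey_hi > self.grey_lo:
            raise ValueError("grey_hi must exceed grey_lo")


@dataclass(frozen=True)
class RegionChannelMeans:
    roi_id: str
    mean_red: float
    mean_green: float
    mean_blue: float
    n_pixels: int


def severity_rubric(n: int) -> SeverityScore:
    """Ordinal severity 0–3 from an abnormality count (integer, >= 0)."""
    if isinstance(n, bool) or not float(n).is_integer():
        raise ValueError(f"count must be an integer, got {n!r}")
    n = int(n)
    if n < 0:
        raise ValueError("count must be >= 0")
    if n == 0:
        score = 0
    elif n <= 3:
        score = 1
    elif n < 5:  # n == 4
        score = 2
    else:
        score = 3
    return SeverityScore(score=score, basis=n)


def score_fish(fusions: int, clefts: int, mode: str = "independent") -> dict:
    """Rubric scores for one fish.

    mode "independent" (default): fusions and clefts scored separately, plus
    their maximum as the per-fish score.  mode "combined": the rubric applied
    to the summed count.
    """
    if mode == "independent":
        fs = severity_rubric(fusions).score
        cs = severity_rubric(clefts).score
        return {"fusion_score": fs, "cleft_score": cs, "fish_score": max(fs, cs)}
    if mode == "combined":
        fs = severity_rubric(fusions).score
        cs = severity_rubric(clefts).score
        return {
            "fusion_score": fs,
            "cleft_score": cs,
            "fish_score": severity_rubric(int(fusions) + int(clefts)).score,
        }
    raise ValueError(f"unknown scoring mode {mode!r}")


def score_table(counts: pd.DataFrame, mode: str = "independent") -> pd.DataFrame:
    """Vectorised :func:`score_fish` over a (fish_id, fusions, clefts) table."""
    rows = []
    for idx, row in counts.iterrows():
        try:
            scores = score_fish(row["fusions"], row["clefts"], mode=mode)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        rows.append({**{c: row[c] for c in counts.columns}, **scores})
    return pd.DataFrame(rows)


def tmd_calibrate(
    grey_lo: float,
    grey_hi: float,
    density_lo: float = 0.25,
    density_hi: float = 0.75,
) -> TmdCalibration:
    """Calibration from the mean grey values of the two density phantoms."""
    return TmdCalibration(
        grey_lo=float(grey_lo),
        grey_hi=float(grey_hi),
        density_lo=float(density_lo),
        density_hi=float(density_hi),
    )


def tmd_apply(cal: TmdCalibration, mean_grey: float) -> tuple[float, bool]:
    """Density (g/cm³ HA) for a segmented-bone mean grey value.

    Returns ``(density, extrapolated)``; values outside the phantom grey
    range are mapped by the same affine extension and flagged, never clamped
    (a negative density is a visible data problem, not something to hide).
    """
    g = float(mean_grey)
    slope = (cal.density_hi - cal.density_lo) / (cal.grey_hi - cal.grey_lo)
    density = cal.density_lo + (g - cal.grey_lo) * slope
    extrapolated = g < cal.grey_lo or g > cal.grey_hi
    return density, extrapolated


def channel_means(
    image: np.ndarray,
    roi: tuple[int, int, int, int] | np.ndarray | None = None,
    roi_id: str = "roi",
) -> RegionChannelMeans:
    """Per-channel arithmetic means of an RGB image over a region of interest.

    ``roi`` is a rectangle ``(y0, y1, x0, x1)`` (half-open), a boolean mask of
    the image shape, or ``None`` for the full frame.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if roi is None:
        sel = image.reshape(-1, 3)
    elif isinstance(roi, np.ndarray):
        if roi.shape != image.shape[:2] or roi.dtype != bool:
            raise ValueError("mask ROI must be boolean with the image's 2D shape")
        sel = image[roi]
    else:
        y0, y1, x0, x1 = roi
        h, w = image.shape[:2]
        if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
            raise ValueError("rectangle ROI out of bounds")
        sel = image[y0:y1, x0:x1].reshape(-1, 3)
    if sel.shape[0] == 0:
        raise ValueError("ROI selects no pixels")
    means = sel.astype(np.float64).mean(axis=0)
    return RegionChannelMeans(
        roi_id=roi_id,
        mean_red=float(means[0]),
        mean_green=float(means[1]),
        mean_blue=float(means[2]),
        n_pixels=int(sel.shape[0]),
    )
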