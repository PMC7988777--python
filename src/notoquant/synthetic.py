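"""Synthetic notochord fluorescence images with known ground truth.

The simulator emulates the kind of image the lesion pipeline consumes: a
single larval zebrafish notochord seen as a bright, gently curved tube on a
dim noisy background, imaged roughly horizontally.  Lesions appear as
localized regions of elevated fluorescence inside the tube — a Gaussian bump
in intensity along the tube axis, i.e. a profile peak with higher intensity
and broader area than the surrounding tube.

Image model
-----------
* Coordinates: ``x`` = column, ``y`` = row, origin top-left, pixel centers at
  integer coordinates.
* The tube is hard-edged: a pixel is "in tube" when ``|y - f(x)| <= radius``
  where ``f`` is a polynomial centerline ``y(x)``.
* In-tube intensity is ``tube_intensity`` plus the sum of lesion terms
  ``amplitude * exp(-(x - center_x)^2 / (2 width_sigma^2))``; off-tube pixels
  take ``background_intensity``.
* Optional Gaussian blur (``edge_softness``) softens the edges, then iid
  Gaussian noise is added, and the result is rounded and clipped to the bit
  depth (camera quantisation and saturation).

Everything is deterministic given the ground truth (including its seed), so
generated images double as oracles for the downstream pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Chebyshev, Polynomial
from numpy.polynomial.polynomial import polyval as _polyval
from scipy.ndimage import gaussian_filter

from .errors import GeometryError

#: bump when the generated pixels for a given GroundTruth could change
GENERATOR_VERSION = "1"

# geometry invariant is checked on a grid this many times finer than a pixel
_GEOM_SUBDIV = 10


# ---------------------------------------------------------------------------
# ground-truth types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeModel:
    """Geometry and photometry of one synthetic notochord."""

    image_height: int
    image_width: int
    centerline_coeffs: tuple[float, ...]  # ascending powers: y = sum c_i x^i
    tube_radius: float
    tube_intensity: float
    background_intensity: float
    edge_softness: float = 0.0  # Gaussian blur sigma (pixels)
    bit_depth: int = 16

    def __post_init__(self):
        object.__setattr__(
            self, "centerline_coeffs", tuple(float(c) for c in self.centerline_coeffs)
        )
        self.validate()

    # -- geometry -----------------------------------------------------------

    def centerline_y(self, x) -> np.ndarray:
        """Evaluate the true centerline y(x)."""
        return _polyval(np.asarray(x, dtype=float), np.asarray(self.centerline_coeffs))

    def in_tube(self) -> np.ndarray:
        """Boolean (H, W) array of pixels with |y - f(x)| <= radius."""
        fy = self.centerline_y(np.arange(self.image_width))
        yy = np.arange(self.image_height)[:, None]
        return np.abs(yy - fy[None, :]) <= self.tube_radius

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    def validate(self) -> None:
        if self.image_height < 3 or self.image_width < 3:
            raise GeometryError("image must be at least 3x3 pixels")
        if self.tube_radius <= 0:
            raise GeometryError("tube_radius must be positive")
        if self.edge_softness < 0:
            raise GeometryError("edge_softness must be >= 0")
        if self.bit_depth not in (8, 16):
            raise GeometryError("bit_depth must be 8 or 16")
        if not self.tube_intensity > self.background_intensity:
            raise GeometryError("tube_intensity must exceed background_intensity")
        # the curve must stay within [r, H - r] for all x in [0, W)
        xs = np.arange(0, self.image_width, 1.0 / _GEOM_SUBDIV)
        fy = self.centerline_y(xs)
        lo, hi = self.tube_radius, self.image_height - self.tube_radius
        if fy.min() < lo or fy.max() > hi:
            raise GeometryError(
                f"centerline leaves the image: y(x) in [{fy.min():.2f}, {fy.max():.2f}]"
                f" must stay within [{lo:.2f}, {hi:.2f}]"
            )


@dataclass(frozen=True)
class LesionSpec:
    """One lesion: a Gaussian intensity bump along the tube axis."""

    center_x: float
    amplitude: float  # grey value added at the bump center (pre-clip)
    width_sigma: float  # pixels

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("lesion amplitude must be > 0")
        if self.width_sigma <= 0:
            raise ValueError("lesion width_sigma must be > 0")
        if self.center_x < 0:
            raise ValueError("lesion center_x must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Full generating description of one synthetic image.

    Serialisable, and together with :data:`GENERATOR_VERSION` it fully
    determines the image — the oracle for recovery tests.
    """

    tube: TubeModel
    lesions: tuple[LesionSpec, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "lesions", tuple(self.lesions))
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for les in self.lesions:
            if not 0 <= les.center_x < self.tube.image_width:
                raise ValueError("lesion center_x must lie within [0, image_width)")

    def lesion_term(self, x) -> np.ndarray:
        """Additive in-tube intensity contributed by all lesions at column x."""
        x = np.asarray(x, dtype=float)
        total = np.zeros_like(x)
        for les in self.lesions:
            total += les.amplitude * np.exp(
                -((x - les.center_x) ** 2) / (2.0 * les.width_sigma ** 2)
            )
        return total

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "generator_version": GENERATOR_VERSION,
            "tube": dataclasses.asdict(self.tube) | {
                "centerline_coeffs": list(self.tube.centerline_coeffs)
            },
            "lesions": [dataclasses.asdict(l) for l in self.lesions],
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        tube = TubeModel(**d["tube"])
        lesions = tuple(LesionSpec(**l) for l in d["lesions"])
        return cls(tube=tube, lesions=lesions,
                   noise_sigma=d["noise_sigma"], seed=d["seed"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# image generation
# ---------------------------------------------------------------------------

def generate_notochord_image(truth: GroundTruth) -> np.ndarray:
    """Render a ground truth into a single-channel image.

    Returns an ``(H, W)`` integer array (uint8 or uint16 per the tube's bit
    depth).  Bit-identical for identical ``truth``.
    """
    tube = truth.tube
    tube.validate()
    W, H = tube.image_width, tube.image_height
    x = np.arange(W)
    add = truth.lesion_term(x)
    in_tube = tube.in_tube()
    img = np.where(
        in_tube,
        tube.tube_intensity + add[None, :],
        float(tube.background_intensity),
    ).astype(np.float64)
    if tube.edge_softness > 0:
        img = gaussian_filter(img, sigma=tube.edge_softness, mode="nearest")
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        img = img + rng.normal(0.0, truth.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, tube.max_value).astype(tube.dtype)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: distribution spec: ("fixed", v) | ("poisson", lam) | ("uniform", lo, hi)
#: | ("normal", mu, sd)
Distribution = tuple


def _sample_count(dist: Distribution, rng: np.random.Generator) -> int:
    kind = dist[0]
    if kind == "fixed":
        v = int(dist[1])
        if v < 0:
            raise ValueError("fixed count must be >= 0")
        return v
    if kind == "poisson":
        lam = float(dist[1])
        if lam < 0:
            raise ValueError("poisson rate must be >= 0")
        return int(rng.poisson(lam))
    raise ValueError(f"unknown count distribution {kind!r}")


def _sample_value(dist: Distribution, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "fixed":
        return float(dist[1])
    if kind == "uniform":
        lo, hi = float(dist[1]), float(dist[2])
        if hi < lo:
            raise ValueError("uniform bounds reversed")
        return float(rng.uniform(lo, hi))
    if kind == "normal":
        return float(rng.normal(float(dist[1]), float(dist[2])))
    raise ValueError(f"unknown value distribution {kind!r}")


@dataclass(frozen=True)
class GroupSpec:
    """One experimental arm of a simulated cohort."""

    label: str
    n_fish: int
    lesion_count: Distribution = ("fixed", 0)
    lesion_amplitude: Distribution = ("uniform", 40.0, 80.0)

    def __post_init__(self):
        if self.n_fish < 1:
            raise ValueError("each group needs n_fish >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Shared imaging conditions plus per-group lesion statistics.

    Per-fish random streams are derived by hashing (cohort seed, group index,
    fish index) through :class:`numpy.random.SeedSequence`, so adding a group
    or extending one never reshuffles existing fish.
    """

    groups: tuple[GroupSpec, ...]
    image_height: int = 150
    image_width: int = 700
    tube_radius: float = 8.0
    tube_intensity: float = 120.0
    background_intensity: float = 20.0
    edge_softness: float = 1.0
    noise_sigma: float = 4.0
    bit_depth: int = 16
    curve_degree: int = 3
    curve_max_amplitude: float = 12.0  # max vertical wiggle of the centerline
    lesion_width: Distribution = ("uniform", 4.0, 10.0)
    min_lesion_spacing: float = 60.0
    lesion_edge_margin: float = 40.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        if self.curve_degree < 0 or self.curve_degree > 6:
            raise ValueError("curve_degree must be in 0..6")
        # the random centerline is H/2 plus a Chebyshev wiggle bounded by
        # curve_max_amplitude, so validity reduces to a margin check
        half = self.image_height / 2.0
        lo = half - self.curve_max_amplitude
        hi = half + self.curve_max_amplitude
        if lo < self.tube_radius or hi > self.image_height - self.tube_radius:
            raise GeometryError(
                "curve_max_amplitude too large: the tube would leave the image"
            )
        if self.min_lesion_spacing <= 0:
            raise ValueError("min_lesion_spacing must be > 0")

    # -- serialisation (CLI config files) -----------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = [
            dataclasses.asdict(g) | {
                "lesion_count": list(g.lesion_count),
                "lesion_amplitude": list(g.lesion_amplitude),
            }
            for g in self.groups
        ]
        d["lesion_width"] = list(self.lesion_width)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["groups"] = tuple(
            GroupSpec(
                label=g["label"],
                n_fish=int(g["n_fish"]),
                lesion_count=tuple(g.get("lesion_count", ("fixed", 0))),
                lesion_amplitude=tuple(g.get("lesion_amplitude", ("uniform", 40.0, 80.0))),
            )
            for g in d["groups"]
        )
        if "lesion_width" in d:
            d["lesion_width"] = tuple(d["lesion_width"])
        return cls(**d)


@dataclass(frozen=True)
class CohortFish:
    """One simulated fish: group label, rendered image and its ground truth."""

    fish_id: str
    label: str
    image: np.ndarray
    truth: GroundTruth


def _random_centerline(spec: CohortSpec, rng: np.random.Generator) -> tuple[float, ...]:
    """Random gentle polynomial centerline, guaranteed inside the image.

    Built as H/2 plus a Chebyshev series on [0, W-1] whose coefficient
    magnitudes sum to at most ``curve_max_amplitude`` (|T_j| <= 1 bounds the
    wiggle), then converted to power-basis coefficients in pixel units.
    """
    d = spec.curve_degree
    coef = np.zeros(d + 1)
    coef[0] = spec.image_height / 2.0
    if d > 0:
        raw = rng.uniform(-1.0, 1.0, size=d)
        coef[1:] = raw * (spec.curve_max_amplitude / d)
    cheb = Chebyshev(coef, domain=[0, spec.image_width - 1])
    poly = cheb.convert(kind=Polynomial)
    return tuple(float(c) for c in poly.coef)


def _place_lesion_centers(
    n: int, lo: float, hi: float, spacing: float, rng: np.random.Generator
) -> list[float]:
    """n uniformly distributed centers in [lo, hi] with pairwise gap >= spacing.

    Uses the classic gap construction (uniform over the feasible simplex), so
    no rejection loop is needed.  Raises if the interval cannot hold n points.
    """
    if n == 0:
        return []
    span = hi - lo
    free = span - (n - 1) * spacing
    if free < 0:
        raise GeometryError(
            f"cannot place {n} lesions with spacing {spacing} in a span of {span:.1f}"
        )
    pts = np.sort(rng.uniform(0.0, free, size=n))
    return list(lo + pts + np.arange(n) * spacing)


def max_lesions(spec: CohortSpec) -> int:
    """Largest lesion count the spacing rule admits for this geometry."""
    span = spec.image_width - 1 - 2 * spec.lesion_edge_margin
    return int(span // spec.min_lesion_spacing) + 1


def generate_cohort(spec: CohortSpec) -> list[CohortFish]:
    """Simulate every fish of a cohort; reproducible from ``spec.seed``.

    Lesion counts are drawn from each group's distribution (capped at the
    number of centers the spacing rule can accommodate), amplitudes from the
    group's amplitude distribution (clipped to be positive), and centers
    uniformly with the minimum spacing enforced.
    """
    fishes: list[CohortFish] = []
    cap = max_lesions(spec)
    for gi, group in enumerate(spec.groups):
        for fi in range(group.n_fish):
            ss = np.random.SeedSequence([int(spec.seed), gi, fi])
            rng = np.random.default_rng(ss)
            image_seed = int(ss.generate_state(1)[0]) & 0x7FFFFFFF
            coeffs = _random_centerline(spec, rng)
            n_lesions = min(_sample_count(group.lesion_count, rng), cap)
            lo = spec.lesion_edge_margin
            hi = spec.image_width - 1 - spec.lesion_edge_margin
            centers = _place_lesion_centers(
                n_lesions, lo, hi, spec.min_lesion_spacing, rng
            )
            lesions = tuple(
                LesionSpec(
                    center_x=c,
                    amplitude=max(1e-6, _sample_value(group.lesion_amplitude, rng)),
                    width_sigma=max(0.5, _sample_value(spec.lesion_width, rng)),
                )
                for c in centers
            )
            tube = TubeModel(
                image_height=spec.image_height,
                image_width=spec.image_width,
                centerline_coeffs=coeffs,
                tube_radius=spec.tube_radius,
                tube_intensity=spec.tube_intensity,
                background_intensity=spec.background_intensity,
                edge_softness=spec.edge_softness,
                bit_depth=spec.bit_depth,
            )
            truth = GroundTruth(
                tube=tube, lesions=lesions,
                noise_sigma=spec.noise_sigma, seed=image_seed,
            )
            fishes.append(
                CohortFish(
                    fish_id=f"{group.label}_{fi:03d}",
                    label=group.label,
                    image=generate_notochord_image(truth),
                    truth=truth,
                )
            )
    return fishes


def study_cohort_spec(seed: int = 0, scale: float = 1.0) -> CohortSpec:
    """Cohort emulating the study's four arms at their reported group sizes.

    Arms: untransformed control (no lesions), RAS-transformed (many lesions),
    RAS with morpholino immune-cell depletion (strong rescue) and RAS with
    CRISPR depletion (partial rescue), sized 52/140/41/105 fish.  ``scale``
    shrinks every group proportionally (minimum 2 fish) for desk-scale runs.
    """
    def n(base: int) -> int:
        return max(2, int(round(base * scale)))

    groups = (
        GroupSpec("control", n(52), ("fixed", 0)),
        GroupSpec("ras", n(140), ("poisson", 5.0)),
        GroupSpec("ras_mo", n(41), ("poisson", 1.0)),
        GroupSpec("ras_crispr", n(105), ("poisson", 3.0)),
    )
    return CohortSpec(groups=groups, seed=seed)


# ---------------------------------------------------------------------------
# RGB histology + tabular fixtures
# ---------------------------------------------------------------------------

def generate_rgb_histology(
    shape: tuple[int, int],
    regions: Sequence[tuple[str, tuple[int, int, int, int], tuple[float, float, float]]],
    background: tuple[float, float, float] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic stain image: labelled rectangles of known channel means.

    ``regions`` is a sequence of ``(name, (y0, y1, x0, x1), (r, g, b))`` with
    half-open row/column bounds.  Regions must not overlap.  With
    ``background=None`` the regions must tile the full frame.  Returns an
    ``(H, W, 3)`` uint8 image whose noiseless per-region channel means equal
    the requested values.
    """
    h, w = shape
    img = np.zeros((h, w, 3), dtype=np.float64)
    covered = np.zeros((h, w), dtype=np.int32)
    for name, (y0, y1, x0, x1), means in regions:
        if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
            raise ValueError(f"region {name!r} out of bounds")
        if any(m < 0 or m > 255 for m in means):
            raise ValueError(f"region {name!r} channel means must be within 0..255")
        covered[y0:y1, x0:x1] += 1
        img[y0:y1, x0:x1, :] = np.asarray(means, dtype=float)
    if covered.max() > 1:
        raise ValueError("regions overlap")
    if background is None:
        if covered.min() == 0:
            raise ValueError("regions do not cover the image and no background given")
    else:
        img[covered == 0] = np.asarray(background, dtype=float)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_skeletal_counts(
    groups: Sequence[tuple[str, int, Distribution, Distribution]],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-fish fusion/cleft count table for the vertebral scoring rubric.

    ``groups`` rows are ``(label, n_fish, fusion_dist, cleft_dist)`` with
    count distributions ``("fixed", k)`` or ``("poisson", lam)``.  Returns a
    DataFrame with columns fish_id, group, fusions, clefts; reproducible from
    the seed.
    """
    rows = []
    for gi, (label, n_fish, fdist, cdist) in enumerate(groups):
        if n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        for fi in range(n_fish):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), gi, fi]))
            rows.append(
                {
                    "fish_id": f"{label}_{fi:03d}",
                    "group": label,
                    "fusions": _sample_count(fdist, rng),
                    "clefts": _sample_count(cdist, rng),
                }
            )
    return pd.DataFrame(rows, columns=["fish_id", "group", "fusions", "clefts"])
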