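"""Shared fixtures: canonical synthetic tubes used across the suite."""

import numpy as np
import pytest
from numpy.polynomial import Chebyshev, Polynomial

import notoquant as nq


@pytest.fixture
def straight_truth() -> nq.GroundTruth:
    """Noiseless hard-edged horizontal tube: y=50, r=5, tube 100, bg 10."""
    tube = nq.TubeModel(
        image_height=100,
        image_width=200,
        centerline_coeffs=(50.0,),
        tube_radius=5.0,
        tube_intensity=100.0,
        background_intensity=10.0,
    )
    return nq.GroundTruth(tube=tube)


@pytest.fixture
def straight_image(straight_truth) -> np.ndarray:
    return nq.generate_notochord_image(straight_truth)


def random_tube_geometry(
    rng: np.random.Generator,
    height: int = 150,
    width: int = 700,
    max_wiggle: float = 12.0,
    max_degree: int = 6,
) -> nq.TubeModel:
    """Random noise-free tube whose centerline is a bounded polynomial.

    The centerline is H/2 plus a Chebyshev series with |coefficients| summing
    to at most ``max_wiggle``, which keeps the curve inside the image by
    construction (|T_j| <= 1) while exercising every degree up to 6.
    """
    deg = int(rng.integers(1, max_degree + 1))
    coef = np.zeros(deg + 1)
    coef[0] = height / 2.0
    coef[1:] = rng.uniform(-1.0, 1.0, size=deg) * (max_wiggle / deg)
    poly = Chebyshev(coef, domain=[0, width - 1]).convert(kind=Polynomial)
    return nq.TubeModel(
        image_height=height,
        image_width=width,
        centerline_coeffs=tuple(poly.coef),
        tube_radius=8.0,
        tube_intensity=120.0,
        background_intensity=20.0,
    )
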