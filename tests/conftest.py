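import numpy as np
import pytest

from hydromorph import (
    ProbeSpec,
    SoluteBody,
    build_template,
    fit_ma_coefficients,
    spt_table,
)


@pytest.fixture(scope="session")
def spt_coeffs():
    """Morphometric coefficients calibrated from the bundled SPT source."""
    return fit_ma_coefficients(spt_table())


@pytest.fixture(scope="session")
def p16_template():
    return build_template()


@pytest.fixture
def unit_probe():
    return ProbeSpec(1.0)


@pytest.fixture
def water_probe():
    return ProbeSpec(2.8)


@pytest.fixture
def single_sphere():
    """One atom of diameter 2.8 Å; with the water probe its accessible R = 2.8 Å."""
    return SoluteBody(np.zeros((1, 3)), np.array([2.8]), label="single")


@pytest.fixture
def touching_unit_pair():
    """Two atoms of accessible radius 1 Å (with unit probe), centers 1 Å apart."""
    return SoluteBody(np.array([[0.0, 0, 0], [1.0, 0, 0]]), np.array([1.0, 1.0]),
                      label="unit-pair")


def sphere_measures(R):
    """Closed-form Minkowski measures of a ball of radius R."""
    return np.array([4 * np.pi * R**3 / 3, 4 * np.pi * R**2, 4 * np.pi * R, 4 * np.pi])


def two_sphere_union_measures(r, d):
    """Closed-form measures of the union of two equal balls (radius r, centers d).

    Volume by lens subtraction, area from cap removal, integrated mean
    curvature from the patch term plus the concave-crease edge term (the
    same expression follows from the valuation identity
    X(A u B) = X(A) + X(B) - X(A n B) with the convex-lens closed form).
    Requires 0 < d < 2r; Y = 4 pi (single component, genus 0).
    """
    h = r - d / 2
    V_lens = np.pi * (2 * r - d) ** 2 * (d**2 + 4 * d * r) / (12 * d)
    V = 2 * (4 * np.pi * r**3 / 3) - V_lens
    A = 2 * (4 * np.pi * r**2 - 2 * np.pi * r * h)
    a = np.sqrt(r**2 - d**2 / 4)
    theta = np.arccos((2 * r**2 - d**2) / (2 * r**2))
    X = A / r - 0.5 * theta * 2 * np.pi * a
    return np.array([V, A, X, 4 * np.pi])
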