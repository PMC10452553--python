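"""Exact lattice-walk evolution, closed form, Fourier inversion, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memdiff.lattice import (
    LatticeWalkSpec,
    RescalingParams,
    WalkDistribution,
    WavenumberGrid,
    characteristic_function,
    closed_form_distribution,
    continuum_density,
    evolve_step,
    invert_characteristic,
    sample_walks,
)


def iterate(spec: LatticeWalkSpec) -> WalkDistribution:
    dist = WalkDistribution.point_mass(spec.origin)
    for _ in range(spec.n_steps):
        dist = evolve_step(dist, spec)
    return dist


@pytest.mark.parametrize(
    "p, n, expected",
    [
        (0.5, 1, {-1: 0.5, 1: 0.5}),
        (1.0, 1, {1: 1.0}),
        (0.3, 2, {-2: 0.49, 0: 0.42, 2: 0.09}),  # enumeration of 4 paths
        (0.0, 3, {-3: 1.0}),
    ],
)
def test_master_equation_iteration(p, n, expected):
    dist = iterate(LatticeWalkSpec(p, n))
    assert dist.as_dict() == pytest.approx(expected, abs=1e-12)
    assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize(
    "p, n, expected",
    [
        (0.5, 2, {-2: 0.25, 0: 0.5, 2: 0.25}),
        (0.7, 1, {-1: 0.3, 1: 0.7}),
        (0.4, 0, {0: 1.0}),
    ],
)
def test_binomial_closed_form(p, n, expected):
    dist = closed_form_distribution(LatticeWalkSpec(p, n))
    assert dist.as_dict() == pytest.approx(expected, abs=1e-12)


def test_three_routes_agree_sitewise():
    """Iteration, binomial closed form and Fourier inversion are the same law."""
    for p in [0.1, 0.3, 0.5, 0.9, 1.0]:
        for n in [0, 1, 2, 7, 20]:
            spec = LatticeWalkSpec(p, n)
            a, b, c = iterate(spec), closed_form_distribution(spec), invert_characteristic(spec)
            assert a.total_variation(b) < 1e-10
            assert b.total_variation(c) < 1e-10


def test_moments_match_bernoulli_sums():
    """Mean displacement n(p - q); variance 4 n p q, in lattice units."""
    for p in [0.2, 0.5, 0.8]:
        n = 15
        dist = closed_form_distribution(LatticeWalkSpec(p, n))
        q = 1 - p
        assert dist.mean() == pytest.approx(n * (p - q), abs=1e-10)
        assert dist.variance() == pytest.approx(4 * n * p * q, abs=1e-10)


def test_characteristic_function_values():
    grid = WavenumberGrid(np.array([-np.pi / 2, 0.0, np.pi / 3]))
    # k = 0 gives 1 for any parameters (normalisation)
    vals = characteristic_function(LatticeWalkSpec(0.3, 7), grid)
    assert vals[1] == pytest.approx(1.0)
    # n = 0 is identically 1 (delta initial condition)
    assert characteristic_function(LatticeWalkSpec(0.3, 0), grid) == pytest.approx(1.0)
    # symmetric single step reduces to cos k
    vals = characteristic_function(LatticeWalkSpec(0.5, 1), grid)
    assert vals[2] == pytest.approx(np.cos(np.pi / 3))
    assert vals[2].real == pytest.approx(0.5)


def test_inversion_flags_quadrature_failure():
    with pytest.raises(ArithmeticError):
        invert_characteristic(LatticeWalkSpec(0.3, 5), imag_tol=1e-30)


def test_sample_walks_deterministic_and_exact_cases():
    spec = LatticeWalkSpec(1.0, 5)
    dist, traj = sample_walks(spec, 50, seed=3)
    assert dist.as_dict() == {5: 1.0}
    assert traj.shape == (50, 6)
    d1, t1 = sample_walks(LatticeWalkSpec(0.5, 10), 200, seed=11)
    d2, t2 = sample_walks(LatticeWalkSpec(0.5, 10), 200, seed=11)
    assert np.array_equal(t1, t2)
    # zero steps: all mass at the origin
    d0, _ = sample_walks(LatticeWalkSpec(0.5, 0, origin=4), 10, seed=0)
    assert d0.as_dict() == {4: 1.0}
    with pytest.raises(ValueError):
        sample_walks(spec, 0, seed=1)


def test_monte_carlo_close_to_exact():
    spec = LatticeWalkSpec(0.5, 20)
    emp, _ = sample_walks(spec, 20_000, seed=5)
    assert emp.total_variation(closed_form_distribution(spec)) < 0.05


def test_continuum_density_rescaling():
    dist = closed_form_distribution(LatticeWalkSpec(0.5, 2))
    x, rho, t = continuum_density(dist, RescalingParams(0.1, 0.01))
    # probability 0.5 at the origin becomes density 0.5 / 0.1 = 5.0
    assert rho[x == 0.0][0] == pytest.approx(5.0)
    assert t == pytest.approx(0.02)
    # symmetric walk gives a density symmetric about the origin
    assert rho == pytest.approx(rho[::-1])
    assert np.trapezoid(rho, x) == pytest.approx(1.0, abs=1e-8)


def test_rescaling_drift_and_diffusivity():
    r = RescalingParams(0.2, 0.01)
    assert r.diffusivity == pytest.approx(0.2**2 / 0.02)
    assert r.drift(LatticeWalkSpec(0.3, 1)) == pytest.approx((0.7 - 0.3) * 0.2 / 0.01)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        LatticeWalkSpec(1.2, 3)
    with pytest.raises(ValueError):
        LatticeWalkSpec(0.5, -1)
    with pytest.raises(ValueError):
        WalkDistribution(np.array([0, 1]), np.array([0.6, 0.6]), 1)
    with pytest.raises(ValueError):
        WalkDistribution(np.array([0]), np.array([-1.0]), 0)
    with pytest.raises(ValueError):
        RescalingParams(0.0, 0.1)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    p=st.floats(0.0, 1.0),
    n=st.integers(0, 25),
)
def test_mass_and_support_invariants(p, n):
    """Every evolution step conserves mass and stays on the parity sublattice."""
    spec = LatticeWalkSpec(p, n)
    dist = iterate(spec)
    assert abs(dist.probabilities.sum() - 1.0) < 1e-12
    assert dist.sites.min() >= -n and dist.sites.max() <= n
    assert np.all((dist.sites + n) % 2 == 0)
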