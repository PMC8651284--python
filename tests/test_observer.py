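"""Ideal observer: percept distribution, decision variable/boundary, and
the psychometric function, checked against quadrature and brute-force
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import kstest, norm

from gliderpsych.observer import (LevelGrid, ObserverParams, decision_boundary,
                                  decision_variable, default_grid,
                                  percept_cdf, percept_density,
                                  prob_report_noise, sample_percept,
                                  single_level_closed_form)


def test_default_grid_levels():
    g = default_grid()
    assert len(g) == 15
    assert g.levels[0] == pytest.approx(0.02)
    assert g.levels[-2] == pytest.approx(0.93)
    assert g.levels[-1] == 1.0
    assert np.allclose(np.diff(g.array[:-1]), 0.07)


def test_level_grid_validation():
    with pytest.raises(ValueError):
        LevelGrid([0.5, 0.2])
    with pytest.raises(ValueError):
        LevelGrid([0.0, 0.5])
    with pytest.raises(ValueError):
        LevelGrid([])


def test_params_validation():
    with pytest.raises(ValueError):
        ObserverParams(0.0, -0.1)
    with pytest.raises(ValueError):
        ObserverParams(0.0, 0.4, 1.0, -1.0)


@pytest.mark.parametrize("s, sigma", [(0.0, 0.4), (0.5, 0.1), (0.93, 1.3)])
def test_percept_density_normalizes(s, sigma):
    params = ObserverParams(0.0, sigma)
    total, _ = quad(lambda x: percept_density(x, s, params), -1, 1)
    assert total == pytest.approx(1.0, abs=1e-8)


def test_percept_density_symmetric_at_zero():
    params = ObserverParams(0.0, 0.4)
    xs = np.linspace(0, 1, 11)
    assert np.allclose(percept_density(xs, 0.0, params),
                       percept_density(-xs, 0.0, params))


def test_percept_density_quadrature_value():
    """Peak density at x = s equals phi(0)/(sigma * gaussian mass)."""
    params = ObserverParams(0.0, 0.1)
    mass = norm.cdf((1 - 0.5) / 0.1) - norm.cdf((-1 - 0.5) / 0.1)
    expected = norm.pdf(0.0) / (0.1 * mass)
    assert percept_density(0.5, 0.5, params) == pytest.approx(expected)


def test_sample_percept_matches_cdf(rng):
    params = ObserverParams(0.0, 0.4)
    x = sample_percept(0.0, params, size=100_000, rng=rng)
    assert ((x >= -1) & (x <= 1)).all()
    stat = kstest(x, lambda v: percept_cdf(v, 0.0, params)).statistic
    assert stat < 0.01


def test_sample_percept_degenerate_noise(rng):
    params = ObserverParams(0.0, 1e-9)
    x = sample_percept(0.3, params, size=100, rng=rng)
    assert np.allclose(x, 0.3, atol=1e-6)


def test_decision_variable_prior_shift(std_params, grid):
    xs = np.linspace(-1, 1, 41)
    shifted = ObserverParams(std_params.prior_logodds + 0.7,
                             std_params.noise_sd)
    d0 = decision_variable(xs, std_params, grid)
    d1 = decision_variable(xs, shifted, grid)
    assert np.allclose(d1 - d0, 0.7)


def test_decision_variable_strictly_decreasing(std_params, grid):
    xs = np.linspace(-1, 1, 10_000)
    d = decision_variable(xs, std_params, grid)
    assert (np.diff(d) < 0).all()


@settings(max_examples=25, derandomize=True)
@given(alpha=st.floats(-2, 2), sigma=st.floats(0.05, 2.0))
def test_decision_variable_monotone_property(alpha, sigma):
    params = ObserverParams(alpha, sigma)
    xs = np.linspace(-1, 1, 2001)
    d = decision_variable(xs, params, default_grid())
    assert (np.diff(d) < 0).all()


def test_single_level_decision_variable_closed_form():
    """Huge bounds, K=1: D(x) = alpha - (2 x s1 - s1^2) / (2 sigma^2)."""
    alpha, sigma, s1 = 0.3, 0.25, 0.5
    params = ObserverParams(alpha, sigma, -1e6, 1e6)
    grid = LevelGrid([s1])
    for x in (-0.4, 0.0, 0.2, 0.8):
        expected = alpha - (2 * x * s1 - s1**2) / (2 * sigma**2)
        assert decision_variable(x, params, grid) == pytest.approx(expected)


def test_decision_boundary_unbounded_limit():
    """beta -> 0 with alpha = 0: the boundary is s1/2."""
    params = ObserverParams(0.0, 0.25, -1e6, 1e6)
    xstar = decision_boundary(params, LevelGrid([0.5]))
    assert xstar == pytest.approx(0.25, abs=1e-6)


def test_decision_boundary_single_level_closed_form():
    """Bounded K=1 case: x* = s1/2 + (sigma^2/s1)(alpha + beta)."""
    alpha, sigma, s1 = 0.2, 0.3, 0.5
    params = ObserverParams(alpha, sigma)
    beta = np.log((norm.cdf((1 - s1) / sigma) - norm.cdf((-1 - s1) / sigma))
                  / (norm.cdf(1 / sigma) - norm.cdf(-1 / sigma)))
    expected = s1 / 2 + sigma**2 / s1 * (alpha + beta)
    assert decision_boundary(params, LevelGrid([s1])) == pytest.approx(
        expected, abs=1e-9)


def test_decision_boundary_sign_scan_oracle(std_params, grid):
    """Brute force: locate the sign change of D on a dense lattice."""
    xs = np.linspace(-1, 1, 1_000_001)
    d = decision_variable(xs, std_params, grid)
    idx = np.searchsorted(-np.sign(d), 0.5)  # first index where d < 0
    xstar = decision_boundary(std_params, grid)
    assert abs(xstar - xs[idx]) < 1e-5


def test_decision_boundary_clamps():
    grid = default_grid()
    assert decision_boundary(ObserverParams(25.0, 0.4), grid) == 1.0
    assert decision_boundary(ObserverParams(-25.0, 0.4), grid) == -1.0


def test_prob_report_noise_prior_dominance(grid):
    p = prob_report_noise(np.concatenate([[0.0], grid.array]),
                          ObserverParams(20.0, 0.4), grid)
    assert (p > 0.999).all()


def test_prob_report_noise_tiny_sigma(grid):
    params = ObserverParams(0.1, 1e-6)
    assert prob_report_noise(0.0, params, grid) == pytest.approx(1.0)
    assert prob_report_noise(0.93, params, grid) == pytest.approx(0.0, abs=1e-9)


def test_prob_report_noise_monotone_in_level(std_params, grid):
    p = prob_report_noise(np.linspace(0, 1, 101), std_params, grid)
    assert (np.diff(p) <= 1e-12).all()
    assert ((p >= 0) & (p <= 1)).all()


def test_prob_report_noise_monotone_in_prior(grid):
    for s in (0.0, 0.3, 0.93):
        ps = [prob_report_noise(s, ObserverParams(a, 0.4), grid)
              for a in np.linspace(-2, 2, 9)]
        assert (np.diff(ps) >= -1e-12).all()


@pytest.mark.parametrize("s", [0.0, 0.09, 0.44, 0.93])
def test_prob_equals_quadrature_over_decision_region(s, std_params, grid):
    """p(report noise | s) is the percept mass on {x : D(x) > 0}."""
    xstar = decision_boundary(std_params, grid)
    mass, _ = quad(lambda x: percept_density(x, s, std_params), -1, xstar,
                   epsabs=1e-10)
    assert prob_report_noise(s, std_params, grid) == pytest.approx(
        mass, abs=1e-6)


def test_closed_form_psychometric_values():
    assert single_level_closed_form(0.25, 0.5, 0.0, 0.3) == pytest.approx(0.5)
    s1 = 0.4
    assert single_level_closed_form(s1, s1, 0.0, s1 / 2) == pytest.approx(
        norm.cdf(-1))
    with pytest.raises(ValueError):
        single_level_closed_form(0.1, -0.5, 0.0, 0.3)


def test_closed_form_matches_bounded_pipeline():
    alpha, sigma, s1 = 0.3, 0.2, 0.4
    params = ObserverParams(alpha, sigma, -1e3, 1e3)
    grid = LevelGrid([s1])
    for s in (0.0, 0.1, 0.4, 0.9):
        assert prob_report_noise(s, params, grid) == pytest.approx(
            single_level_closed_form(s, s1, alpha, sigma), abs=1e-6)
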