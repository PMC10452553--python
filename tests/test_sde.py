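"""Force/drag SDE: Wiener paths, exact solution, Euler-Maruyama, convergence."""

import numpy as np
import pytest

from memdiff.sde import (
    BrownianPath,
    SDEParams,
    euler_maruyama,
    exact_solution,
    force_sweep,
    generate_brownian_path,
    strong_error,
)


def batched_path(n_paths, n_steps, T, seed):
    rng = np.random.default_rng(seed)
    inc = rng.normal(0.0, np.sqrt(T / n_steps), (n_paths, n_steps))
    return BrownianPath(np.linspace(0.0, T, n_steps + 1), inc)


def test_brownian_path_statistics_and_determinism():
    path = generate_brownian_path(100_000, 1.0, seed=12)
    dt = path.dt
    inc = path.increments
    assert abs(inc.mean()) < 4 * np.sqrt(dt / inc.size)
    assert inc.var() == pytest.approx(dt, rel=0.05)
    again = generate_brownian_path(100_000, 1.0, seed=12)
    assert np.array_equal(path.increments, again.increments)
    with pytest.raises(ValueError):
        generate_brownian_path(0, 1.0, 0)


def test_bridge_refinement_couples_levels():
    """Each coarse increment equals the sum of its two refined children."""
    rng = np.random.default_rng(9)
    coarse = generate_brownian_path(16, 2.0, seed=9)
    fine = coarse.refine(rng)
    assert fine.n_steps == 32
    assert fine.dt == pytest.approx(coarse.dt / 2)
    sums = fine.increments.reshape(16, 2).sum(axis=1)
    assert sums == pytest.approx(coarse.increments, abs=1e-14)
    # refined midpoints have the right conditional spread on average
    finer = fine.refine(rng)
    assert finer.increments.var() == pytest.approx(finer.dt, rel=0.35)


@pytest.mark.parametrize(
    "F, D, expected",
    [
        (1.0, 0.0, np.e),  # noise-free exponential growth
        (0.0, 0.0, 1.0),  # no force, no noise: constant
    ],
)
def test_exact_solution_degenerate_cases(F, D, expected):
    params = SDEParams(force=F, drag=1.0, diffusivity=D, x0=1.0, horizon=1.0, n_steps=64)
    path = generate_brownian_path(64, 1.0, seed=2)
    sol = exact_solution(params, path)
    assert sol.terminal == pytest.approx(expected, rel=1e-12)
    assert np.all(sol.positions > 0)


def test_exact_solution_lognormal_mean():
    """E[X_T] = x0 exp((F/gamma) T) for geometric Brownian motion."""
    params = SDEParams(force=0.5, drag=1.0, diffusivity=0.5, x0=2.0, horizon=1.0)
    path = batched_path(100_000, 64, 1.0, seed=4)
    x_T = exact_solution(params, path).terminal
    target = 2.0 * np.exp(0.5)
    stderr = x_T.std() / np.sqrt(x_T.size)
    assert abs(x_T.mean() - target) < 3 * stderr


def test_euler_maruyama_deterministic_limit():
    params = SDEParams(force=1.0, drag=1.0, diffusivity=0.0, x0=1.0, horizon=1.0, n_steps=1)
    one_step = euler_maruyama(params, generate_brownian_path(1, 1.0, seed=0))
    assert one_step.terminal == pytest.approx(2.0)
    # with D = 0 the scheme is explicit Euler: error O(dt)
    errors = []
    for n in [64, 128, 256]:
        p = SDEParams(force=1.0, drag=1.0, diffusivity=0.0, x0=1.0, horizon=1.0, n_steps=n)
        path = generate_brownian_path(n, 1.0, seed=1)
        errors.append(abs(euler_maruyama(p, path).terminal - np.e))
    ratios = np.array(errors[:-1]) / np.array(errors[1:])
    assert np.all((ratios > 1.8) & (ratios < 2.2))


def test_solvers_ignore_noise_when_d_zero():
    """With D = 0 both solvers are deterministic in the Brownian path."""
    params = SDEParams(force=0.3, drag=2.0, diffusivity=0.0, x0=1.5, horizon=1.0, n_steps=32)
    a = exact_solution(params, generate_brownian_path(32, 1.0, seed=1))
    b = exact_solution(params, generate_brownian_path(32, 1.0, seed=999))
    assert a.positions == pytest.approx(b.positions)
    c = euler_maruyama(params, generate_brownian_path(32, 1.0, seed=1))
    d = euler_maruyama(params, generate_brownian_path(32, 1.0, seed=999))
    assert c.positions == pytest.approx(d.positions)


def test_overflow_guard():
    params = SDEParams(force=100.0, drag=1.0, diffusivity=0.0, x0=1.0, horizon=1.0, n_steps=2)
    with pytest.raises(OverflowError, match="reduce dt"):
        euler_maruyama(params, generate_brownian_path(2, 1.0, seed=0), overflow_bound=10.0)


def test_strong_error_ladder_shape_and_monotonicity():
    params = SDEParams(force=0.5, drag=1.0, diffusivity=0.5, x0=1.0, horizon=1.0)
    report = strong_error(params, [2.0**-k for k in range(4, 9)], 2000, seed=6)
    assert np.all(report.strong_errors > 0)
    # refinement shrinks the error, within two standard errors of noise
    slack = 2 * (report.standard_errors[:-1] + report.standard_errors[1:])
    assert np.all(np.diff(report.strong_errors) < slack)
    assert 0.2 < report.fitted_order < 0.8
    with pytest.raises(ValueError):
        strong_error(params, [0.25, 0.125], 100, seed=0)
    with pytest.raises(ValueError):
        strong_error(params, [0.3, 0.2, 0.1], 100, seed=0)


def test_strong_error_order_one_when_deterministic():
    params = SDEParams(force=1.0, drag=1.0, diffusivity=0.0, x0=1.0, horizon=1.0)
    report = strong_error(params, [2.0**-k for k in range(4, 8)], 10, seed=0)
    assert report.fitted_order == pytest.approx(1.0, abs=0.1)


def test_force_sweep_shared_path_ordering():
    params = SDEParams(force=1.0, drag=1.0, diffusivity=0.25, x0=1.0, horizon=1.0, n_steps=128)
    sweep = force_sweep(params, [1e-6, 1e-3, 1.0], seed=8)
    assert [f for f, _ in sweep] == [1e-6, 1e-3, 1.0]
    terminals = [traj.terminal for _, traj in sweep]
    # identical Wiener path, so terminal value is increasing in the force
    assert terminals[0] < terminals[1] < terminals[2]
    single = force_sweep(params, [1.0], seed=8)[0][1]
    ref = euler_maruyama(params, generate_brownian_path(128, 1.0, 8))
    assert single.positions == pytest.approx(ref.positions)
    with pytest.raises(ValueError):
        force_sweep(params, [-1.0], seed=0)


def test_params_validation():
    with pytest.raises(ValueError):
        SDEParams(force=1.0, drag=0.0, diffusivity=0.1)
    with pytest.raises(ValueError):
        SDEParams(force=1.0, drag=1.0, diffusivity=-0.1)
    with pytest.raises(ValueError):
        SDEParams(force=1.0, drag=1.0, diffusivity=0.1, x0=0.0)
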