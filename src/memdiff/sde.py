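"""Protein position under external force and drag: a multiplicative-noise SDE.

Outside the membrane a messenger protein of position ``X_t`` is pushed by a
constant external force ``F`` against drag ``gamma`` while diffusing with
rate ``D`` (volatility ``sigma = sqrt(D)``):

    dX_t = (F / gamma) X_t dt + sqrt(D) X_t dW_t

This is geometric Brownian motion with drift ``mu = F / gamma``.  The module
provides the exact (Ito) solution

    X_t = x0 * exp((F/gamma - D/2) t + sqrt(D) W_t)

the Euler-Maruyama discretisation

    X_{i+1} = X_i + (F/gamma) X_i dt_i + sqrt(D) X_i dW_i

and strong-convergence diagnostics: the mean absolute terminal gap
``E|Y(T) - X(T)|`` between the exact and numerical solutions driven by the
SAME Wiener path, measured over a ladder of step sizes and fitted for its
convergence order (1/2 for this scheme).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SDEParams",
    "BrownianPath",
    "SDEPath",
    "ConvergenceReport",
    "generate_brownian_path",
    "exact_solution",
    "euler_maruyama",
    "strong_error",
    "force_sweep",
]


@dataclass(frozen=True)
class SDEParams:
    """Physical and numerical parameters of the protein-position SDE.

    ``force`` is quoted in micronewtons; only the ratio ``force / drag``
    and ``diffusivity`` enter the dynamics, so drag and diffusivity are
    accepted as raw numerics and no unit conversion is performed.
    """

    force: float
    drag: float
    diffusivity: float
    x0: float = 1.0
    horizon: float = 1.0
    n_steps: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drag <= 0:
            raise ValueError("drag must be positive")
        if self.diffusivity < 0:
            raise ValueError("diffusivity must be >= 0")
        if self.x0 <= 0:
            raise ValueError("x0 must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def mu(self) -> float:
        """Drift rate F / gamma."""
        return self.force / self.drag


@dataclass(frozen=True)
class BrownianPath:
    """A discretised Wiener path: uniform time grid plus its increments.

    Each increment is drawn as ``sqrt(dt) * Z`` with ``Z`` standard normal;
    a fixed seed reproduces the path bit-for-bit.  ``refine`` splits every
    increment by a Brownian-bridge midpoint draw, so successively finer
    paths are realisations of the SAME underlying Wiener path — the
    coupling that strong-error estimation requires.
    """

    times: np.ndarray
    increments: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        inc = np.asarray(self.increments, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "increments", inc)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("times must hold at least two points")
        if inc.shape[-1] != times.size - 1:
            raise ValueError("need one increment per time interval")
        dts = np.diff(times)
        if not np.allclose(dts, dts[0], rtol=1e-9):
            raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    @property
    def n_steps(self) -> int:
        return int(self.times.size - 1)

    def cumulative(self) -> np.ndarray:
        """W at every grid time, starting from W(0) = 0."""
        w = np.empty(self.increments.shape[:-1] + (self.times.size,))
        w[..., 0] = 0.0
        np.cumsum(self.increments, axis=-1, out=w[..., 1:])
        return w

    def refine(self, rng: np.random.Generator) -> "BrownianPath":
        """Halve dt by Brownian-bridge midpoint sampling.

        Conditional on an increment ``dW`` over ``dt``, the first half-step
        increment is ``dW/2 + N(0, dt/4)``; the second is the remainder, so
        coarse increments are exactly the sums of the fine pair.
        """
        dt = self.dt
        shape = self.increments.shape
        mid = 0.5 * self.increments + rng.normal(0.0, np.sqrt(dt / 4.0), shape)
        fine = np.empty(shape[:-1] + (2 * shape[-1],))
        fine[..., 0::2] = mid
        fine[..., 1::2] = self.increments - mid
        times = np.linspace(0.0, self.horizon, 2 * self.n_steps + 1)
        return BrownianPath(times, fine)


@dataclass(frozen=True)
class SDEPath:
    """A discrete-time trajectory X(t) on a uniform grid."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        pos = np.asarray(self.positions, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", pos)
        if pos.shape[-1] != times.size:
            raise ValueError("positions must match the time grid")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")

    @property
    def terminal(self) -> np.ndarray | float:
        out = self.positions[..., -1]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        pos = np.atleast_2d(self.positions)
        frames = [
            pd.DataFrame(
                {"time": self.times, "position": row, "path_id": i}
            )
            for i, row in enumerate(pos)
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ConvergenceReport:
    """Strong-error ladder and the fitted convergence order.

    ``strong_errors[i]`` estimates ``E|Y(T) - X(T)|`` at step size
    ``dt_levels[i]``; ``fitted_order`` is the least-squares slope of
    log error against log dt.
    """

    dt_levels: np.ndarray
    strong_errors: np.ndarray
    standard_errors: np.ndarray
    fitted_order: float
    n_paths: int

    def __post_init__(self) -> None:
        dts = np.asarray(self.dt_levels, dtype=np.float64)
        errs = np.asarray(self.strong_errors, dtype=np.float64)
        object.__setattr__(self, "dt_levels", dts)
        object.__setattr__(self, "strong_errors", errs)
        object.__setattr__(
            self, "standard_errors", np.asarray(self.standard_errors, dtype=np.float64)
        )
        if np.any(np.diff(dts) >= 0):
            raise ValueError("dt_levels must be strictly decreasing")
        if np.any(errs < 0):
            raise ValueError("strong errors must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dt": self.dt_levels,
                "strong_error": self.strong_errors,
                "standard_error": self.standard_errors,
            }
        )


def generate_brownian_path(n_steps: int, T: float, seed: int) -> BrownianPath:
    """Draw a seeded Wiener path on a uniform grid with dt = T / n_steps."""
    if n_steps < 1 or T <= 0:
        raise ValueError("need n_steps >= 1 and T > 0")
    rng = np.random.default_rng(seed)
    dt = T / n_steps
    inc = rng.normal(0.0, np.sqrt(dt), n_steps)
    return BrownianPath(np.linspace(0.0, T, n_steps + 1), inc)


def exact_solution(params: SDEParams, path: BrownianPath) -> SDEPath:
    """Evaluate the closed-form solution along a Wiener path.

    ``X_t = x0 exp((F/gamma - D/2) t + sqrt(D) W_t)``; strictly positive.
    The noise enters with a plus sign, the convention under which the
    solution couples pathwise with the Euler-Maruyama recursion.
    """
    _check_grid(params, path)
    w = path.cumulative()
    drift = (params.mu - 0.5 * params.diffusivity) * path.times
    x = params.x0 * np.exp(drift + np.sqrt(params.diffusivity) * w)
    return SDEPath(path.times, x)


def euler_maruyama(
    params: SDEParams, path: BrownianPath, overflow_bound: float = 1e12
) -> SDEPath:
    """Integrate the SDE by the explicit Euler-Maruyama scheme.

    ``X_{i+1} = X_i + (F/gamma) X_i dt + sqrt(D) X_i dW_i`` from
    ``X_0 = x0``.  Aborts with a diagnostic if any |X| exceeds
    ``overflow_bound`` — the symptom of a step size too coarse for the
    drift or noise scale.
    """
    _check_grid(params, path)
    inc = path.increments
    dt = path.dt
    growth = 1.0 + params.mu * dt + np.sqrt(params.diffusivity) * inc
    x = np.empty(inc.shape[:-1] + (path.times.size,))
    x[..., 0] = params.x0
    for i in range(inc.shape[-1]):
        x[..., i + 1] = x[..., i] * growth[..., i]
        if np.abs(x[..., i + 1]).max() > overflow_bound:
            raise OverflowError(
                f"|X| exceeded {overflow_bound:g} at t = {path.times[i + 1]:g}; "
                "reduce dt"
            )
    return SDEPath(path.times, x)


def strong_error(
    params: SDEParams,
    dt_levels: np.ndarray,
    n_paths: int,
    seed: int,
    batch_size: int = 2000,
) -> ConvergenceReport:
    """Estimate the strong error of Euler-Maruyama on a step-size ladder.

    For each step size the numerical terminal value is compared with the
    exact solution driven by the SAME Wiener path: increments are drawn
    once at the finest level and block-summed to every coarser level (the
    exact coupling that Brownian-bridge refinement produces, built top
    down).  Reports ``E|Y(T) - X(T)|`` per level with its Monte-Carlo
    standard error, and the least-squares slope of log error vs log dt.
    """
    dts = np.sort(np.asarray(dt_levels, dtype=np.float64))[::-1]
    if dts.size < 3:
        raise ValueError("need at least 3 dt levels")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    T = params.horizon
    steps = T / dts
    steps_int = np.rint(steps).astype(int)
    if not np.allclose(steps, steps_int, rtol=1e-9):
        raise ValueError("every dt level must divide the horizon T")
    if np.any(steps_int[:-1] * np.rint(steps_int[1:] / steps_int[:-1]) != steps_int[1:]):
        raise ValueError("coarser step counts must divide finer ones")
    n_fine = steps_int[-1]
    rng = np.random.default_rng(seed)
    sqrt_d = np.sqrt(params.diffusivity)
    sum_abs = np.zeros(dts.size)
    sum_sq = np.zeros(dts.size)
    done = 0
    while done < n_paths:
        m = min(batch_size, n_paths - done)
        fine = rng.normal(0.0, np.sqrt(T / n_fine), (m, n_fine))
        w_T = fine.sum(axis=1)
        y = params.x0 * np.exp(
            (params.mu - 0.5 * params.diffusivity) * T + sqrt_d * w_T
        )
        for j, n_j in enumerate(steps_int):
            inc = fine.reshape(m, n_j, n_fine // n_j).sum(axis=2)
            x = np.full(m, params.x0)
            dt = T / n_j
            for i in range(n_j):
                x = x * (1.0 + params.mu * dt + sqrt_d * inc[:, i])
            gap = np.abs(y - x)
            sum_abs[j] += gap.sum()
            sum_sq[j] += (gap**2).sum()
        done += m
    errors = sum_abs / n_paths
    var = sum_sq / n_paths - errors**2
    stderr = np.sqrt(np.clip(var, 0.0, None) / n_paths)
    slope = np.polyfit(np.log(dts), np.log(errors), 1)[0]
    return ConvergenceReport(dts, errors, stderr, float(slope), n_paths)


def force_sweep(
    params: SDEParams,
    forces: np.ndarray,
    seed: int,
    method: str = "em",
) -> list[tuple[float, SDEPath]]:
    """Simulate one trajectory per external force on a shared Wiener path.

    All other parameters are held constant, so the trajectories differ only
    through the drift ratio F / gamma; larger forces give larger terminal
    means.  ``method`` selects the Euler-Maruyama scheme (``"em"``) or the
    closed-form solution (``"exact"``).
    """
    forces = np.asarray(forces, dtype=np.float64)
    if np.any(forces <= 0):
        raise ValueError("forces must be positive")
    path = generate_brownian_path(params.n_steps, params.horizon, seed)
    solver = euler_maruyama if method == "em" else exact_solution
    out = []
    for f in forces:
        p = replace(params, force=float(f))
        out.append((float(f), solver(p, path)))
    return out


def _check_grid(params: SDEParams, path: BrownianPath) -> None:
    if abs(path.horizon - params.horizon) > 1e-9 * params.horizon:
        raise ValueError(
            f"path horizon {path.horizon} != params horizon {params.horizon}"
        )
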