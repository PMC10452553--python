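"""Dimensionless advection-diffusion of proteins across the membrane.

Applying Ito's lemma to the force/drag SDE gives a backward PDE for a
function Theta(X, t) of the protein position; the log/time-reversal change
of variables ``X = K e^x``, ``tau = (T - t) sigma^2 / 2``, ``Theta = K
theta`` maps it onto the dimensionless advection-diffusion equation

    d theta / d tau = a(x) d^2 theta / dx^2 + b(x) d theta / dx

on x in [0, 1], with spatially dependent coefficients inherited from the
membrane's diffusivity profile ``D(x) = e^{2x} / 2`` and force profile
``F(x) = gamma e^x / 2``:

    a(x) = e^{2x} / (2 sigma^2),    b(x) = (e^x / sigma^2) (1 - e^x / 2)

subject to homogeneous Dirichlet boundaries theta(0, tau) = theta(1, tau)
= 0 and the initial profile theta(x, 0) = e^{2x} (x - x^2).

The solver is method-of-lines: second-order central differences on a
uniform grid, implicit adaptive time stepping (BDF) on the resulting
stiff linear system.  Because sigma enters both coefficients as 1/sigma^2,
raising the volatility freezes the field — the large-sigma solutions stay
close to the initial profile while small-sigma ones decay toward the
boundary-imposed zero state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.sparse import diags
from scipy.special import gamma as gamma_function

__all__ = [
    "TransformParams",
    "DiffusivityProfile",
    "PDEProblem",
    "PDESolution",
    "diffusivity_profile",
    "force_profile",
    "bulk_diffusivity",
    "default_problem",
    "solve_pde",
    "sigma_sweep",
]


@dataclass(frozen=True)
class TransformParams:
    """Change of variables between physical and dimensionless coordinates.

    ``X = K e^x`` maps log-position to position, ``tau = (T - t) sigma^2/2``
    reverses and rescales time (t = T maps to tau = 0), and ``Theta = K
    theta`` rescales the field.  ``sigma = sqrt(D)`` is the volatility.
    """

    K: float
    sigma: float
    horizon: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def to_physical(self, x, tau):
        """(x, tau) -> (X, t)."""
        x = np.asarray(x, dtype=np.float64)
        tau = np.asarray(tau, dtype=np.float64)
        return self.K * np.exp(x), self.horizon - 2.0 * tau / self.sigma**2

    def to_dimensionless(self, X, t):
        """(X, t) -> (x, tau); requires X > 0."""
        X = np.asarray(X, dtype=np.float64)
        t = np.asarray(t, dtype=np.float64)
        if np.any(X <= 0):
            raise ValueError("X must be positive for the log map")
        return np.log(X / self.K), (self.horizon - t) * self.sigma**2 / 2.0

    def field_to_physical(self, theta):
        return self.K * np.asarray(theta, dtype=np.float64)

    def field_to_dimensionless(self, Theta):
        return np.asarray(Theta, dtype=np.float64) / self.K


@dataclass(frozen=True)
class DiffusivityProfile:
    """Spatially dependent membrane diffusivity ``e^{2x} / Gamma(1+alpha)^2``.

    The quoted maximal-diffusivity convention fixes the alpha = 1 value to
    ``e^{2x} / 2`` — note this differs from the Gamma-function formula,
    which gives ``e^{2x}`` there since Gamma(2) = 1; both conventions are
    exposed and the printed alpha = 1 value is the default.  See
    ``docs/methods.md`` for the discrepancy.
    """

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= -1.0:
            raise ValueError("alpha must exceed -1 (Gamma pole region)")

    def __call__(self, x):
        return diffusivity_profile(x, self)


def diffusivity_profile(x, profile: DiffusivityProfile | None = None):
    """Evaluate the membrane diffusivity profile D(x); increasing in x.

    At alpha = 1 the printed convention ``e^{2x} / 2`` is used; any other
    alpha uses ``e^{2x} / Gamma(1 + alpha)^2`` verbatim.
    """
    if profile is None:
        profile = DiffusivityProfile()
    x = np.asarray(x, dtype=np.float64)
    if profile.alpha == 1.0:
        return np.exp(2.0 * x) / 2.0
    return np.exp(2.0 * x) / gamma_function(1.0 + profile.alpha) ** 2


def force_profile(x, gamma: float):
    """Position-dependent external force ``F(x) = gamma e^x / 2``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(x, dtype=np.float64)
    return gamma * np.exp(x) / 2.0


def bulk_diffusivity(F: float, gamma: float) -> float:
    """Bulk relation ``D = 2 F / gamma^2`` between diffusivity, force, drag.

    Implemented verbatim.  Note it is not algebraically consistent with the
    spatial profiles: substituting F(x) = gamma e^x / 2 yields e^x / gamma
    rather than e^{2x} / 2 (the squared form 2 F^2 / gamma^2 would
    reconcile them); ``profile_consistency_gap`` quantifies the mismatch.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 2.0 * F / gamma**2


def profile_consistency_gap(x, gamma: float):
    """|bulk_diffusivity(F(x), gamma) - D(x)| — the bulk/profile mismatch."""
    x = np.asarray(x, dtype=np.float64)
    return np.abs(
        2.0 * force_profile(x, gamma) / gamma**2 - diffusivity_profile(x)
    )


@dataclass(frozen=True)
class PDEProblem:
    """The advection-diffusion problem on [0, 1] with Dirichlet data.

    ``n_grid`` counts interior points; the stored grid includes both
    endpoints.  ``diffusion_coeff`` and ``advection_coeff`` are injectable
    callables a(x) > 0 and b(x), so alternative coefficient parsings can be
    explored without touching the solver.
    """

    n_grid: int
    sigma: float
    diffusion_coeff: Callable[[np.ndarray], np.ndarray]
    advection_coeff: Callable[[np.ndarray], np.ndarray]
    initial_profile: np.ndarray
    tau_end: float
    boundary: tuple[float, float] = (0.0, 0.0)
    domain: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_grid < 3:
            raise ValueError("n_grid must be >= 3")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.tau_end < 0:
            raise ValueError("tau_end must be >= 0")
        ic = np.asarray(self.initial_profile, dtype=np.float64)
        object.__setattr__(self, "initial_profile", ic)
        if ic.size != self.n_grid + 2:
            raise ValueError("initial profile must cover interior + endpoints")
        if abs(ic[0] - self.boundary[0]) > 1e-12 or abs(ic[-1] - self.boundary[1]) > 1e-12:
            raise ValueError("initial profile incompatible with Dirichlet data")
        a = np.asarray(self.diffusion_coeff(self.grid[1:-1]), dtype=np.float64)
        if np.any(a <= 0):
            raise ValueError("diffusion coefficient must be positive on (0, 1)")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.domain[0], self.domain[1], self.n_grid + 2)


@dataclass(frozen=True)
class PDESolution:
    """theta(x, tau) at the stored checkpoints; endpoints pinned exactly."""

    grid: np.ndarray
    times: np.ndarray
    field: np.ndarray  # shape (n_times, n_grid + 2)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        times = np.asarray(self.times, dtype=np.float64)
        fld = np.asarray(self.field, dtype=np.float64)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "field", fld)
        if fld.shape != (times.size, grid.size):
            raise ValueError("field must be (n_times, n_grid)")
        if np.any(fld[:, 0] != fld[0, 0]) or np.any(fld[:, -1] != fld[0, -1]):
            raise ValueError("Dirichlet boundary values must be pinned")
        bound = np.abs(fld[0]).max() + 1e-8
        if np.abs(fld).max() > bound:
            raise ValueError("field exceeds the no-source maximum bound")

    def l2_distance_from_initial(self) -> float:
        """L2 distance between the final checkpoint and the initial profile."""
        diff = self.field[-1] - self.field[0]
        return float(np.sqrt(np.trapezoid(diff**2, self.grid)))

    def to_frame(self) -> pd.DataFrame:
        tau, x = np.meshgrid(self.times, self.grid, indexing="ij")
        return pd.DataFrame(
            {"tau": tau.ravel(), "x": x.ravel(), "theta": self.field.ravel()}
        )


def default_problem(sigma: float, n_grid: int = 199, tau_end: float = 2.0) -> PDEProblem:
    """Build the membrane problem with its canonical coefficients.

    ``a(x) = e^{2x}/(2 sigma^2)``, ``b(x) = (e^x/sigma^2)(1 - e^x/2)``,
    homogeneous Dirichlet boundaries and the initial bump
    ``theta(x, 0) = e^{2x}(x - x^2)``, sampled on a uniform grid of
    ``n_grid`` interior points plus the endpoints.
    """
    x = np.linspace(0.0, 1.0, n_grid + 2)
    ic = np.exp(2.0 * x) * (x - x**2)
    ic[0] = 0.0
    ic[-1] = 0.0
    s2 = sigma**2
    return PDEProblem(
        n_grid=n_grid,
        sigma=sigma,
        diffusion_coeff=lambda x: np.exp(2.0 * x) / (2.0 * s2),
        advection_coeff=lambda x: (np.exp(x) / s2) * (1.0 - np.exp(x) / 2.0),
        initial_profile=ic,
        tau_end=tau_end,
    )


def solve_pde(
    problem: PDEProblem,
    checkpoints: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> PDESolution:
    """Solve the problem by method of lines with implicit time stepping.

    Space: second-order central differences for both the diffusion and the
    advection term on the uniform grid (self-convergence order 2).  Time:
    BDF with adaptive error control and the exact (tridiagonal) Jacobian —
    the advection term is stiff near x = 1 for small sigma.  Checkpoints
    default to 11 uniform times in [0, tau_end].  The Dirichlet rows are
    never integrated; they are pinned to the boundary data.
    """
    if checkpoints is None:
        checkpoints = np.linspace(0.0, problem.tau_end, 11)
    checkpoints = np.asarray(checkpoints, dtype=np.float64)
    grid = problem.grid
    n_ckpt = checkpoints.size
    if problem.tau_end == 0.0 or (n_ckpt == 1 and checkpoints[0] == 0.0):
        fld = np.tile(problem.initial_profile, (n_ckpt, 1))
        return PDESolution(grid, checkpoints, fld)
    h = grid[1] - grid[0]
    xi = grid[1:-1]
    a = np.asarray(problem.diffusion_coeff(xi), dtype=np.float64)
    b = np.asarray(problem.advection_coeff(xi), dtype=np.float64)
    lower = a[1:] / h**2 - b[1:] / (2.0 * h)
    main = -2.0 * a / h**2
    upper = a[:-1] / h**2 + b[:-1] / (2.0 * h)
    A = diags([lower, main, upper], offsets=[-1, 0, 1], format="csc")
    # constant source from non-homogeneous Dirichlet values
    c = np.zeros(problem.n_grid)
    c[0] = (a[0] / h**2 - b[0] / (2.0 * h)) * problem.boundary[0]
    c[-1] = (a[-1] / h**2 + b[-1] / (2.0 * h)) * problem.boundary[1]

    def rhs(_tau, theta):
        return A @ theta + c

    sol = solve_ivp(
        rhs,
        (0.0, problem.tau_end),
        problem.initial_profile[1:-1],
        method="BDF",
        t_eval=checkpoints,
        jac=lambda _tau, _theta: A,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"time stepping failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        bad = checkpoints[np.argmax(~np.isfinite(sol.y).all(axis=0))]
        raise RuntimeError(f"non-finite field values at tau = {bad}")
    fld = np.empty((n_ckpt, grid.size))
    fld[:, 0] = problem.boundary[0]
    fld[:, -1] = problem.boundary[1]
    fld[:, 1:-1] = sol.y.T
    return PDESolution(grid, checkpoints, fld)


def sigma_sweep(
    sigmas,
    n_grid: int = 199,
    tau_end: float = 2.0,
    checkpoints: np.ndarray | None = None,
) -> tuple[dict[float, PDESolution], pd.DataFrame]:
    """Solve the membrane problem across volatilities.

    Returns the solutions keyed by sigma and a table of the L2 distance of
    the final-time field from the initial profile per sigma.  Because both
    coefficients scale as 1/sigma^2, the distance shrinks as sigma grows:
    the large-sigma field stays consistent with the initial condition,
    while small sigma lets the field decay to the zero boundary state.
    """
    sigmas = [float(s) for s in np.atleast_1d(sigmas)]
    if any(s <= 0 for s in sigmas):
        raise ValueError("all sigmas must be positive")
    solutions: dict[float, PDESolution] = {}
    rows = []
    for s in sigmas:
        sol = solve_pde(default_problem(s, n_grid, tau_end), checkpoints)
        solutions[s] = sol
        rows.append({"sigma": s, "l2_distance_from_ic": sol.l2_distance_from_initial()})
    return solutions, pd.DataFrame(rows)
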