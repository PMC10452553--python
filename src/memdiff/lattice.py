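"""One-dimensional lattice random walk of a membrane protein.

A protein hops between neighbouring sites of a unit-spaced lattice, one hop
per time step: right with probability ``p``, left with probability
``q = 1 - p``.  The site-occupation law ``P(x, n)`` obeys the master
equation

    P(x, n+1) = p * P(x-1, n) + q * P(x+1, n)

This module evolves that law exactly (recursion, binomial closed form and
Fourier inversion, which are required to agree site-wise), samples it by
Monte Carlo, and rescales it to a continuum probability density whose
refinement limit is the heat kernel with diffusivity ``D = dx^2 / (2 dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "LatticeWalkSpec",
    "WalkDistribution",
    "WavenumberGrid",
    "RescalingParams",
    "evolve_step",
    "closed_form_distribution",
    "characteristic_function",
    "invert_characteristic",
    "sample_walks",
    "continuum_density",
]

_MASS_TOL = 1e-12


@dataclass(frozen=True)
class LatticeWalkSpec:
    """Step law of the walk.

    Parameters
    ----------
    p : float
        Probability of a unit step to the right, in [0, 1].
    n_steps : int
        Number of steps, >= 0.
    origin : int
        Initial lattice site (the walk starts as a point mass there).
    """

    p: float
    n_steps: int
    origin: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.n_steps < 0:
            raise ValueError(f"n_steps must be >= 0, got {self.n_steps}")

    @property
    def q(self) -> float:
        """Left-step probability, exactly 1 - p."""
        return 1.0 - self.p


@dataclass(frozen=True)
class WalkDistribution:
    """Exact (or empirical) probability mass over lattice sites at one step.

    ``sites`` are strictly increasing integers, ``probabilities`` the mass on
    each.  Mass must sum to one within 1e-12 and be non-negative.
    """

    sites: np.ndarray
    probabilities: np.ndarray
    step_index: int
    origin: int = 0

    def __post_init__(self) -> None:
        sites = np.asarray(self.sites, dtype=np.int64)
        probs = np.asarray(self.probabilities, dtype=np.float64)
        object.__setattr__(self, "sites", sites)
        object.__setattr__(self, "probabilities", probs)
        if sites.shape != probs.shape or sites.ndim != 1:
            raise ValueError("sites and probabilities must be 1-d and congruent")
        if sites.size and np.any(np.diff(sites) <= 0):
            raise ValueError("sites must be strictly increasing")
        if np.any(probs < -_MASS_TOL):
            raise ValueError("negative probability mass")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"mass {probs.sum()} not normalised")

    @classmethod
    def point_mass(cls, origin: int = 0) -> "WalkDistribution":
        """Delta distribution at ``origin`` — the step-0 initial condition."""
        return cls(np.array([origin]), np.array([1.0]), step_index=0, origin=origin)

    def as_dict(self) -> dict[int, float]:
        return {int(s): float(m) for s, m in zip(self.sites, self.probabilities)}

    def mean(self) -> float:
        return float(np.dot(self.sites, self.probabilities))

    def variance(self) -> float:
        mu = self.mean()
        return float(np.dot((self.sites - mu) ** 2, self.probabilities))

    def total_variation(self, other: "WalkDistribution") -> float:
        """TV distance = half the L1 distance over the union support."""
        support = np.union1d(self.sites, other.sites)
        a = np.zeros(support.size)
        b = np.zeros(support.size)
        a[np.searchsorted(support, self.sites)] = self.probabilities
        b[np.searchsorted(support, other.sites)] = other.probabilities
        return 0.5 * float(np.abs(a - b).sum())


@dataclass(frozen=True)
class WavenumberGrid:
    """Wavenumbers in [-pi, pi] for the characteristic function."""

    k_values: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.k_values, dtype=np.float64)
        object.__setattr__(self, "k_values", k)
        if k.ndim != 1 or k.size < 1:
            raise ValueError("k_values must be a non-empty 1-d array")
        if np.any(np.diff(k) <= 0):
            raise ValueError("k_values must be strictly increasing")
        if k[0] < -np.pi - 1e-12 or k[-1] > np.pi + 1e-12:
            raise ValueError("k_values must lie within [-pi, pi]")

    @property
    def n_points(self) -> int:
        return int(self.k_values.size)

    @classmethod
    def uniform(cls, n_points: int) -> "WavenumberGrid":
        return cls(np.linspace(-np.pi, np.pi, n_points))


@dataclass(frozen=True)
class RescalingParams:
    """Lattice-to-continuum rescaling: step length dx and step duration dt.

    The drift and diffusivity of the continuum limit are
    ``psi = (q - p) dx / dt`` and ``D = dx^2 / (2 dt)``.
    """

    delta_x: float
    delta_t: float
    N_x: int = 1
    N_t: int = 1

    def __post_init__(self) -> None:
        if self.delta_x <= 0 or self.delta_t <= 0:
            raise ValueError("delta_x and delta_t must be positive")
        if self.N_x < 1 or self.N_t < 1:
            raise ValueError("N_x and N_t must be >= 1")

    def drift(self, spec: LatticeWalkSpec) -> float:
        """Continuum drift psi = (q - p) dx / dt."""
        return (spec.q - spec.p) * self.delta_x / self.delta_t

    @property
    def diffusivity(self) -> float:
        """Continuum diffusivity D = dx^2 / (2 dt)."""
        return self.delta_x**2 / (2.0 * self.delta_t)


def evolve_step(dist: WalkDistribution, spec: LatticeWalkSpec) -> WalkDistribution:
    """Advance the occupation law by one step of the master equation.

    ``P(x, n+1) = p P(x-1, n) + q P(x+1, n)``.  Mass is conserved exactly;
    the support widens by at most one site on each side.
    """
    lo, hi = int(dist.sites[0]) - 1, int(dist.sites[-1]) + 1
    new_sites = np.arange(lo, hi + 1)
    new_probs = np.zeros(new_sites.size)
    idx = dist.sites - lo  # position of old sites inside the new support
    new_probs[idx + 1] += spec.p * dist.probabilities  # hop right
    new_probs[idx - 1] += spec.q * dist.probabilities  # hop left
    keep = new_probs > 0.0
    # always keep at least the original support so a delta at p=0/1 survives
    if not keep.any():
        keep = np.ones_like(keep, dtype=bool)
    return WalkDistribution(
        new_sites[keep], new_probs[keep], dist.step_index + 1, dist.origin
    )


def closed_form_distribution(spec: LatticeWalkSpec) -> WalkDistribution:
    """Binomial closed form of the n-step law.

    With ``l`` counting left steps, the displacement is ``n - 2l`` and its
    mass ``C(n, l) p^{n-l} q^{l}``.  Computed in log space for stability at
    large n; p = 0 and p = 1 short-circuit to deterministic walks.
    """
    n, p, q = spec.n_steps, spec.p, spec.q
    if n == 0:
        return WalkDistribution.point_mass(spec.origin)
    if p == 0.0 or p == 1.0:
        site = spec.origin + (n if p == 1.0 else -n)
        return WalkDistribution(np.array([site]), np.array([1.0]), n, spec.origin)
    ell = np.arange(n + 1)
    log_comb = gammaln(n + 1) - gammaln(ell + 1) - gammaln(n - ell + 1)
    mass = np.exp(log_comb + (n - ell) * np.log(p) + ell * np.log(q))
    sites = spec.origin + (n - 2 * ell)  # ell=0 -> +n ... ell=n -> -n
    order = np.argsort(sites)
    return WalkDistribution(sites[order], mass[order], n, spec.origin)


def characteristic_function(
    spec: LatticeWalkSpec, grid: WavenumberGrid
) -> np.ndarray:
    """Characteristic function ``(p e^{-jk} + q e^{jk})^n`` on the grid.

    Assumes the walk starts as a delta at the origin, so the step-0
    transform is identically 1.
    """
    k = grid.k_values
    base = spec.p * np.exp(-1j * k) + spec.q * np.exp(1j * k)
    return base**spec.n_steps


def invert_characteristic(
    spec: LatticeWalkSpec, imag_tol: float = 1e-10
) -> WalkDistribution:
    """Recover the site law by inverting the characteristic function.

    Evaluates ``(1/2pi) \\int_{-pi}^{pi} e^{jkx} (p e^{-jk} + q e^{jk})^n dk``
    by composite trapezoid on ``4n + 1`` uniform points (>= 5).  The phase
    ``e^{+jkx}`` is the inverse of the forward convention ``sum_x P(x)
    e^{-jkx}`` under which the characteristic function reads ``p e^{-jk} +
    q e^{jk}``; it is the sign for which the inversion reproduces the
    master-equation iteration (the normative definition).  The integrand
    is a trigonometric polynomial of degree ``n + |x|`` <= 2n on the reachable
    support, so this rule is exact up to rounding.  Raises if any imaginary
    residual exceeds ``imag_tol`` (a quadrature failure).
    """
    n = spec.n_steps
    if n == 0:
        return WalkDistribution.point_mass(spec.origin)
    grid = WavenumberGrid.uniform(max(4 * n + 1, 5))
    k = grid.k_values
    phat = characteristic_function(spec, grid)
    ell = np.arange(n + 1)
    displacements = n - 2 * ell
    # trapezoid weights on the uniform k-grid
    w = np.full(k.size, k[1] - k[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    phase = np.exp(1j * np.outer(displacements, k))  # e^{+jkx} per site
    vals = (phase * phat) @ w / (2.0 * np.pi)
    if np.abs(vals.imag).max() > imag_tol:
        raise ArithmeticError(
            f"imaginary residual {np.abs(vals.imag).max():.3e} exceeds {imag_tol}"
        )
    mass = np.clip(vals.real, 0.0, None)
    sites = spec.origin + displacements
    order = np.argsort(sites)
    sites, mass = sites[order], mass[order]
    keep = mass > _MASS_TOL
    return WalkDistribution(sites[keep], mass[keep] / mass.sum(), n, spec.origin)


def sample_walks(
    spec: LatticeWalkSpec, n_walks: int, seed: int
) -> tuple[WalkDistribution, np.ndarray]:
    """Monte-Carlo realisation of the walk.

    Returns the empirical site law at step ``n_steps`` and the full
    trajectory array of shape ``(n_walks, n_steps + 1)``.  Deterministic
    for a fixed seed.
    """
    if n_walks < 1:
        raise ValueError(f"n_walks must be >= 1, got {n_walks}")
    rng = np.random.default_rng(seed)
    n = spec.n_steps
    steps = np.where(
        rng.random((n_walks, n)) < spec.p, 1, -1
    ) if n else np.zeros((n_walks, 0), dtype=np.int64)
    trajectories = spec.origin + np.concatenate(
        [np.zeros((n_walks, 1), dtype=np.int64), np.cumsum(steps, axis=1)], axis=1
    )
    finals = trajectories[:, -1]
    sites, counts = np.unique(finals, return_counts=True)
    dist = WalkDistribution(sites, counts / n_walks, n, spec.origin)
    return dist, trajectories


def continuum_density(
    dist: WalkDistribution,
    rescaling: RescalingParams,
    sublattice: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rescale a site law to a probability density per unit length.

    Returns ``(x, rho, t)`` with ``x = site * dx``, ``rho = P / dx`` and
    ``t = step_index * dt``, on a dense lattice grid padded by one empty
    site each side so the trapezoid integral of ``rho`` equals one to
    rounding.

    An n-step walk only occupies sites of the parity of ``origin + n``, so
    the dense density is a comb alternating between ``P/dx`` and zero.  With
    ``sublattice=True`` only the occupied sites are returned, carrying
    ``rho = P / (2 dx)`` — the probability per unit length once the period-2
    support is accounted for.  That is the form whose refinement limit (at
    ``p = q``, ``dx**2 = 2 D dt``) is the heat kernel.
    """
    t = dist.step_index * rescaling.delta_t
    if sublattice:
        x = dist.sites * rescaling.delta_x
        rho = dist.probabilities / (2.0 * rescaling.delta_x)
        return x, rho, t
    lo, hi = int(dist.sites[0]) - 1, int(dist.sites[-1]) + 1
    sites = np.arange(lo, hi + 1)
    rho = np.zeros(sites.size)
    rho[dist.sites - lo] = dist.probabilities / rescaling.delta_x
    return sites * rescaling.delta_x, rho, t
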