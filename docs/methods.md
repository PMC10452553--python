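# Methods

## Model chain

The package implements one physical picture at four levels of
description, with explicit numerical bridges between them.

**Lattice walk.** A protein inside the membrane hops on a unit-spaced
one-dimensional lattice, one hop per time step: right with probability
p, left with q = 1 − p. The occupation law is evolved by the master
equation, and two independent re-derivations are maintained as oracles
against it: the binomial closed form (with l counting left steps, the
displacement is n − 2l with weight C(n, l) p^{n−l} q^l) and quadrature
inversion of the characteristic function (p e^{−jk} + q e^{jk})^n. The
forward transform convention is P̂(k) = Σ_x P(x) e^{−jkx}; the inversion
therefore carries the phase e^{+jkx}. The opposite inversion phase is
sometimes written alongside this forward convention, but it reflects the
law about the origin (it sends the right-step mass to −1); the
convention used here is fixed by requiring the inversion to reproduce
the master-equation iteration site-wise to 1e−10.

**Continuum limit.** With step length δx and duration δt, the density
ρ = P/δx has drift ψ = (q − p)δx/δt and diffusivity D = δx²/(2δt) in the
limit δx, δt → 0. Only the ψ = 0 case is solved as a PDE; ψ is exposed
as a derived constant. A subtlety: an n-step walk occupies only sites of
one parity, so ρ = P/δx on the dense lattice is a comb. The dense form
(with one padding site each side, exact unit trapezoid mass) is the
default; a sublattice form P/(2δx) on occupied sites — the density once
the period-2 support is accounted for — is what converges to the heat
kernel and is selected with `sublattice=True`.

**Force/drag SDE.** Outside the membrane the position follows
dX = (F/γ)X dt + √D X dW: geometric Brownian motion with drift F/γ. The
exact solution is X_t = x₀ exp((F/γ − D/2)t + √D W_t). The sign of the
noise term is a pure convention at the level of distributions (W and −W
are equal in law); it is fixed to + here because that is the sign under
which the closed form couples pathwise to the Euler–Maruyama recursion
X_{i+1} = X_i(1 + (F/γ)Δt + √D ΔW_i), which is treated as the normative
discretisation. x₀ must be positive: the multiplicative process started
at zero stays at zero.

**Membrane PDE.** Itô's lemma turns the SDE into a backward second-order
PDE for a function Θ(X, t); the substitution X = K e^x,
τ = (T − t)σ²/2, Θ = Kθ (σ = √D) makes it dimensionless and forward in
the pseudo-time τ. With the spatial diffusivity profile D(x) = e^{2x}/2
and force profile F(x) = γe^x/2 this gives

    ∂θ/∂τ = a(x) ∂²θ/∂x² + b(x) ∂θ/∂x,
    a(x) = e^{2x}/(2σ²),  b(x) = (e^x/σ²)(1 − e^x/2)

on x ∈ [0, 1], θ(0, τ) = θ(1, τ) = 0, θ(x, 0) = e^{2x}(x − x²). The
coefficient functions are injectable so alternative groupings of the
transformed equation can be explored without touching the solver. The
pre-transform backward equation in (X, t) is never solved directly; it
is represented by the transform plus the transformed problem.

Two printed-formula tensions are deliberately left visible rather than
reconciled:

- The Gamma-function diffusivity profile e^{2x}/Γ(1+α)² gives e^{2x} at
  α = 1 (Γ(2) = 1), while the maximal-diffusivity convention adopted for
  all α = 1 defaults is e^{2x}/2. `DiffusivityProfile` uses the ½ factor
  at exactly α = 1 and the Gamma formula verbatim elsewhere.
- The bulk relation D = 2F/γ² is implemented verbatim in
  `bulk_diffusivity`, although substituting F(x) = γe^x/2 into it yields
  e^x/γ, not e^{2x}/2 (the squared form 2F²/γ² would reconcile the two);
  `profile_consistency_gap` quantifies the mismatch instead of hiding it.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| p | right-step probability | — | 0.5 |
| n_steps | walk length | steps | 20 |
| δx, δt | lattice step length / duration | length, time | chosen per refinement study |
| D (diffusion) | diffusivity | length²/time | 1.0 |
| F | external force | μN | sweep 1e−6 … 1 |
| γ | drag coefficient | force·time/length | 1.0 |
| D (SDE) | squared volatility of the multiplicative process | 1/time | 0.5 |
| x₀ | initial position | length | 1.0 |
| T | horizon | time | 1.0 |
| σ | volatility √D of the transformed problem | — | sweep 5, 10, 15, 20 |
| τ_end | pseudo-time horizon of the sweep | — | 2.0 |

Only F/γ and D enter the SDE dynamics, so F, γ and D are accepted as raw
numerics with no unit conversion; the μN quotation for F is kept for
interpretability of the sweep range. The sweep defaults (forces 1e−6,
1e−3, 1 μN; σ = 5, 10, 15, 20) are the study conditions the scenarios
reproduce. τ_end = 2 is a package choice: the slowest decay mode of the
σ = 5 problem has rate ≈ 0.5 in τ, so two pseudo-time units let the
small-σ field decay visibly (its L2 norm falls below a third of the
initial value) while σ = 20, whose coefficients are 16× smaller, barely
moves — making both volatility limits observable in one sweep.

## Synthetic data

No external data exist; all stochastic inputs are generated internally
from a single integer seed (numpy PCG64). `sample_walks` realises the
exact Bernoulli step law, so its only departure from the modelled system
is Monte-Carlo error (~N^{−1/2} per site). Wiener increments are drawn
i.i.d. N(0, Δt); refinement uses Brownian-bridge midpoint sampling, so
coarse increments are exactly the sums of their children and all step
sizes share one underlying path — the coupling that strong-error
estimation requires. The fixture bundle (two-step walk table, three
nested refinement levels of one Wiener path, a sine-mode diffusion
reference) is byte-reproducible per seed. What passing tests show is
internal consistency of the model chain and correctness of the
numerics; nothing here emulates measured protein trajectories, crowding,
binding kinetics, or two-dimensional membrane geometry.

## Numerical choices

- **Characteristic-function inversion**: composite trapezoid on 4n + 1
  uniform wavenumbers in [−π, π]. The integrand is a trigonometric
  polynomial of degree ≤ 2n, so the rule is exact up to rounding; any
  imaginary residual above 1e−10 raises instead of being discarded.
- **Binomial masses** are computed in log space (gammaln) for stability
  at large n; p = 0 and p = 1 short-circuit to deterministic walks.
- **Heat-kernel convolution**: composite trapezoid on the caller's grid.
  The kernel's mass beyond ±8 standard deviations is < 1e−15, so the
  finite grid is an adequate truncation of the infinite domain whenever
  the initial mass is interior; a warning fires if the initial profile
  carries more than 1e−10 of its peak at the grid edge, and another if
  the spacing resolves √(2Dt) with fewer than 10 points.
- **Euler–Maruyama** guards against overflow (default bound 1e12), the
  failure mode of the multiplicative scheme at coarse Δt; positivity of
  the numerical path is only guaranteed for Δt small against γ/F and
  1/D and is documented rather than asserted.
- **Strong-error ladder**: increments drawn once at the finest level and
  block-summed to each coarser one (equivalent to bridge refinement,
  built top-down); the order is the least-squares slope of log error
  against log Δt.
- **PDE solver**: second-order central differences for both terms on a
  uniform grid of n_grid interior points plus pinned Dirichlet
  endpoints; BDF time stepping (rtol 1e−8, atol 1e−11 defaults) with the
  exact tridiagonal Jacobian, since the advection term is stiff near
  x = 1 for small σ. At the default resolutions the cell Péclet number
  is ≪ 2, so the semi-discrete system is monotone and the discrete
  solution obeys the no-source maximum bound that `PDESolution`
  enforces. Checkpoints default to 11 uniform τ values.
- **Tie-breaks and degenerate inputs**: n = 0 returns the initial delta;
  τ_end = 0 returns the initial profile exactly; D = 0 makes both SDE
  solvers ignore the Brownian path entirely.

## Problem sizes

The validation suite uses 10⁵ walks for the Monte-Carlo total-variation
check (expected TV ≈ 0.005 at n = 20), three diffusion-limit refinement
levels down to δx = 0.05 (1600-step walks), 10⁴ coupled paths across
step sizes 2⁻⁴ … 2⁻¹⁰ for the strong-order fit, and 199 interior grid
points for the PDE studies. These sizes give standard errors an order of
magnitude below every tolerance they are tested against while keeping
the full suite in a few seconds on one core.

## Limitations

- One spatial dimension throughout; no absorbing/reflecting lattice
  boundaries, no site-dependent step probabilities.
- The free-diffusion solver handles only constant, isotropic D on an
  effectively unbounded domain; bounded domains belong to the membrane
  PDE, which in turn supports only Dirichlet data.
- Euler–Maruyama only; no Milstein or higher-order schemes, no
  time-dependent forcing, no jumps.
- The strong-convergence statement is about the terminal time only, as
  is standard for this diagnostic.
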