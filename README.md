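# memdiff

Stochastic simulation of membrane-protein motion during cell-to-cell
communication. Messenger proteins diffuse laterally inside the fluid
lipid bilayer and pass through it to bind partners on other cells; this
package implements that picture as a ladder of connected models, each one
the limit or transform of the previous:

1. **Lattice random walk** (`memdiff.lattice`) — a protein hops on a
   one-dimensional unit lattice, right with probability *p*, left with
   *q = 1 − p*. The site law obeys the master equation
   `P(x, n+1) = p P(x−1, n) + q P(x+1, n)`, evaluated three independent
   ways (step-by-step iteration, the binomial closed form
   `C(n, l) p^{n−l} q^l` at displacement `n − 2l`, and inversion of the
   characteristic function `(p e^{−jk} + q e^{jk})^n`), plus seeded
   Monte-Carlo sampling and the rescaling `ρ = P/δx` to a continuum
   density with drift `ψ = (q−p)δx/δt` and diffusivity `D = δx²/(2δt)`.
2. **Free diffusion** (`memdiff.diffusion`) — the drift-free continuum
   limit `∂ρ/∂t = D ∂²ρ/∂x²`: Fourier-mode decay `e^{−Dk²t}` and the
   Green's-function (heat-kernel) convolution solver.
3. **Force/drag SDE** (`memdiff.sde`) — outside the membrane the
   protein position follows geometric Brownian motion
   `dX = (F/γ) X dt + √D X dW`, with the exact solution
   `X_t = x₀ exp((F/γ − D/2)t + √D W_t)`, the Euler–Maruyama scheme
   `X_{i+1} = X_i + (F/γ)X_i Δt + √D X_i ΔW_i`, a shared-path force
   sweep, and strong-convergence diagnostics `E|Y(T) − X(T)|` on
   bridge-coupled Wiener paths (order ½ for this scheme).
4. **Membrane PDE** (`memdiff.pde`) — applying Itô's lemma and the
   log/time-reversal transform `X = K e^x`, `τ = (T−t)σ²/2` yields the
   dimensionless advection–diffusion equation
   `∂θ/∂τ = [e^{2x}/(2σ²)] ∂²θ/∂x² + [e^x/σ²](1 − e^x/2) ∂θ/∂x`
   on x ∈ [0, 1] with θ = 0 at both ends and
   θ(x, 0) = e^{2x}(x − x²), solved by method of lines with implicit
   adaptive time stepping, including the volatility sweep σ = 5…20.

The intended users are modellers who want a small, fully tested, seeded
reference implementation of this chain — walk → diffusion limit → SDE →
transformed PDE — rather than a black-box solver.

## Worked example

Strong convergence of the Euler–Maruyama scheme for F/γ = 0.5, D = 0.5,
x₀ = 1, T = 1, with 10 000 bridge-coupled paths per step size:

```python
from memdiff import SDEParams, strong_error, sigma_sweep

params = SDEParams(force=0.5, drag=1.0, diffusivity=0.5, x0=1.0, horizon=1.0)
report = strong_error(params, [2.0**-k for k in range(4, 11)], n_paths=10_000, seed=1)
print(report.to_frame().to_string(index=False))
print(f"fitted strong order: {report.fitted_order:.3f}")
```

```
      dt  strong_error  standard_error
0.062500      0.115965        0.001840
0.031250      0.082813        0.001223
0.015625      0.058282        0.000795
0.007812      0.042067        0.000572
0.003906      0.029647        0.000392
0.001953      0.021138        0.000273
0.000977      0.014823        0.000185
fitted strong order: 0.494
```

Each row is the Monte-Carlo estimate of `E|Y(T) − X(T)|` — the mean
absolute gap at the horizon between the exact solution and the numerical
one driven by the *same* Wiener path — and halving dt shrinks it by
about √2: the fitted slope 0.494 is the strong order ½ expected for
Euler–Maruyama with multiplicative noise.

The volatility sweep of the membrane equation shows the freezing effect
of large σ (both coefficients carry 1/σ²):

```python
_, table = sigma_sweep([5, 10, 15, 20], n_grid=199, tau_end=2.0)
print(table.to_string(index=False))
```

```
 sigma  l2_distance_from_ic
   5.0             0.422918
  10.0             0.241459
  15.0             0.153587
  20.0             0.105763
```

The L2 distance of θ(·, τ_end) from the initial profile decreases
monotonically in σ: at σ = 20 the field stays close to its initial
condition, while at σ = 5 it has decayed most of the way to the zero
state imposed by the boundaries.

## Command line

Every subcommand writes CSV output plus a JSON manifest recording all
parameters and the seed; replaying a manifest reproduces stochastic
output bit-for-bit.

```sh
memdiff --seed 1 --out-dir out walk --p 0.5 --steps 20 --mode montecarlo --n-walks 100000
memdiff --out-dir out diffuse --d 1.0 --t 0.5
memdiff --seed 1 --out-dir out sde --force-sweep 1e-6 --force-sweep 1e-3 --force-sweep 1
memdiff --seed 1 --out-dir out converge --levels 4,5,6,7,8,9,10 --paths 10000
memdiff --out-dir out pde --sigma 5 --sigma 10 --sigma 15 --sigma 20
memdiff --seed 1 --out-dir out --config experiment.yaml scenario figure2
```

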