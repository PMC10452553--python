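"""Scenario execution: seeded runs producing CSV outputs plus a manifest.

Each ``run_*`` function performs one experiment, writes its tables under an
output directory, and returns the :class:`~memdiff.manifest.RunManifest`
that records every parameter and seed.  ``replay`` re-executes a manifest;
stochastic outputs must come back bit-for-bit identical, which the test
suite enforces.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import diffusion, lattice, pde, sde
from .fixtures import make_fixtures
from .manifest import ExperimentConfig, RunManifest, log_seed

DEFAULT_FIGURE2_FORCES = [1e-6, 1e-3, 1.0]  # micronewtons
DEFAULT_FIGURE3_SIGMAS = [5.0, 10.0, 15.0, 20.0]


def read_output(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by any subcommand with lossless float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def _finish(
    subcommand: str, params: dict[str, Any], seed: int, out_dir: Path, files: list[Path]
) -> RunManifest:
    manifest = RunManifest(
        subcommand=subcommand,
        parameters=params,
        seed=seed,
        outputs=[f.name for f in files],
    )
    manifest.write(out_dir / f"{subcommand}_manifest.json")
    return manifest


def run_walk(
    out_dir: str | Path,
    p: float = 0.5,
    steps: int = 20,
    mode: str = "exact",
    n_walks: int = 10_000,
    origin: int = 0,
    seed: int = 0,
) -> RunManifest:
    """Walk distribution by exact recursion-equivalent closed form,
    Fourier inversion, or Monte Carlo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = lattice.LatticeWalkSpec(p=p, n_steps=steps, origin=origin)
    if mode == "exact":
        dist = lattice.closed_form_distribution(spec)
    elif mode == "fourier":
        dist = lattice.invert_characteristic(spec)
    elif mode == "montecarlo":
        log_seed("sample_walks", seed)
        dist, _ = lattice.sample_walks(spec, n_walks, seed)
    else:
        raise ValueError(f"unknown walk mode {mode!r}")
    path = out / "walk_distribution.csv"
    pd.DataFrame({"site": dist.sites, "probability": dist.probabilities}).to_csv(
        path, index=False
    )
    params = dict(p=p, steps=steps, mode=mode, n_walks=n_walks, origin=origin)
    return _finish("walk", params, seed, out, [path])


def run_diffuse(
    out_dir: str | Path,
    D: float = 1.0,
    t: float = 0.5,
    ic: str = "gaussian",
    ic_params: dict[str, float] | None = None,
    grid_min: float = -10.0,
    grid_max: float = 10.0,
    grid_points: int = 401,
    seed: int = 0,
) -> RunManifest:
    """Free diffusion of an initial profile by heat-kernel convolution."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = np.linspace(grid_min, grid_max, grid_points)
    ic_params = dict(ic_params or {})
    if ic == "gaussian":
        mean = ic_params.get("mean", 0.0)
        std = ic_params.get("std", 1.0)
        f = np.exp(-((grid - mean) ** 2) / (2 * std**2)) / (std * np.sqrt(2 * np.pi))
    elif ic == "delta-approx":
        # narrow Gaussian standing in for a point mass: 3 grid cells wide
        std = 3.0 * (grid[1] - grid[0])
        f = np.exp(-(grid**2) / (2 * std**2)) / (std * np.sqrt(2 * np.pi))
    elif ic.startswith("csv:"):
        table = pd.read_csv(ic[4:])
        grid = table["x"].to_numpy()
        f = table["f"].to_numpy()
    else:
        raise ValueError(f"unknown initial condition {ic!r}")
    field = diffusion.solve_free_diffusion(f, t, D, grid)
    path = out / "diffusion_profile.csv"
    pd.DataFrame({"x": field.grid, "rho": field.density}).to_csv(path, index=False)
    params = dict(
        D=D, t=t, ic=ic, ic_params=ic_params, grid_min=grid_min,
        grid_max=grid_max, grid_points=grid_points,
    )
    return _finish("diffuse", params, seed, out, [path])


def run_sde(
    out_dir: str | Path,
    F: float = 1.0,
    gamma: float = 1.0,
    D: float = 0.25,
    x0: float = 1.0,
    T: float = 1.0,
    steps: int = 256,
    paths: int = 1,
    method: str = "em",
    forces: list[float] | None = None,
    seed: int = 0,
) -> RunManifest:
    """Protein trajectories under force and drag; optionally a force sweep
    on a shared Wiener path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_seed("run_sde", seed)
    params = sde.SDEParams(
        force=F, drag=gamma, diffusivity=D, x0=x0, horizon=T, n_steps=steps, seed=seed
    )
    solver = sde.euler_maruyama if method == "em" else sde.exact_solution
    frames = []
    if forces:
        for f_val, traj in sde.force_sweep(params, forces, seed, method=method):
            frame = traj.to_frame()
            frame["force"] = f_val
            frames.append(frame)
    else:
        rng = np.random.default_rng(seed)
        dt = T / steps
        inc = rng.normal(0.0, np.sqrt(dt), (paths, steps))
        wpath = sde.BrownianPath(np.linspace(0.0, T, steps + 1), inc)
        frames.append(solver(params, wpath).to_frame())
    table = pd.concat(frames, ignore_index=True)
    path = out / "sde_paths.csv"
    table.to_csv(path, index=False)
    run_params = dict(
        F=F, gamma=gamma, D=D, x0=x0, T=T, steps=steps, paths=paths,
        method=method, forces=list(forces) if forces else None,
    )
    return _finish("sde", run_params, seed, out, [path])


def run_converge(
    out_dir: str | Path,
    F: float = 0.5,
    gamma: float = 1.0,
    D: float = 0.5,
    x0: float = 1.0,
    T: float = 1.0,
    levels: list[int] | None = None,
    paths: int = 10_000,
    seed: int = 0,
) -> RunManifest:
    """Strong-convergence study; ``levels`` are dyadic exponents k giving
    step sizes dt = T * 2^-k."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_seed("run_converge", seed)
    levels = list(levels or range(4, 11))
    dts = np.array([T * 2.0 ** (-k) for k in levels])
    params = sde.SDEParams(
        force=F, drag=gamma, diffusivity=D, x0=x0, horizon=T,
        n_steps=int(2 ** max(levels)), seed=seed,
    )
    report = sde.strong_error(params, dts, paths, seed)
    csv_path = out / "strong_errors.csv"
    report.to_frame().to_csv(csv_path, index=False)
    json_path = out / "convergence_report.json"
    pd.Series(
        {
            "fitted_order": report.fitted_order,
            "n_paths": report.n_paths,
            "n_levels": len(levels),
        }
    ).to_json(json_path, indent=2)
    run_params = dict(
        F=F, gamma=gamma, D=D, x0=x0, T=T, levels=levels, paths=paths
    )
    return _finish("converge", run_params, seed, out, [csv_path, json_path])


def run_pde(
    out_dir: str | Path,
    sigmas: list[float] | None = None,
    grid: int = 199,
    tau_end: float = 2.0,
    checkpoints: int = 11,
    seed: int = 0,
) -> RunManifest:
    """Advection-diffusion sigma sweep with per-sigma distance table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sigmas = list(sigmas or DEFAULT_FIGURE3_SIGMAS)
    ckpts = np.linspace(0.0, tau_end, checkpoints)
    solutions, distances = pde.sigma_sweep(sigmas, grid, tau_end, ckpts)
    frames = []
    for s, sol in solutions.items():
        frame = sol.to_frame()
        frame.insert(0, "sigma", s)
        frames.append(frame)
    field_path = out / "pde_field.csv"
    pd.concat(frames, ignore_index=True).to_csv(field_path, index=False)
    dist_path = out / "pde_distances.csv"
    distances.to_csv(dist_path, index=False)
    run_params = dict(
        sigmas=sigmas, grid=grid, tau_end=tau_end, checkpoints=checkpoints
    )
    return _finish("pde", run_params, seed, out, [field_path, dist_path])


def run_fixtures(out_dir: str | Path, seed: int = 0) -> RunManifest:
    files = make_fixtures(seed, out_dir)
    return _finish("fixtures", {}, seed, Path(out_dir), list(files.values()))


_SCENARIOS = {
    "walk": ("walk", run_walk),
    "diffuse": ("diffusion", run_diffuse),
    "sde": ("sde", run_sde),
    "converge": ("converge", run_converge),
    "pde": ("pde", run_pde),
}


def run_scenario(
    config: ExperimentConfig, scenario: str, out_dir: str | Path | None = None
) -> RunManifest:
    """Dispatch a named scenario from a validated configuration.

    Bundled scenarios: ``figure2`` (force sweep over 1e-6 ... 1 uN on a
    shared Wiener path) and ``figure3`` (sigma sweep over 5, 10, 15, 20).
    """
    out = Path(out_dir or config.output_dir)
    if scenario == "figure2":
        block = dict(config.blocks.get("sde", {}))
        block.setdefault("forces", list(DEFAULT_FIGURE2_FORCES))
        return run_sde(out, seed=config.seed, **block)
    if scenario == "figure3":
        block = dict(config.blocks.get("pde", {}))
        block.setdefault("sigmas", list(DEFAULT_FIGURE3_SIGMAS))
        return run_pde(out, seed=config.seed, **block)
    if scenario in _SCENARIOS:
        block_name, fn = _SCENARIOS[scenario]
        block = config.require(block_name)
        return fn(out, seed=config.seed, **block)
    raise ValueError(
        f"unknown scenario {scenario!r}; known: "
        f"{sorted(_SCENARIOS) + ['figure2', 'figure3']}"
    )


def replay(manifest: RunManifest, out_dir: str | Path) -> RunManifest:
    """Re-execute a recorded run; stochastic outputs reproduce bit-for-bit."""
    runners = {
        "walk": run_walk,
        "diffuse": run_diffuse,
        "sde": run_sde,
        "converge": run_converge,
        "pde": run_pde,
        "fixtures": run_fixtures,
    }
    if manifest.subcommand not in runners:
        raise ValueError(f"cannot replay subcommand {manifest.subcommand!r}")
    return runners[manifest.subcommand](
        out_dir, seed=manifest.seed, **manifest.parameters
    )
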