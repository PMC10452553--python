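"""Deterministic fixture bundles for tests and demonstrations.

Everything here is reproducible from a single integer seed: a two-step
enumerated walk table, a coupled Brownian path stored at three refinement
levels (each coarse increment is exactly the sum of its two children), and
a sine-mode reference solution of the constant-coefficient diffusion
equation for which the decay law is known in closed form.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import LatticeWalkSpec, closed_form_distribution
from .manifest import log_seed
from .sde import generate_brownian_path


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture bundle; byte-identical across runs per seed."""
    log_seed("make_fixtures", seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # two-step walk at p = 0.3: the four-path enumeration in table form
    dist = closed_form_distribution(LatticeWalkSpec(p=0.3, n_steps=2))
    walk = pd.DataFrame({"site": dist.sites, "probability": dist.probabilities})
    paths["walk"] = out / "walk_two_step.csv"
    walk.to_csv(paths["walk"], index=False)

    # one Wiener path at three nested refinement levels
    rng = np.random.default_rng(seed)
    coarse = generate_brownian_path(8, 1.0, seed)
    mid = coarse.refine(rng)
    fine = mid.refine(rng)
    rows = []
    for level, path in enumerate([coarse, mid, fine]):
        for t0, t1, dw in zip(path.times[:-1], path.times[1:], path.increments):
            rows.append({"level": level, "t_start": t0, "t_end": t1, "dW": dw})
    paths["brownian"] = out / "brownian_refinement.csv"
    pd.DataFrame(rows).to_csv(paths["brownian"], index=False)

    # sine-mode diffusion reference: theta = exp(-D m^2 pi^2 tau) sin(m pi x)
    D0, m, tau = 1.0, 2, 0.05
    x = np.linspace(0.0, 1.0, 101)
    ref = pd.DataFrame(
        {
            "x": x,
            "theta_initial": np.sin(m * np.pi * x),
            "theta_final": np.exp(-D0 * m**2 * np.pi**2 * tau) * np.sin(m * np.pi * x),
        }
    )
    paths["sine_mode"] = out / "sine_mode_reference.csv"
    ref.to_csv(paths["sine_mode"], index=False)
    return paths
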