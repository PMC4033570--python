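"""Synthetic pseudo-experimental data with the structure of the chondrocyte
stimulation experiments.

Cells are (virtually) treated at t=0 and harvested at 4, 8, 12, 24, 48 and
72 hours; observations are species amounts at those times with
multiplicative log-normal noise per replicate, mimicking qPCR-style
relative quantification of positive, right-skewed expression measurements.
The generating parameter vector and seed ride along with every dataset so
parameter-recovery tests can close the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ModelSpec
from .ode import simulate_ode

DEFAULT_TIMEPOINTS = (4.0, 8.0, 12.0, 24.0, 48.0, 72.0)


@dataclass
class SyntheticDataset:
    observations: pd.DataFrame       # columns: species, time_h, replicate, value
    timepoints: tuple
    generating_params: dict
    noise_sigma: float
    seed: int
    scenario_label: str = ""

    def values(self, species_id: str, time_h: float) -> np.ndarray:
        df = self.observations
        sel = df[(df.species == species_id) & (np.isclose(df.time_h, time_h))]
        return sel.value.to_numpy()

    def to_csv(self) -> str:
        return self.observations.to_csv(index=False)

    def sidecar_json(self) -> str:
        return json.dumps({
            "generating_params": {k: float(v) for k, v in self.generating_params.items()},
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "timepoints": list(self.timepoints),
            "scenario": self.scenario_label,
        }, indent=2)


def generate_timecourse_data(
    model: ModelSpec,
    params: dict | None = None,
    scenario=None,
    species=("mRNA_MMP1", "mRNA_MMP13", "mRNA_TIMP1"),
    timepoints=DEFAULT_TIMEPOINTS,
    noise_sigma: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate, sample at harvest times, add log-normal noise per replicate.

    ``noise_sigma`` is the standard deviation of the log-amount; zero noise
    returns the deterministic values exactly.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    m = model.with_parameters(params) if params else model
    horizon = max(timepoints)
    grid = np.unique(np.concatenate([[0.0], np.asarray(timepoints, dtype=float)]))
    tc = simulate_ode(m, scenario, horizon_h=horizon, grid_h=grid)
    rng = np.random.default_rng(seed)
    rows = []
    for sp in species:
        y = tc[sp]
        for t in timepoints:
            true = y[np.argmin(np.abs(grid - t))]
            noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=n_replicates) \
                if noise_sigma > 0 else np.ones(n_replicates)
            for rep in range(n_replicates):
                rows.append({"species": sp, "time_h": float(t),
                             "replicate": rep, "value": float(true * noise[rep])})
    return SyntheticDataset(
        observations=pd.DataFrame(rows),
        timepoints=tuple(float(t) for t in timepoints),
        generating_params={} if params is None else dict(params),
        noise_sigma=noise_sigma,
        seed=seed,
        scenario_label=getattr(scenario, "label", "untreated"),
    )


def latin_hypercube_log(bounds: dict, n: int, seed: int = 0):
    """Latin-hypercube sample on log scale: one point per stratum per axis.

    ``bounds`` maps parameter name -> (low, high), both positive; degenerate
    bounds (low == high) pin the axis to that value.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(bounds)
    cols = {}
    for name in names:
        lo, hi = bounds[name]
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError(f"bounds for {name} must satisfy 0 < low <= high")
        if lo == hi:
            cols[name] = np.full(n, lo)
            continue
        strata = (np.arange(n) + rng.uniform(size=n)) / n
        rng.shuffle(strata)
        cols[name] = 10.0 ** (np.log10(lo) + strata * (np.log10(hi) - np.log10(lo)))
    return [{name: float(cols[name][i]) for name in names} for i in range(n)]


def generate_parameter_sets(bounds: dict, n: int, seed: int = 0):
    """Seeded Latin-hypercube parameter vectors within (positive) bounds."""
    return latin_hypercube_log(bounds, n, seed=seed)
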