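"""Exact stochastic simulation: the Gillespie direct method.

Propensities follow the combinatorial mass-action convention: a reactant
with stoichiometry s contributes the falling factorial n(n-1)...(n-s+1)/s!,
modifiers contribute their count.  Waiting times are exponential draws and
the reaction index a categorical draw, both obtained from one named,
seedable uniform generator by inverse transform, so a given (model,
scenario, seed) reproduces the identical event sequence.  Trajectories are
recorded on an output grid by last-event carry-forward.

The inner loop is compiled with numba; the generator is numba's
NumPy-compatible Mersenne Twister seeded per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import HOUR, ModelSpec
from .ode import GRID_48H, TimeCourse, _apply_scenario, parameter_hash


class PropensityOverflowError(RuntimeError):
    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


def propensities(model: ModelSpec, state) -> np.ndarray:
    """Propensity of every reaction at an integer state."""
    state = np.asarray(state)
    if np.any(state < 0) or not np.all(np.equal(np.mod(state, 1), 0)):
        raise ValueError("state must be non-negative integers")
    idx = model.species_index()
    pm = model.parameter_map()
    a = np.empty(len(model.reactions))
    for j, r in enumerate(model.reactions):
        v = pm[r.rate_constant].value
        for sid, sto in r.reactants.items():
            n = state[idx[sid]]
            for i in range(sto):
                v *= (n - i)
            v /= math.factorial(sto)
        for sid in r.modifiers:
            v *= state[idx[sid]]
        a[j] = max(v, 0.0)
    return a


def _compile_ssa(model: ModelSpec):
    idx = model.species_index()
    pm = model.parameter_map()
    n_r = len(model.reactions)
    mr = max(1, max((len(r.reactants) for r in model.reactions), default=0))
    mc = max(1, max((len(set(r.reactants) | set(r.products)) for r in model.reactions), default=0))
    mm = max(1, max((len(r.modifiers) for r in model.reactions), default=0))
    react_idx = np.full((n_r, mr), -1, dtype=np.int64)
    react_sto = np.zeros((n_r, mr), dtype=np.int64)
    mod_idx = np.full((n_r, mm), -1, dtype=np.int64)
    chg_idx = np.full((n_r, mc), -1, dtype=np.int64)
    chg_val = np.zeros((n_r, mc), dtype=np.int64)
    k = np.empty(n_r)
    for j, r in enumerate(model.reactions):
        k[j] = pm[r.rate_constant].value
        for c, (sid, sto) in enumerate(r.reactants.items()):
            react_idx[j, c] = idx[sid]
            react_sto[j, c] = sto
            k[j] /= math.factorial(sto)
        for c, sid in enumerate(r.modifiers):
            mod_idx[j, c] = idx[sid]
        net = {}
        for sid, sto in r.reactants.items():
            net[sid] = net.get(sid, 0) - sto
        for sid, sto in r.products.items():
            net[sid] = net.get(sid, 0) + sto
        for c, (sid, d) in enumerate(net.items()):
            chg_idx[j, c] = idx[sid]
            chg_val[j, c] = d
    return k, react_idx, react_sto, mod_idx, chg_idx, chg_val


@njit(cache=True)
def _ssa_core(state, k, react_idx, react_sto, mod_idx, chg_idx, chg_val,
              t_grid, out, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    n_r = k.shape[0]
    a = np.zeros(n_r)
    t = 0.0
    gi = 0
    n_grid = t_grid.shape[0]
    t_end = t_grid[n_grid - 1]
    while True:
        # propensities
        total = 0.0
        for j in range(n_r):
            v = k[j]
            for c in range(react_idx.shape[1]):
                si = react_idx[j, c]
                if si < 0:
                    break
                n = state[si]
                for i in range(react_sto[j, c]):
                    v *= (n - i)
            for c in range(mod_idx.shape[1]):
                si = mod_idx[j, c]
                if si < 0:
                    break
                v *= state[si]
            if v < 0.0:
                v = 0.0
            a[j] = v
            total += v
        if not np.isfinite(total):
            return -1, t
        if total <= 0.0:
            while gi < n_grid:
                for s in range(state.shape[0]):
                    out[gi, s] = state[s]
                gi += 1
            return 0, t
        # exponential waiting time by inverse transform
        u1 = np.random.random()
        while u1 <= 0.0:
            u1 = np.random.random()
        t_next = t + (-np.log(u1)) / total
        # record grid points passed
        while gi < n_grid and t_grid[gi] < t_next:
            for s in range(state.shape[0]):
                out[gi, s] = state[s]
            gi += 1
        if gi >= n_grid or t_next > t_end:
            return 0, t
        t = t_next
        # categorical reaction choice by inverse transform
        u2 = np.random.random() * total
        acc = 0.0
        jsel = n_r - 1
        for j in range(n_r):
            acc += a[j]
            if u2 <= acc:
                jsel = j
                break
        for c in range(chg_idx.shape[1]):
            si = chg_idx[jsel, c]
            if si < 0:
                break
            state[si] += chg_val[jsel, c]


def simulate_ssa(model: ModelSpec, scenario=None, horizon_h: float = 48.0,
                 seed: int = 0, grid_h=None) -> TimeCourse:
    """One exact direct-method trajectory, recorded on the output grid."""
    m, label = _apply_scenario(model, scenario)
    if grid_h is None:
        grid_h = GRID_48H if horizon_h <= 48.0 else np.arange(0.0, horizon_h + 1e-9, 1.0)
    grid_h = np.asarray(grid_h, dtype=float)
    y0 = m.initial_state()
    if not np.all(np.equal(np.mod(y0, 1), 0)):
        raise ValueError("stochastic simulation requires integer initial amounts")
    state = y0.astype(np.int64)
    k, ri, rs, mi, ci, cv = _compile_ssa(m)
    out = np.zeros((grid_h.size, state.size), dtype=np.int64)
    status, t_last = _ssa_core(state, k, ri, rs, mi, ci, cv,
                               grid_h * HOUR, out, np.uint32(seed & 0x7FFFFFFF))
    if status != 0:
        raise PropensityOverflowError(
            f"propensity overflow at t={t_last / HOUR:.3f} h", state=state.copy()
        )
    return TimeCourse(
        time_h=grid_h,
        species=[s.id for s in m.species],
        values=out.astype(float),
        provenance={
            "scenario": label,
            "engine": "ssa",
            "seed": int(seed),
            "param_hash": parameter_hash(m),
        },
    )


@dataclass
class EnsembleResult:
    """A batch of stochastic trajectories sharing one output grid."""

    trajectories: list
    seeds: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")
        if len(self.seeds) != len(self.trajectories):
            raise ValueError("one seed per trajectory")

    @property
    def n_runs(self) -> int:
        return len(self.trajectories)

    def stack(self, species_id: str) -> np.ndarray:
        """(n_runs, n_times) array for one species."""
        return np.stack([tc[species_id] for tc in self.trajectories])

    def to_tidy_frame(self):
        import pandas as pd

        frames = []
        for seed, tc in zip(self.seeds, self.trajectories):
            df = tc.to_tidy_frame()
            df.insert(0, "run", seed)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def run_ensemble(model: ModelSpec, scenario=None, horizon_h: float = 48.0,
                 n_runs: int = 50, base_seed: int = 0, grid_h=None) -> EnsembleResult:
    """n_runs independent trajectories; run i uses seed base_seed + i.

    Runs are mutually independent (each has its own generator), so the
    result does not depend on execution order.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = [base_seed + i for i in range(n_runs)]
    trajectories = [
        simulate_ssa(model, scenario, horizon_h=horizon_h, seed=s, grid_h=grid_h)
        for s in seeds
    ]
    return EnsembleResult(
        trajectories=trajectories,
        seeds=seeds,
        provenance={"engine": "ssa-ensemble", "base_seed": int(base_seed)},
    )


@dataclass
class EnsembleSummary:
    time_h: np.ndarray
    species: list
    mean: np.ndarray       # (n_times, n_species)
    variance: np.ndarray   # unbiased, ddof=1
    cv: np.ndarray         # NaN where the mean is 0 (undefined)
    quantiles: dict        # q -> (n_times, n_species)

    def mean_timecourse(self) -> TimeCourse:
        return TimeCourse(time_h=self.time_h, species=list(self.species),
                          values=self.mean.copy(),
                          provenance={"engine": "ssa-ensemble-mean"})

    def series(self, which: str, species_id: str) -> np.ndarray:
        j = self.species.index(species_id)
        return getattr(self, which)[:, j]


def ensemble_summary(ens: EnsembleResult, quantiles=(0.05, 0.5, 0.95)) -> EnsembleSummary:
    """Per-species mean, unbiased variance, CV and quantiles on the grid."""
    if ens.n_runs < 2:
        raise ValueError("variance requires at least 2 runs")
    arr = np.stack([tc.values for tc in ens.trajectories])  # (runs, times, species)
    mean = arr.mean(axis=0)
    var = arr.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, np.sqrt(var) / mean, np.nan)
    qs = {q: np.quantile(arr, q, axis=0) for q in quantiles}
    tc0 = ens.trajectories[0]
    return EnsembleSummary(time_h=tc0.time_h, species=list(tc0.species),
                           mean=mean, variance=var, cv=cv, quantiles=qs)
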