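"""Treatments and virtual interventions.

A :class:`Scenario` is a named set of initial-amount overrides plus
parameter scalings; treatments add cytokines/activator as t=0 boluses,
interventions either scale one rate constant (kinase inhibition), add a
competing species (receptor antagonists) or raise an initial protein amount
(TIMP overexpression).  ``dose_scan`` runs one simulation per dose level and
collects the standard readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .network import ModelSpec
from .ode import GRID_14D, GRID_48H, peak_metrics, percent_release, simulate_ode

DAY14_H = 336.0

#: kinase-inhibition targets -> the rate constant each scales
KINASE_TARGETS = {"JAK1": "k_phosSTAT3", "JNK": "k_phoscJun", "p38": "k_phoscFos"}
RECEPTORS = {"IL1R": ("IL1Ra", "IL1R"), "OSMR": ("OSMRa", "OSMR")}
TIMPS = ("TIMP1", "TIMP3")


@dataclass
class Scenario:
    label: str
    initial_overrides: dict = field(default_factory=dict)
    parameter_scalings: dict = field(default_factory=dict)
    horizon_h: float = 48.0

    def __post_init__(self):
        for k, v in self.parameter_scalings.items():
            if v < 0:
                raise ValueError(f"scaling for {k} must be >= 0")

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "label": self.label,
                "initial_overrides": dict(self.initial_overrides),
                "parameter_scalings": dict(self.parameter_scalings),
                "horizon_h": self.horizon_h,
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        d = yaml.safe_load(text)
        return cls(
            label=d["label"],
            initial_overrides=d.get("initial_overrides", {}) or {},
            parameter_scalings=d.get("parameter_scalings", {}) or {},
            horizon_h=float(d.get("horizon_h", 48.0)),
        )


def make_treatment(model: ModelSpec, il1: bool, osm: bool, activator: bool,
                   horizon_h: float = 48.0) -> Scenario:
    """Cytokine/activator addition: set t=0 boluses to the calibrated doses."""
    pm = model.parameter_map()
    overrides = {
        "IL1": pm["il1_dose"].value if il1 else 0,
        "OSM": pm["osm_dose"].value if osm else 0,
        "MMPact": pm["mmpact_dose"].value if activator else 0,
    }
    bits = [name for name, on in (("il1", il1), ("osm", osm), ("activator", activator)) if on]
    label = "_".join(bits) if bits else "basal"
    return Scenario(label=label, initial_overrides=overrides, horizon_h=horizon_h)


def apply_kinase_inhibition(model: ModelSpec, target: str, fraction: float) -> ModelSpec:
    """Scale the kinase's rate constant by (1 - fraction); nothing else changes."""
    if target not in KINASE_TARGETS:
        raise ValueError(
            f"unknown kinase target {target!r}; valid targets: {sorted(KINASE_TARGETS)}"
        )
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("inhibition fraction must be in [0, 1]")
    return model.scaled_parameters({KINASE_TARGETS[target]: 1.0 - fraction})


def apply_receptor_antagonist(model: ModelSpec, receptor: str, ratio: float) -> ModelSpec:
    """Add antagonist at ratio x (receptor initial amount); competitive, silent."""
    if receptor not in RECEPTORS:
        raise ValueError(f"unknown receptor {receptor!r}; valid: {sorted(RECEPTORS)}")
    if ratio < 0:
        raise ValueError("antagonist:receptor ratio must be >= 0")
    antagonist, rec = RECEPTORS[receptor]
    r0 = model.species_map()[rec].initial_amount
    return model.with_initial_amounts({antagonist: ratio * r0})


def apply_timp_overexpression(model: ModelSpec, which: str, amount: float) -> ModelSpec:
    """Set the initial amount of free TIMP-1 or TIMP-3 protein."""
    if which not in TIMPS:
        raise ValueError(f"unknown TIMP {which!r}; valid: {TIMPS}")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    return model.with_initial_amounts({which: amount})


def readout_set(tc, initial_pool: float = 10000.0, peak_species: str = "mRNA_MMP1") -> dict:
    """Standard figure readouts from one trajectory."""
    agg = percent_release(tc, "AggFrag", initial_pool) if "AggFrag" in tc else None
    coll = percent_release(tc, "CollFrag", initial_pool) if "CollFrag" in tc else None
    pt, pv, fold, flags = peak_metrics(tc, peak_species)
    out = {
        "peak_time_h": pt,
        "peak_value": pv,
        "fold_induction": fold,
        "peak_flags": flags,
    }
    if agg is not None:
        out["pct_aggrecan_final"] = float(agg[-1])
    if coll is not None:
        out["pct_collagen_final"] = float(coll[-1])
    return out


@dataclass
class ScanResult:
    levels: list
    readouts: list
    engine: str
    label: str = ""

    def __post_init__(self):
        if len(self.levels) != len(self.readouts):
            raise ValueError("one readout per level required")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level, ro in zip(self.levels, self.readouts):
            row = {"level": level}
            row.update({k: v for k, v in ro.items() if not isinstance(v, list)})
            rows.append(row)
        return pd.DataFrame(rows)

    def day14_collagen(self) -> np.ndarray:
        return np.array([ro["pct_collagen_final"] for ro in self.readouts])

    def day14_aggrecan(self) -> np.ndarray:
        return np.array([ro["pct_aggrecan_final"] for ro in self.readouts])


def dose_scan(model: ModelSpec, intervention, levels, scenario: Scenario | None = None,
              horizon_h: float = DAY14_H, engine: str = "ode", n_runs: int = 0,
              base_seed: int = 0, label: str = "") -> ScanResult:
    """Run one simulation (or SSA ensemble) per dose level.

    ``intervention(model, level) -> model`` applies one dose.  Levels are run
    in the given order; results are deterministic for the ODE engine and
    seed-determined (seed = base_seed + run index, restarting per level)
    for the SSA engine.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("a scan needs at least 2 levels")
    if scenario is None:
        scenario = make_treatment(model, True, True, True, horizon_h=horizon_h)
    step = 1.0 if horizon_h > 48.0 else 0.25
    grid = np.arange(0.0, horizon_h + 1e-9, step)
    readouts = []
    for level in levels:
        m = intervention(model, level)
        if engine == "ode":
            tc = simulate_ode(m, scenario, horizon_h=horizon_h, grid_h=grid)
            readouts.append(readout_set(tc))
        elif engine == "ssa":
            from .ssa import ensemble_summary, run_ensemble

            ens = run_ensemble(m, scenario, horizon_h=horizon_h, n_runs=n_runs,
                               base_seed=base_seed, grid_h=grid)
            summ = ensemble_summary(ens)
            mean_tc = summ.mean_timecourse()
            ro = readout_set(mean_tc)
            ro["day14_collagen_per_run"] = [
                float(100.0 * t["CollFrag"][-1] / 10000.0) for t in ens.trajectories
            ]
            readouts.append(ro)
        else:
            raise ValueError("engine must be 'ode' or 'ssa'")
    return ScanResult(levels=levels, readouts=readouts, engine=engine, label=label)


# named scan presets mirroring the intervention figures
SCAN_PRESETS = {
    "fig3a_il1ra": ("receptor_antagonist", "IL1R", [1, 10, 100, 1000]),
    "fig3b_osmra": ("receptor_antagonist", "OSMR", [1, 10, 100, 1000]),
    "fig4a_jak1": ("kinase_inhibition", "JAK1", [round(f, 1) for f in np.arange(0, 1.01, 0.1)]),
    "fig4b_p38": ("kinase_inhibition", "p38", [round(f, 1) for f in np.arange(0, 1.01, 0.1)]),
    "fig4c_jnk": ("kinase_inhibition", "JNK", [round(f, 1) for f in np.arange(0, 1.01, 0.1)]),
    "fig6a_timp1": ("timp_overexpression", "TIMP1", [200, 2000, 20000, 200000]),
    "fig6b_timp3": ("timp_overexpression", "TIMP3", [200, 2000, 20000, 200000]),
}


def preset_scan(model: ModelSpec, preset: str, engine: str = "ode", n_runs: int = 0,
                base_seed: int = 0) -> ScanResult:
    if preset not in SCAN_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid: {sorted(SCAN_PRESETS)}")
    kind, target, levels = SCAN_PRESETS[preset]
    if kind == "receptor_antagonist":
        intervention = lambda m, x: apply_receptor_antagonist(m, target, x)  # noqa: E731
    elif kind == "kinase_inhibition":
        intervention = lambda m, x: apply_kinase_inhibition(m, target, x)  # noqa: E731
    else:
        intervention = lambda m, x: apply_timp_overexpression(m, target, x)  # noqa: E731
    return dose_scan(model, intervention, levels, engine=engine, n_runs=n_runs,
                     base_seed=base_seed, label=preset)
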