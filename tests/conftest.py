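import numpy as np
import pytest

from chondrosim import build_integrated_model, make_treatment, simulate_ode
from chondrosim.network import (
    COMPARTMENTS,
    ModelSpec,
    RateParameter,
    ReactionDef,
    SpeciesDef,
)
from chondrosim.ode import GRID_14D

MATRIX_POOL = 10000.0


def small_model(species, reactions, parameters):
    """Assemble a ModelSpec from bare pieces (test helper)."""
    return ModelSpec(
        name="test_model",
        version="1",
        compartments=COMPARTMENTS,
        species=[SpeciesDef(sid, sid, "cytoplasm", init, role)
                 for sid, init, role in species],
        reactions=[ReactionDef(rid, dict(rea), dict(pro), tuple(mod), k)
                   for rid, rea, pro, mod, k in reactions],
        parameters=[RateParameter(pid, val, units) for pid, val, units in parameters],
    )


@pytest.fixture(scope="session")
def model():
    return build_integrated_model()


@pytest.fixture(scope="session")
def runs(model):
    """Shared baseline simulations, computed once per session."""
    out = {
        "il1_48h": simulate_ode(model, make_treatment(model, True, False, False), 48.0),
        "osm_48h": simulate_ode(model, make_treatment(model, False, True, False), 48.0),
        "both_48h": simulate_ode(model, make_treatment(model, True, True, False), 48.0),
        "both_14d": simulate_ode(
            model, make_treatment(model, True, True, False, horizon_h=336.0),
            336.0, grid_h=GRID_14D),
        "both_act_14d": simulate_ode(
            model, make_treatment(model, True, True, True, horizon_h=336.0),
            336.0, grid_h=GRID_14D),
    }
    return out


@pytest.fixture(scope="session")
def birth_death():
    """Birth-death process: 0 -> A at rate lam, A -> 0 at rate mu."""
    def build(lam=5.0, mu=0.01, a0=0):
        return small_model(
            species=[("A", a0, "protein")],
            reactions=[("birth", {}, {"A": 1}, (), "lam"),
                       ("death", {"A": 1}, {}, (), "mu")],
            parameters=[("lam", lam, "per_second"), ("mu", mu, "per_second")],
        )
    return build


@pytest.fixture(scope="session")
def linear_chain():
    """Linear network 0 -> A -> B -> 0: SSA mean equals the ODE solution."""
    return small_model(
        species=[("A", 0, "protein"), ("B", 0, "protein")],
        reactions=[("src", {}, {"A": 1}, (), "k_in"),
                   ("conv", {"A": 1}, {"B": 1}, (), "k_conv"),
                   ("sink", {"B": 1}, {}, (), "k_out")],
        parameters=[("k_in", 2.0, "per_second"),
                    ("k_conv", 5e-4, "per_second"),
                    ("k_out", 2e-4, "per_second")],
    )


def day14_collagen(tc):
    return float(np.clip(100.0 * tc["CollFrag"][-1] / MATRIX_POOL, 0, 100))


def day14_aggrecan(tc):
    return float(np.clip(100.0 * tc["AggFrag"][-1] / MATRIX_POOL, 0, 100))
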