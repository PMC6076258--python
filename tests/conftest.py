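import numpy as np
import pytest

from metresponse.gpr import parse_gpr
from metresponse.model import MetabolicModel, Metabolite, Reaction


def make_toy1(uptake_limit: float = 10.0) -> MetabolicModel:
    """Linear chain A_e -> A_c -> B_c -> B_e with uptake of A capped.

    Five reactions, four metabolites, one gene-gated conversion (R1).
    Producing B at rate f forces |v| = f on every reaction, so the
    weighted production cost is f times the weight sum — hand-checkable.
    """
    return MetabolicModel(
        metabolites=[
            Metabolite("A_e", name="A", compartment="e"),
            Metabolite("A_c", name="A", compartment="c"),
            Metabolite("B_c", name="B", compartment="c"),
            Metabolite("B_e", name="B", compartment="e"),
        ],
        reactions=[
            Reaction("EX_A", {"A_e": -1.0}, lb=-uptake_limit, ub=0.0, is_exchange=True),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, lb=0.0, ub=1000.0),
            Reaction(
                "R1",
                {"A_c": -1.0, "B_c": 1.0},
                lb=0.0,
                ub=1000.0,
                gpr=parse_gpr("g1"),
            ),
            Reaction("T_B", {"B_c": -1.0, "B_e": 1.0}, lb=0.0, ub=1000.0),
            Reaction("EX_B", {"B_e": -1.0}, lb=0.0, ub=1000.0, is_exchange=True),
        ],
        genes=["g1"],
        id="TOY1",
    )


def make_toy_parallel(uptake_limit: float = 10.0) -> MetabolicModel:
    """TOY1 plus a second, independent route A_c -> C_c -> C_e.

    Gives two competing products so directional scoring has a population
    to z-transform over.
    """
    base = make_toy1(uptake_limit)
    metabolites = base.metabolites + [
        Metabolite("C_c", name="C", compartment="c"),
        Metabolite("C_e", name="C", compartment="e"),
    ]
    reactions = base.reactions + [
        Reaction(
            "R2", {"A_c": -1.0, "C_c": 1.0}, lb=0.0, ub=1000.0, gpr=parse_gpr("g2")
        ),
        Reaction("T_C", {"C_c": -1.0, "C_e": 1.0}, lb=0.0, ub=1000.0),
        Reaction("EX_C", {"C_e": -1.0}, lb=0.0, ub=1000.0, is_exchange=True),
    ]
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=["g1", "g2"],
        id="TOY1_parallel",
    )


@pytest.fixture
def toy1() -> MetabolicModel:
    return make_toy1()


@pytest.fixture
def toy_parallel() -> MetabolicModel:
    return make_toy_parallel()


@pytest.fixture
def uniform_weights5() -> np.ndarray:
    return np.ones(5)
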