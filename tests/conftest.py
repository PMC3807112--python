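import numpy as np
import pytest
from cobra.core.gene import GPR

from subflux.model import MetabolicModel, Metabolite, Reaction
from subflux.energetics import load_fa_cycle
from subflux.synth import make_scenario


def simple_model(reactions: dict[str, dict[str, float]], boundary=(), reversible=(),
                 gprs: dict[str, str] | None = None) -> MetabolicModel:
    """Build a model from {reaction_id: {metabolite_id: coef}} shorthand."""
    mets = {}
    for stoich in reactions.values():
        for mid in stoich:
            mets.setdefault(
                mid,
                Metabolite(mid, "b" if mid in boundary else "c",
                           is_boundary=mid in boundary),
            )
    gprs = gprs or {}
    rxns = [
        Reaction(rid, dict(stoich), reversible=rid in reversible,
                 gpr=GPR.from_string(gprs[rid]) if rid in gprs else None)
        for rid, stoich in reactions.items()
    ]
    return MetabolicModel(list(mets.values()), rxns)


@pytest.fixture
def chain3():
    """{→A, A→B, B→} with A, B internal: one fully coupled class, nullity 1."""
    return simple_model(
        {
            "EX_A": {"x_in": -1, "A": 1},
            "R_AB": {"A": -1, "B": 1},
            "EX_B": {"B": -1, "x_out": 1},
        },
        boundary={"x_in", "x_out"},
    )


@pytest.fixture
def dead_end():
    """{A→B} with no exchanges: full column rank, the reaction is blocked."""
    return simple_model({"R1": {"A": -1, "B": 1}})


@pytest.fixture
def diamond():
    """→A; A→B twice in parallel; B→: branches uncoupled, exchanges coupled."""
    return simple_model(
        {
            "EX_A": {"x_in": -1, "A": 1},
            "R2": {"A": -1, "B": 1},
            "R3": {"A": -1, "B": 1},
            "EX_B": {"B": -1, "x_out": 1},
        },
        boundary={"x_in", "x_out"},
    )


@pytest.fixture
def chain4_embedded():
    """4-reaction series A→B→C→D→E embedded so B, C, D occur nowhere else;
    A and E also feed side reactions."""
    return simple_model(
        {
            "EX_A": {"x1": -1, "A": 1},
            "S1": {"A": -1, "B": 1},
            "S2": {"B": -1, "C": 1},
            "S3": {"C": -1, "D": 1},
            "S4": {"D": -1, "E": 1},
            "EX_E": {"E": -1, "x2": 1},
            "SIDE_A": {"A": -1, "x3": 1},
            "SIDE_E": {"x4": -1, "E": 1},
        },
        boundary={"x1", "x2", "x3", "x4"},
    )


@pytest.fixture(scope="session")
def fa_cycle():
    return load_fa_cycle()


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic benchmark (seeded, reused across tests)."""
    return make_scenario(seed=7)
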