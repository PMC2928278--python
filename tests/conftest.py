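import numpy as np
import pytest

from warburg import build_cancer_core_network, equimolar_objective
from warburg.fba import LinearProblem

FIG3_TARGETS = [
    "ENO", "GAPD", "PGMT", "PYK", "TPI", "LDH", "RPI",
    "PDHm", "AKGDm", "CSm", "FUMm", "MDHm", "SUCD1m", "SUCOAS",
]


@pytest.fixture(scope="session")
def core_net():
    return build_cancer_core_network()


@pytest.fixture(scope="session")
def core_objective(core_net):
    return equimolar_objective(core_net)


@pytest.fixture(scope="session")
def core_lp(core_net):
    return LinearProblem(core_net)


def random_toy_network(rng: np.random.Generator):
    """A random small connected network for round-trip property tests."""
    from warburg.network import MetabolicNetwork, Metabolite, Reaction

    n_mets = rng.integers(2, 6)
    comps = rng.choice(["e", "c", "m"], size=n_mets)
    mets = [
        Metabolite(id=f"m{i}[{c}]", name=f"met{i}", compartment=str(c))
        for i, c in enumerate(comps)
    ]
    rxns = [
        Reaction(
            id="SRC", stoich={mets[0].id: 1.0}, lower_bound=0,
            upper_bound=float(rng.integers(1, 20)), kind="demand",
        )
    ]
    n_rxns = rng.integers(1, 6)
    for j in range(n_rxns):
        a, b = rng.choice(n_mets, size=2, replace=False)
        coeff = float(rng.integers(1, 4))
        rev = bool(rng.random() < 0.4)
        rxns.append(
            Reaction(
                id=f"R{j}",
                stoich={mets[a].id: -coeff, mets[b].id: 1.0},
                lower_bound=-100.0 if rev else 0.0,
                upper_bound=100.0,
                kind="internal",
            )
        )
    rxns.append(
        Reaction(
            id="SNK", stoich={mets[-1].id: -1.0}, lower_bound=0,
            upper_bound=1000.0, kind="sink",
        )
    )
    return MetabolicNetwork(mets, rxns, name="random_toy")
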