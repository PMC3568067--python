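import numpy as np
import pytest

from cardiocore import coregen


@pytest.fixture(scope="session")
def core_network():
    return coregen.build_core_network()


@pytest.fixture(scope="session")
def core_problem(core_network):
    return coregen.core_flux_problem(core_network)


@pytest.fixture(scope="session")
def full_network():
    """Core network with glycogen, lipid targets and NADPH enabled."""
    opts = coregen.CoreOptions(
        include_glycogen=True, include_lipid_targets=True, include_nadph=True
    )
    return coregen.build_core_network(options=opts), opts


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def to_cobra(network):
    """Convert a MetabolicNetwork to a cobra.Model (independent cross-checks)."""
    import cobra

    model = cobra.Model("xcheck")
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
            for m in network.metabolites}
    rxns = []
    for r in network.reactions:
        rx = cobra.Reaction(r.id)
        rx.bounds = (r.lower_bound, r.upper_bound)
        rxns.append(rx)
    model.add_reactions(rxns)
    for r in network.reactions:
        model.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: coef for mid, coef in r.stoichiometry.items()}
        )
    return model
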