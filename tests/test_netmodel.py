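"""Network container, stoichiometric matrix, I/O and structural diagnostics."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiocore import netmodel
from cardiocore.netmodel import (
    MetabolicNetwork,
    Metabolite,
    NetworkStructureError,
    Reaction,
    build_stoich_matrix,
    find_blocked_reactions,
    find_deadend_metabolites,
    read_native,
    read_sbml,
    write_native,
)

from conftest import to_cobra


def chain_network(open_secretion=True):
    """A -> B -> C with A uptake and (optionally) C secretion."""
    mets = [Metabolite(x) for x in "ABC"]
    rxns = [
        Reaction("EX_A", {"A": 1.0}, is_exchange=True, allowed_secretion=False),
        Reaction("R_AB", {"A": -1.0, "B": 1.0}),
        Reaction("R_BC", {"B": -1.0, "C": 1.0}),
    ]
    if open_secretion:
        rxns.append(Reaction("EX_C", {"C": -1.0}, is_exchange=True, allowed_uptake=False))
    return MetabolicNetwork(metabolites=mets, reactions=rxns)


class TestStoichMatrix:
    def test_single_conversion(self):
        net = MetabolicNetwork(
            metabolites=[Metabolite("A"), Metabolite("B")],
            reactions=[Reaction("R", {"A": -1.0, "B": 1.0})],
        )
        assert build_stoich_matrix(net).tolist() == [[-1.0], [1.0]]

    def test_empty_network(self):
        assert build_stoich_matrix(MetabolicNetwork()).shape == (0, 0)

    def test_column_count_matches_generator(self, core_network):
        N = build_stoich_matrix(core_network)
        # independent count over the generator's declared reactions
        assert N.shape[1] == len(core_network.reactions)
        assert N.shape[0] == len(core_network.metabolites)

    def test_unresolved_metabolite_errors_with_reaction_name(self):
        net = MetabolicNetwork(
            metabolites=[Metabolite("A")],
            reactions=[Reaction("BAD", {"A": -1.0, "ghost": 1.0})],
        )
        with pytest.raises(NetworkStructureError, match="BAD"):
            build_stoich_matrix(net)


class TestInvariants:
    def test_duplicate_reaction_ids_rejected(self):
        net = chain_network()
        net.reactions.append(Reaction("EX_A", {"A": 1.0}))
        with pytest.raises(NetworkStructureError):
            net.validate()

    def test_bounds_ordering_enforced(self):
        with pytest.raises(NetworkStructureError):
            Reaction("R", {"A": -1.0}, lower_bound=1.0, upper_bound=0.0).validate()

    def test_irreversible_negative_lower_bound_rejected(self):
        with pytest.raises(NetworkStructureError):
            Reaction("R", {"A": -1.0}, reversible=False, lower_bound=-1.0).validate()


class TestNativeIO:
    def test_round_trip_identity(self, core_network, tmp_path):
        p = tmp_path / "core.json"
        write_native(core_network, p)
        back = read_native(p)
        assert back.metabolite_ids() == core_network.metabolite_ids()
        assert back.reaction_ids() == core_network.reaction_ids()
        for a, b in zip(back.reactions, core_network.reactions):
            assert a == b

    def test_two_writes_byte_identical(self, core_network, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_native(core_network, p1)
        write_native(core_network, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_keys_preserved_in_annotations(self, tmp_path):
        obj = netmodel.write_native_obj(chain_network())
        obj["custom_top_level"] = {"x": 1}
        obj["reactions"][0]["custom_field"] = "kept"
        p = tmp_path / "m.json"
        p.write_text(json.dumps(obj))
        net = read_native(p)
        extra = net.annotations["_extra"]
        assert extra["custom_top_level"] == {"x": 1}
        assert any("custom_field" in str(v) for v in extra.values())

    def test_schema_violation_reports_path(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{\"metabolites\": 3}")
        with pytest.raises(NetworkStructureError):
            read_native(p)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=5), st.integers(min_value=1, max_value=6))
    def test_round_trip_generated_networks(self, n_mets, n_rxns):
        rng = np.random.default_rng(n_mets * 7 + n_rxns)
        mets = [Metabolite(f"m{i}") for i in range(n_mets)]
        rxns = []
        for j in range(n_rxns):
            ids = rng.choice(n_mets, size=min(n_mets, 2), replace=False)
            stoich = {f"m{i}": float(rng.integers(-3, 4) or 1) for i in ids}
            rev = bool(rng.integers(0, 2))
            rxns.append(Reaction(f"r{j}", stoich, reversible=rev,
                                 lower_bound=-10.0 if rev else 0.0, upper_bound=10.0))
        net = MetabolicNetwork(metabolites=mets, reactions=rxns)
        assert netmodel.read_native_obj(netmodel.write_native_obj(net)).reactions == net.reactions


class TestSBML:
    def test_reader_on_small_fixture(self, tmp_path):
        import cobra

        m = cobra.Model("tiny")
        a, b, c = (cobra.Metabolite(x, compartment="c") for x in "ABC")
        r1 = cobra.Reaction("R1"); r1.add_metabolites({a: -1, b: 1}); r1.bounds = (0, 1000)
        r2 = cobra.Reaction("R2"); r2.add_metabolites({b: -1, c: 1}); r2.bounds = (-1000, 1000)
        m.add_reactions([r1, r2])
        path = tmp_path / "tiny.xml"
        cobra.io.write_sbml_model(m, str(path))
        net = read_sbml(path)
        assert len(net.metabolites) == 3
        assert len(net.reactions) == 2
        rev = {r.id: r.reversible for r in net.reactions}
        assert rev["R_R1"] is False and rev["R_R2"] is True

    def test_boundary_species_excluded_from_mass_balance(self, tmp_path):
        sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="m">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="c" boundaryCondition="true"/>
   <species id="B" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="R" reversible="false">
    <listOfReactants><speciesReference species="A" stoichiometry="1"/></listOfReactants>
    <listOfProducts><speciesReference species="B" stoichiometry="1"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>"""
        p = tmp_path / "boundary.xml"
        p.write_text(sbml)
        net = read_sbml(p)
        assert net.metabolite_ids() == ["B"]
        assert net.reaction("R").stoichiometry == {"B": 1.0}

    def test_sbml_then_native_round_trip(self, tmp_path):
        import cobra

        m = cobra.Model("rt")
        a, b = cobra.Metabolite("A", compartment="c"), cobra.Metabolite("B", compartment="c")
        r = cobra.Reaction("R"); r.add_metabolites({a: -2, b: 1}); r.bounds = (0, 50)
        m.add_reactions([r])
        xml = tmp_path / "rt.xml"
        cobra.io.write_sbml_model(m, str(xml))
        net = read_sbml(xml)
        j = tmp_path / "rt.json"
        write_native(net, j)
        assert read_native(j).reactions == net.reactions

    def test_malformed_xml_raises(self, tmp_path):
        p = tmp_path / "broken.xml"
        p.write_text("<sbml><unclosed>")
        with pytest.raises(NetworkStructureError):
            read_sbml(p)


class TestBlockedReactions:
    def test_open_chain_not_blocked(self):
        assert find_blocked_reactions(chain_network()) == set()

    def test_dead_end_blocks_chain(self):
        net = chain_network(open_secretion=False)
        blocked = find_blocked_reactions(net)
        assert {"R_AB", "R_BC"} <= blocked

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_independent_fva(self, seed):
        """Blocked set equals cobra's FVA-based detection on random networks."""
        rng = np.random.default_rng(seed)
        n_m, n_r = 4, 10
        mets = [Metabolite(f"m{i}") for i in range(n_m)]
        rxns = [
            Reaction("EX_in", {"m0": 1.0}, is_exchange=True, allowed_secretion=False),
            Reaction("EX_out", {f"m{n_m-1}": -1.0}, is_exchange=True, allowed_uptake=False),
        ]
        for j in range(n_r - 2):
            i1, i2 = rng.choice(n_m, size=2, replace=False)
            rev = bool(rng.integers(0, 2))
            rxns.append(
                Reaction(f"r{j}", {f"m{i1}": -1.0, f"m{i2}": 1.0},
                         reversible=rev, lower_bound=-100.0 if rev else 0.0,
                         upper_bound=100.0)
            )
        net = MetabolicNetwork(metabolites=mets, reactions=rxns)
        ours = find_blocked_reactions(net)
        import cobra.flux_analysis

        theirs = set(cobra.flux_analysis.find_blocked_reactions(to_cobra(net)))
        assert ours == theirs

    def test_infeasible_base_reports_all_blocked(self):
        net = chain_network()
        net.reactions[1].lower_bound = 5.0  # force flux the closed system can't carry
        net.reactions[1].upper_bound = 5.0
        net.reactions[0].upper_bound = 0.0
        blocked = find_blocked_reactions(net, open_exchanges=set())
        assert blocked == set(net.reaction_ids())


class TestDeadEnds:
    def test_unconsumed_product(self):
        net = MetabolicNetwork(
            metabolites=[Metabolite("A"), Metabolite("B")],
            reactions=[Reaction("R", {"A": -1.0, "B": 1.0}),
                       Reaction("EX_A", {"A": 1.0}, is_exchange=True)],
        )
        assert find_deadend_metabolites(net) == {"B"}

    def test_closed_cycle_has_none(self):
        net = MetabolicNetwork(
            metabolites=[Metabolite("A"), Metabolite("B")],
            reactions=[Reaction("R1", {"A": -1.0, "B": 1.0}),
                       Reaction("R2", {"B": -1.0, "A": 1.0})],
        )
        assert find_deadend_metabolites(net) == set()

    def test_core_network_is_closed(self, full_network):
        net, _ = full_network
        assert find_deadend_metabolites(net) == set()
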