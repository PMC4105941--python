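"""Mass-action rate law, RHS assembly, conservation and validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgfsmad import (
    NetworkConfigError,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    Species,
    conserved_moieties,
    conserved_totals,
    mass_action_rate,
)
from tgfsmad.models import TOTAL_SMAD2_NM, TOTAL_SMAD4_NM


def toy_reversible_network(k_on=2.0, k_off=0.7, k_back=0.3):
    """A + B <-> C plus C -> A + B with separate constants."""
    return ReactionNetwork(
        name="toy",
        species=[Species("A", "cytoplasm", 1.0),
                 Species("B", "cytoplasm", 2.0),
                 Species("C", "cytoplasm", 0.0)],
        reactions=[
            Reaction("bind", ("A", "B"), ("C",), "k_on"),
            Reaction("unbind", ("C",), ("A", "B"), "k_off"),
            Reaction("decay", ("C",), ("A", "B"), "k_back"),
        ],
        parameters=ParameterSet({"k_on": k_on, "k_off": k_off,
                                 "k_back": k_back}),
    )


class TestMassActionRate:
    @pytest.mark.parametrize("state,expected", [
        ({"A": 3.0, "B": 4.0}, 24.0),   # bimolecular k=2: 2*3*4
        ({"A": 0.0, "B": 4.0}, 0.0),    # annihilation at zero reactant
    ])
    def test_bimolecular(self, state, expected):
        rxn = Reaction("r", ("A", "B"), ("C",), "k")
        assert mass_action_rate(rxn, state, {"k": 2.0}) == expected

    def test_first_order_degradation(self):
        rxn = Reaction("deg", ("X",), (), "kd")
        assert mass_action_rate(rxn, {"X": 10.0}, {"kd": 0.1}) == \
            pytest.approx(1.0)

    def test_zeroth_order_returns_k(self):
        rxn = Reaction("syn", (), ("X",), "ks")
        assert mass_action_rate(rxn, {}, {"ks": 0.5}) == 0.5

    def test_modifier_multiplies_without_consumption(self):
        rxn = Reaction("cat", ("S",), ("P",), "k", modifiers=("E",))
        rate = mass_action_rate(rxn, {"S": 2.0, "E": 5.0}, {"k": 0.1})
        assert rate == pytest.approx(1.0)

    def test_unknown_species_named_in_error(self):
        rxn = Reaction("r", ("Q",), (), "k")
        with pytest.raises(NetworkConfigError, match="Q"):
            mass_action_rate(rxn, {"X": 1.0}, {"k": 1.0})

    def test_unknown_parameter_named_in_error(self):
        rxn = Reaction("r", ("X",), (), "k_missing")
        with pytest.raises(NetworkConfigError, match="k_missing"):
            mass_action_rate(rxn, {"X": 1.0}, {"k": 1.0})


class TestBuildRhs:
    def test_unimolecular_stoichiometry(self):
        net = ReactionNetwork(
            "ab", [Species("A", "cytoplasm", 1.0), Species("B")],
            [Reaction("conv", ("A",), ("B",), "k")],
            ParameterSet({"k": 1.0}))
        dy = net.build_rhs()(0.0, np.array([1.0, 0.0]))
        assert dy == pytest.approx([-1.0, 1.0])

    def test_closed_network_conserves_mass(self):
        net = toy_reversible_network()
        y = np.array([0.3, 0.9, 0.5])
        dy = net.build_rhs()(0.0, y)
        # moiety weights: A-moiety in A and C; B-moiety in B and C
        assert dy[0] + dy[2] == pytest.approx(0.0, abs=1e-14)
        assert dy[1] + dy[2] == pytest.approx(0.0, abs=1e-14)

    def test_constant_species_pinned(self):
        net = ReactionNetwork(
            "buf", [Species("E", "cytoplasm", 1.0, constant=True),
                    Species("S", "cytoplasm", 1.0)],
            [Reaction("drain", ("E",), (), "k"),
             Reaction("deg", ("S",), (), "k")],
            ParameterSet({"k": 1.0}))
        dy = net.build_rhs()(0.0, np.array([1.0, 1.0]))
        assert dy[0] == 0.0 and dy[1] == pytest.approx(-1.0)

    @given(st.lists(st.floats(min_value=0.0, max_value=50.0),
                    min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None)
    def test_rhs_matches_hand_coded_derivatives(self, state):
        """Oracle: the assembled RHS equals independently hand-written
        ODEs for A + B <-> C, C -> A + B at arbitrary states."""
        k_on, k_off, k_back = 2.0, 0.7, 0.3
        a, b, c = state
        net = toy_reversible_network(k_on, k_off, k_back)
        dy = net.build_rhs()(0.0, np.array(state))
        flux_bind = k_on * a * b
        flux_out = (k_off + k_back) * c
        expected = np.array([flux_out - flux_bind,
                             flux_out - flux_bind,
                             flux_bind - flux_out])
        np.testing.assert_allclose(dy, expected, rtol=1e-14, atol=1e-14)


class TestConservedTotals:
    def test_model1_smad_totals_at_rest(self, model1):
        totals = conserved_totals(model1.network, model1.equilibrated_state,
                                  conserved_moieties(model1.network))
        assert totals["Smad2"] == pytest.approx(TOTAL_SMAD2_NM, rel=1e-6)
        assert totals["Smad4"] == pytest.approx(TOTAL_SMAD4_NM, rel=1e-6)

    def test_homodimer_counts_twice(self, model1):
        state = {n: 0.0 for n in model1.network.species_names}
        state["pS2_pS2_n"] = 10.0
        totals = conserved_totals(model1.network, state,
                                  conserved_moieties(model1.network))
        assert totals["Smad2"] == pytest.approx(20.0)

    def test_unknown_moiety_species_rejected(self, model1):
        with pytest.raises(NetworkConfigError, match="nope"):
            conserved_totals(model1.network, model1.equilibrated_state,
                             {"bad": {"nope": 1.0}})


class TestValidate:
    def test_well_formed_model_has_no_findings(self, model1):
        assert model1.network.validate() == []

    def test_dangling_parameter_reported(self):
        net = ReactionNetwork(
            "bad", [Species("A", "cytoplasm", 1.0)],
            [Reaction("r", ("A",), (), "k_missing")],
            ParameterSet({"k": 1.0}))
        findings = net.validate()
        assert len(findings) == 1 and "k_missing" in findings[0]

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(NetworkConfigError):
            Species("A", "cytoplasm", -1.0)

    def test_duplicate_species_names_rejected(self):
        with pytest.raises(NetworkConfigError, match="duplicate"):
            ReactionNetwork("dup",
                            [Species("A"), Species("A")], [],
                            ParameterSet())


class TestReactionStrings:
    def test_roundtrip(self):
        from tgfsmad.network import reaction_from_string, reaction_to_string
        rxn = reaction_from_string("r", "A + B -> C @ k1 [E]")
        assert rxn.reactants == ("A", "B")
        assert rxn.products == ("C",)
        assert rxn.rate_constant == "k1"
        assert rxn.modifiers == ("E",)
        assert reaction_to_string(rxn) == "A + B -> C @ k1 [E]"

    def test_synthesis_and_degradation_sides(self):
        from tgfsmad.network import reaction_from_string
        syn = reaction_from_string("s", "-> X @ ks")
        assert syn.reactants == () and syn.products == ("X",)
        deg = reaction_from_string("d", "X -> @ kd")
        assert deg.reactants == ("X",) and deg.products == ()

    def test_missing_rate_rejected(self):
        from tgfsmad.network import reaction_from_string
        with pytest.raises(NetworkConfigError, match="missing"):
            reaction_from_string("r", "A -> B")

    def test_every_model_reaction_survives_roundtrip(self, model8):
        from tgfsmad.network import reaction_from_string, reaction_to_string
        for rxn in model8.network.reactions:
            back = reaction_from_string(rxn.name, reaction_to_string(rxn))
            assert back == rxn
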