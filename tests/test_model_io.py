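"""Parsing, serialization, the stoichiometry matrix and flux capability."""

from fractions import Fraction

import numpy as np
import pytest

import leaffba as L
from leaffba.io import ModelSyntaxError, dumps, loads
from leaffba.model import ModelValidationError

SBML_MINI = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="mini">
    <listOfCompartments>
      <compartment id="cyt" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="x_A" compartment="cyt" boundaryCondition="true"
               hasOnlySubstanceUnits="false" constant="false"/>
      <species id="A" compartment="cyt" boundaryCondition="false"
               hasOnlySubstanceUnits="false" constant="false"/>
      <species id="B" compartment="cyt" boundaryCondition="false"
               hasOnlySubstanceUnits="false" constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="T1" reversible="true" fast="false">
        <listOfReactants><speciesReference species="x_A" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="A" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
      <reaction id="R1" reversible="false" fast="false">
        <listOfReactants><speciesReference species="A" stoichiometry="2" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="B" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


class TestReactionListDialect:
    def test_basic_irreversible_parse(self):
        net = loads("R1: A + 2 B -> C")
        rxn = net.reaction("R1")
        assert rxn.stoichiometry == {
            "A": Fraction(-1),
            "B": Fraction(-2),
            "C": Fraction(1),
        }
        assert not rxn.reversible

    def test_external_prefix_marks_transporter(self):
        net = loads("T1: x_CO2 <> CO2")
        rxn = net.reaction("T1")
        assert rxn.reversible
        assert "transporter" in rxn.tags
        assert net.metabolite("x_CO2").is_external
        assert not net.metabolite("CO2").is_external

    def test_compartment_suffixes_and_default(self):
        net = loads("R: A_chl + B_mit -> C")
        assert net.metabolite("A_chl").compartment == "chl"
        assert net.metabolite("B_mit").compartment == "mit"
        assert net.metabolite("C").compartment == "cyt"
        assert net.compartments == {"chl", "mit", "cyt"}

    def test_rational_and_decimal_coefficients(self):
        net = loads("R: 3/2 A + 0.5 B -> C")
        assert net.reaction("R").stoichiometry["A"] == Fraction(-3, 2)
        assert net.reaction("R").stoichiometry["B"] == Fraction(-1, 2)

    @pytest.mark.parametrize(
        "text,lineno",
        [
            ("R1: A -> B\nR2 A -> C", 2),
            ("R1: A => B", 1),
            ("R1: A -> B\nR1: A -> C", 2),
        ],
    )
    def test_syntax_errors_carry_line_numbers(self, text, lineno):
        with pytest.raises(ModelSyntaxError) as exc:
            loads(text)
        assert exc.value.line == lineno

    def test_tag_directive_for_unknown_reaction_rejected(self):
        with pytest.raises(ModelValidationError):
            loads("#@ Nope: maintenance_atpase\nR1: A -> B")

    def test_round_trip_preserves_everything(self, core_model):
        net = core_model.network
        again = loads(dumps(net))
        assert again.reaction_ids == net.reaction_ids
        for rxn in net.reactions:
            other = again.reaction(rxn.id)
            assert other.stoichiometry == rxn.stoichiometry
            assert other.reversible == rxn.reversible
            assert other.tags == rxn.tags


class TestSBML:
    def test_minimal_document(self):
        net = L.load_model(SBML_MINI, format="sbml")
        assert net.metabolite("x_A").is_external
        t1 = net.reaction("T1")
        assert t1.reversible and "transporter" in t1.tags
        assert net.reaction("R1").stoichiometry == {
            "A": Fraction(-2),
            "B": Fraction(1),
        }

    def test_agrees_with_dialect_equivalent(self):
        sb = L.load_model(SBML_MINI, format="sbml")
        spy = loads("T1: x_A <> A\nR1: 2 A -> B")
        M1 = sb.stoichiometric_matrix()
        M2 = spy.stoichiometric_matrix()
        assert np.array_equal(M1, M2)


class TestStoichiometricMatrix:
    def test_single_reaction_column(self):
        net = loads("R: A -> B")
        assert np.array_equal(net.stoichiometric_matrix(), [[-1.0], [1.0]])

    def test_external_metabolites_have_no_row(self):
        net = loads("T: x_A -> A")
        M = net.stoichiometric_matrix()
        assert M.shape == (1, 1) and M[0, 0] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_columns_resum_to_stoichiometry_maps(self, seed):
        net, _ = L.random_branched_network(seed, n_reactions=7)
        M = net.stoichiometric_matrix()
        ids = net.internal_metabolite_ids
        assert all(np.any(M[:, j] != 0) for j in range(M.shape[1]))
        assert M.shape[0] == len(ids)
        for j, rxn in enumerate(net.reactions):
            for i, met_id in enumerate(ids):
                assert M[i, j] == float(rxn.stoichiometry.get(met_id, 0))


class TestFluxCapability:
    def test_dead_branch_excluded(self):
        net = loads(
            "T_in: x_A -> A\nR1: A -> B\nT_out: B -> x_B\nDead: B -> C"
        )
        capable = L.flux_capable_reactions(net, {"T_in"}, {"T_out"})
        assert capable == {"T_in", "R1", "T_out"}

    def test_core_leaf_model_fully_capable(self, core_model):
        from conftest import NUTRIENTS, OUTPUTS

        net = core_model.network
        capable = L.flux_capable_reactions(net, NUTRIENTS, OUTPUTS)
        assert capable == set(net.reaction_ids)

    def test_invariant_under_reordering(self):
        net, _ = L.random_branched_network(3, n_reactions=6)
        capable = L.flux_capable_reactions(net, {"T_in"}, {"T_out"})
        reordered = L.MetabolicNetwork(
            metabolites=list(net.metabolites),
            reactions=list(reversed(net.reactions)),
            compartments=set(net.compartments),
        )
        assert L.flux_capable_reactions(reordered, {"T_in"}, {"T_out"}) == capable

    def test_invariant_under_reversible_split(self):
        net = loads("T_in: x_A -> A\nR1: A <> B\nT_out: B -> x_B")
        cap = L.flux_capable_reactions(net, {"T_in"}, {"T_out"})
        split = loads(
            "T_in: x_A -> A\nR1f: A -> B\nR1b: B -> A\nT_out: B -> x_B"
        )
        cap_split = L.flux_capable_reactions(split, {"T_in"}, {"T_out"})
        assert ("R1" in cap) == ("R1f" in cap_split or "R1b" in cap_split)
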