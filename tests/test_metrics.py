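"""Assimilatory quotient, active counts, compartment exchange, N sources."""

import numpy as np
import pytest

import leaffba as L
from leaffba.fba import FluxSolution, activity_threshold
from leaffba.metrics import UndefinedQuotientError
from leaffba.targets import CompositionTable


@pytest.fixture(scope="module")
def carb_setup(core_model):
    """Pure-carbohydrate (sucrose only) output scenario and its threshold."""
    net = core_model.network
    scn = L.composition_to_fluxes(
        net, CompositionTable({"Suc_tx": 1.0}, label="biomass"), rate=0.5
    )
    c = core_model.constraints(scn)
    t = L.find_min_photon_flux(net, c, 0.0, 1000.0, 1e-8)
    return net, c, t


class TestAssimilationQuotient:
    def test_carbohydrate_output_on_ammonia_is_exactly_one(self, carb_setup):
        # CO2 + H2O -> CH2O + O2: one O2 evolved per CO2 fixed, and both
        # the shuttle-driven mitochondrial ATP route and the dissipation
        # routes are O2-neutral
        net, c, t = carb_setup
        sol = L.minimize_total_flux(net, c.with_photon_flux(t * 1.2))
        assert L.assimilation_quotient(sol) == pytest.approx(1.0, abs=1e-9)

    def test_nitrate_strictly_lowers_aq(self, core_model, scenarios):
        # nitrate reduction demands extra reductant, so extra O2 is evolved
        # per carbon fixed; the drop is larger for the N-richer phloem mix
        net = core_model.network
        drops = {}
        for label, scn in zip(("biomass", "phloem"), scenarios):
            aq = {}
            for nsrc, blocked in (("NH3", ("NO3_tx",)), ("NO3", ("NH3_tx",))):
                c = core_model.constraints(scn, blocked_reactions=blocked)
                t = L.find_min_photon_flux(net, c, 0.0, 2000.0, 1e-8)
                sol = L.minimize_total_flux(net, c.with_photon_flux(t * 1.01))
                aq[nsrc] = L.assimilation_quotient(sol)
            assert aq["NO3"] < aq["NH3"]
            drops[label] = aq["NH3"] - aq["NO3"]
        assert drops["phloem"] > drops["biomass"]

    def test_invariant_under_uniform_rescaling(self, core_model):
        # the LP is homogeneous: scaling output rate and photon flux by the
        # same factor scales fluxes but leaves AQ unchanged
        net = core_model.network
        aqs = []
        for k in (1.0, 3.0):
            scn = L.composition_to_fluxes(net, core_model.biomass, rate=k)
            c = L.LeafConstraints(
                output=scn,
                maintenance_atp=core_model.manifest["maintenance_atp"] * k,
                rubisco_cap=core_model.manifest["rubisco_cap"] * k,
            )
            t = L.find_min_photon_flux(net, c, 0.0, 5000.0, 1e-8)
            sol = L.minimize_total_flux(net, c.with_photon_flux(t * 1.05))
            aqs.append(L.assimilation_quotient(sol))
        assert aqs[0] == pytest.approx(aqs[1], rel=1e-6)

    def test_constant_across_photorespiratory_regions(self, phloem_scan):
        # photorespiratory O2 uptake is balanced by the O2 evolved while
        # refixing the released CO2, so AQ does not move with light
        aqs = [
            L.assimilation_quotient(row[0])
            for row in phloem_scan.solutions
            if row[0].optimal and row[0].net_flux["NO3_tx"] < 1e-9
        ]
        assert len(aqs) >= 3
        assert np.ptp(aqs) <= 1e-9

    def test_zero_o2_release_raises(self, atp_toy):
        net, constraints = atp_toy
        sol = L.minimize_total_flux(net, constraints.with_photon_flux(3.0))
        with pytest.raises((UndefinedQuotientError, KeyError)):
            L.assimilation_quotient(sol)


class TestActiveReactionCount:
    def test_all_zero_solution_counts_nothing(self):
        sol = FluxSolution(
            "optimal", {"R1": 0.0, "R2": 1e-12}, 0.0, photon_flux=1.0, r=0.0
        )
        assert L.active_reaction_count(sol) == 0

    def test_atp_toy_uses_every_reaction_at_threshold(self, atp_toy):
        net, constraints = atp_toy
        sol = L.minimize_total_flux(net, constraints.with_photon_flux(3.0))
        assert L.active_reaction_count(sol) == 4

    def test_phloem_needs_fewer_reactions_than_biomass(
        self, biomass_scan, phloem_scan
    ):
        # the phloem mix is the narrower product spectrum
        nb = [L.active_reaction_count(r[0]) for r in biomass_scan.solutions]
        np_ = [L.active_reaction_count(r[0]) for r in phloem_scan.solutions]
        assert min(np_) < max(nb)
        assert max(np_) <= max(nb)


class TestCompartmentExchange:
    def test_unknown_compartment_rejected(self, biomass_scan, core_model):
        with pytest.raises(KeyError):
            L.compartment_exchange(
                biomass_scan.solutions[0][0], core_model.network, "vac"
            )

    def test_mitochondrial_atp_supplements_low_light_only(
        self, biomass_scan, core_model
    ):
        low = biomass_scan.solutions[0][0]
        high = biomass_scan.solutions[-1][0]
        assert low.net_flux["ComplexV"] > 1.0
        assert abs(high.net_flux["ComplexV"]) <= activity_threshold(high.photon_flux)
        # at high light the chloroplast, not the mitochondrion, exports ATP
        ex_low = L.compartment_exchange(low, core_model.network, "mit")
        assert ex_low.fluxes["ATP_mit"] < 0  # mitochondrion exports ATP
        ex_high = L.compartment_exchange(high, core_model.network, "chl")
        assert ex_high.fluxes["ATP_chl"] < 0  # chloroplast exports ATP

    def test_chloroplast_exports_reductant_at_low_light(
        self, biomass_scan, core_model
    ):
        # the malate valve: malate out, oxaloacetate back
        low = biomass_scan.solutions[0][0]
        ex = L.compartment_exchange(low, core_model.network, "chl")
        assert ex.fluxes["Mal_chl"] < 0
        assert ex.fluxes["OAA_chl"] > 0

    def test_boundary_flux_balances_internal_production(
        self, biomass_scan, core_model
    ):
        # steady state restricted to one compartment: what crosses the
        # boundary equals what internal reactions net-produce
        net = core_model.network
        sol = biomass_scan.solutions[10][0]
        for comp in ("chl", "mit"):
            ex = L.compartment_exchange(sol, net, comp)
            for met_id, imported in ex.fluxes.items():
                internal = 0.0
                for rxn in net.reactions:
                    comps = {net.metabolite(m).compartment for m in rxn.stoichiometry}
                    if comps == {comp} and met_id in rxn.stoichiometry:
                        internal += float(rxn.stoichiometry[met_id]) * sol.net_flux[
                            rxn.id
                        ]
                assert imported + internal == pytest.approx(0.0, abs=1e-8)


class TestNitrogenSourceShares:
    def test_ammonia_only_at_minimal_light(self, biomass_scan):
        nh3, no3 = L.nitrogen_source_shares(biomass_scan.solutions[0][0])
        assert nh3 == pytest.approx(1.0, abs=1e-6)
        assert no3 == pytest.approx(0.0, abs=1e-6)

    def test_nitrate_only_at_high_light(self, biomass_scan):
        nh3, no3 = L.nitrogen_source_shares(biomass_scan.solutions[-1][0])
        assert no3 == pytest.approx(1.0, abs=1e-6)

    def test_shares_sum_to_one_along_scan(self, phloem_scan):
        for row in phloem_scan.solutions:
            if row[0].optimal:
                nh3, no3 = L.nitrogen_source_shares(row[0])
                assert nh3 + no3 == pytest.approx(1.0, abs=1e-9)

    def test_zero_uptake_raises(self, carb_setup):
        net, c, t = carb_setup  # carbohydrate output needs no nitrogen
        sol = L.minimize_total_flux(net, c.with_photon_flux(t * 1.05))
        with pytest.raises(ZeroDivisionError):
            L.nitrogen_source_shares(sol)
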