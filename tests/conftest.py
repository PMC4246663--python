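"""Shared fixtures: the core-leaf model, its scenarios, and cached scans.

Scan fixtures are session-scoped because each grid cell is an LP solve;
tests share one biomass slice, one phloem slice and one 2-D grid.
"""

import numpy as np
import pytest

import leaffba as L

NUTRIENTS = ["Photon_tx", "CO2_tx", "O2_tx", "H2O_tx", "NH3_tx", "NO3_tx"]
OUTPUTS = ["CellWall_tx", "Starch_tx", "Suc_tx", "AA_tx"]

#: 4-reaction energy toy: photons convert 1:1 to ATP, the exported product
#: costs 2 ATP per unit, maintenance burns 1 ATP.  With unit export the
#: analytic minimal photon flux is 2*1 + 1 = 3.
ATP_TOY = """
#@ Photon_tx: photon_import
Photon_tx: x_Photon -> Ph
ATPSyn: Ph -> ATP
#@ Out_tx: output_transporter
Out_tx: 2 ATP -> x_Out
#@ NGAM: maintenance_atpase
NGAM: ATP ->
"""


@pytest.fixture(scope="session")
def atp_toy():
    net = L.loads(ATP_TOY)
    constraints = L.LeafConstraints(
        output=L.OutputScenario(fixed_fluxes={"Out_tx": 1.0}),
        maintenance_atp=1.0,
    )
    return net, constraints


@pytest.fixture(scope="session")
def core_model():
    return L.build_core_leaf_model()


@pytest.fixture(scope="session")
def scenarios(core_model):
    """(biomass, equal-carbon-scaled phloem) at the manifest output rate."""
    return core_model.scenarios()


@pytest.fixture(scope="session")
def thresholds(core_model, scenarios):
    """Bisection minimal photon fluxes {'biomass': .., 'phloem': ..}."""
    b, p = scenarios
    net = core_model.network
    return {
        "biomass": L.find_min_photon_flux(
            net, core_model.constraints(b), 0.0, 1000.0, 1e-8
        ),
        "phloem": L.find_min_photon_flux(
            net, core_model.constraints(p), 0.0, 1000.0, 1e-8
        ),
    }


def _light_grid(threshold):
    return np.geomspace(threshold * 1.0005, threshold * 4.0, 48)


@pytest.fixture(scope="session")
def biomass_scan(core_model, scenarios, thresholds):
    b, _ = scenarios
    return L.scan_light(
        core_model.network, core_model.constraints(b), _light_grid(thresholds["biomass"])
    )


@pytest.fixture(scope="session")
def phloem_scan(core_model, scenarios, thresholds):
    _, p = scenarios
    return L.scan_light(
        core_model.network, core_model.constraints(p), _light_grid(thresholds["phloem"])
    )


@pytest.fixture(scope="session")
def grid_scan(core_model, scenarios, thresholds):
    """2-D light x phloem-fraction scan, 24 x 11 cells, all feasible."""
    b, p = scenarios
    grid = np.geomspace(thresholds["biomass"] * 1.001, thresholds["biomass"] * 4, 24)
    r_values = [k / 10 for k in range(11)]
    return L.scan_2d(
        core_model.network, core_model.constraints(b), grid, r_values, b, p
    )
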