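"""Synthetic models: a parameterized core-leaf cell and random small nets.

The core-leaf model is a ~43-reaction, three-compartment (cytosol /
chloroplast / mitochondrion) network with lumped pathways — one pseudo-
reaction each for non-cyclic and cyclic photophosphorylation, the Calvin
cycle (rubisco carboxylase), photorespiration (rubisco oxygenase plus
salvage), glycolysis, pyruvate oxidation (PDH + TCA), mitochondrial
oxidative phosphorylation (complex V) and the alternative oxidase, a
malate-oxaloacetate shuttle, starch and sucrose synthesis, ammonia and
nitrate assimilation (nitrate needing extra reductant), a maintenance
ATPase, and export transporters for a biomass-like and a phloem-like
output mix (the phloem mix has the higher N:C ratio).  Lumping keeps the
energy/redox trade-offs that drive the light-scan phenotypes while staying
small enough for exact oracles.

Carbon species are carried in single-carbon carbohydrate units (CH2O);
cofactors (ATP, NADPH, NADH) are element-free bookkeeping species, and
reactions balance C, N and O (hydrogen and phosphate are not tracked).

The builder also computes, in closed form, the minimal photon flux at
which each pure output scenario becomes feasible (the light-threshold
manifest), independently of any LP solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction as F

import numpy as np

from .exact import brute_force_min_flux
from .fba import FluxSolution, LeafConstraints
from .io import apply_element_table, loads
from .model import MetabolicNetwork, Metabolite, Reaction, elemental_imbalances
from .targets import (
    CompositionTable,
    OutputScenario,
    composition_to_fluxes,
    scale_to_equal_carbon,
)

#: C, N, O atom counts per (bare) species; compartment and external
#: variants inherit these.  Cofactors and photons carry no elements.
ELEMENT_TABLE: dict[str, dict[str, int]] = {
    "Photon": {"carbon": 0, "nitrogen": 0, "oxygen": 0},
    "CO2": {"carbon": 1, "nitrogen": 0, "oxygen": 2},
    "O2": {"carbon": 0, "nitrogen": 0, "oxygen": 2},
    "H2O": {"carbon": 0, "nitrogen": 0, "oxygen": 1},
    "NH3": {"carbon": 0, "nitrogen": 1, "oxygen": 0},
    "NO3": {"carbon": 0, "nitrogen": 1, "oxygen": 3},
    "ATP": {"carbon": 0, "nitrogen": 0, "oxygen": 0},
    "NADPH": {"carbon": 0, "nitrogen": 0, "oxygen": 0},
    "NADH": {"carbon": 0, "nitrogen": 0, "oxygen": 0},
    "CH2O": {"carbon": 1, "nitrogen": 0, "oxygen": 1},
    "Starch": {"carbon": 6, "nitrogen": 0, "oxygen": 5},
    "CellWall": {"carbon": 6, "nitrogen": 0, "oxygen": 5},
    "Suc": {"carbon": 12, "nitrogen": 0, "oxygen": 11},
    "Pyr": {"carbon": 3, "nitrogen": 0, "oxygen": 3},
    "AA": {"carbon": 3, "nitrogen": 1, "oxygen": 2},
    "Mal": {"carbon": 4, "nitrogen": 0, "oxygen": 5},
    "OAA": {"carbon": 4, "nitrogen": 0, "oxygen": 5},
}


@dataclass(frozen=True)
class CoreLeafParams:
    """Stoichiometric/energetic parameters of the core-leaf model.

    Energy units are "per reaction turnover" in the lumped stoichiometry;
    light is in photon-flux model units.  Defaults follow textbook
    photosynthetic stoichiometry (8 photons per 2 NADPH + 3 ATP non-cyclic,
    2 photons per cyclic ATP, 3 ATP + 2 NADPH per CO2 fixed, 8 electrons =
    4 NADPH per nitrate reduced, P/O-equivalent 2.5 ATP per mitochondrial
    NADH) and are chosen so that the full ladder of light regimes —
    mitochondrial ATP support, its replacement by chloroplast ATP export,
    nitrate substitution, photorespiration, and substrate-cycle dissipation
    at the Calvin-cycle cap — unfolds within roughly a 100-fold light
    range above the feasibility threshold.
    """

    photons_per_nadph_noncyclic: F = F(4)
    atp_per_nadph_noncyclic: F = F(3, 2)
    photons_per_atp_cyclic: F = F(2)
    nadph_per_co2_calvin: F = F(2)
    atp_per_co2_calvin: F = F(3)
    oxygenase_atp_cost: F = F(1)
    nadph_per_no3: F = F(4)
    atp_per_mito_nadh: F = F(5, 2)
    atp_per_pyruvate_oxidation: F = F(1)
    nadh_per_pyruvate_oxidation: F = F(5)
    atp_per_starch: F = F(1)
    atp_per_sucrose: F = F(2)
    atp_per_cellwall: F = F(2)
    atp_per_aa: F = F(1)
    maintenance_atp: F = F(20)
    rubisco_cap: F = F(12)
    output_rate: F = F(1)
    biomass_composition: dict[str, float] = field(
        default_factory=lambda: {
            "CellWall_tx": 0.4,
            "Starch_tx": 0.3,
            "Suc_tx": 0.1,
            "AA_tx": 0.3,
        }
    )
    phloem_composition: dict[str, float] = field(
        default_factory=lambda: {"Suc_tx": 1.0, "AA_tx": 0.9}
    )


@dataclass
class CoreLeafModel:
    """Bundle the builder returns: network, the two composition tables,
    and a manifest of parameters plus analytic minimal-light thresholds."""

    network: MetabolicNetwork
    biomass: CompositionTable
    phloem: CompositionTable
    manifest: dict

    def __iter__(self):  # allow (net, biomass, phloem) unpacking
        return iter((self.network, self.biomass, self.phloem))

    def scenarios(self) -> tuple[OutputScenario, OutputScenario]:
        """(biomass, equal-carbon-scaled phloem) at the manifest rate."""
        rate = self.manifest["output_rate"]
        b = composition_to_fluxes(self.network, self.biomass, rate)
        p = composition_to_fluxes(self.network, self.phloem, rate)
        return b, scale_to_equal_carbon(p, b)

    def constraints(self, output: OutputScenario, **overrides) -> LeafConstraints:
        kw = dict(
            output=output,
            rubisco_cap=self.manifest["rubisco_cap"],
            maintenance_atp=self.manifest["maintenance_atp"],
        )
        kw.update(overrides)
        return LeafConstraints(**kw)


def _model_text(p: CoreLeafParams) -> str:
    """The core-leaf model in the reaction-list dialect."""
    pn = 2 * p.photons_per_nadph_noncyclic  # photons per O2 evolved
    an = 2 * p.atp_per_nadph_noncyclic
    return f"""
# --- exchange ---
#@ Photon_tx: photon_import
Photon_tx: x_Photon -> Photon_chl
CO2_tx: x_CO2 <> CO2_cyt
O2_tx: x_O2 <> O2_cyt
H2O_tx: x_H2O <> H2O_cyt
NH3_tx: x_NH3 -> NH3_cyt
NO3_tx: x_NO3 -> NO3_chl
# --- output transporters ---
#@ CellWall_tx: output_transporter
CellWall_tx: CellWall_cyt -> x_CellWall
#@ Starch_tx: output_transporter
Starch_tx: Starch_chl -> x_Starch
#@ Suc_tx: output_transporter
Suc_tx: Suc_cyt -> x_Suc
#@ AA_tx: output_transporter
AA_tx: AA_cyt -> x_AA
# --- intracellular transport ---
CO2_chl_tx: CO2_cyt <> CO2_chl
CO2_mit_tx: CO2_cyt <> CO2_mit
O2_chl_tx: O2_chl <> O2_cyt
O2_mit_tx: O2_cyt <> O2_mit
H2O_chl_tx: H2O_cyt <> H2O_chl
H2O_mit_tx: H2O_cyt <> H2O_mit
TP_tx: CH2O_chl <> CH2O_cyt
Mal_chl_tx: Mal_chl <> Mal_cyt
OAA_chl_tx: OAA_cyt <> OAA_chl
Mal_mit_tx: Mal_cyt <> Mal_mit
OAA_mit_tx: OAA_mit <> OAA_cyt
Pyr_mit_tx: Pyr_cyt -> Pyr_mit
ATP_chl_tx: ATP_chl -> ATP_cyt
ATP_mit_tx: ATP_mit -> ATP_cyt
NH3_chl_tx: NH3_chl -> NH3_cyt
# --- chloroplast ---
#@ NonCyclic: noncyclic_photophos
NonCyclic: {pn} Photon_chl + 2 H2O_chl -> O2_chl + 2 NADPH_chl + {an} ATP_chl
#@ Cyclic: cyclic_photophos
Cyclic: {p.photons_per_atp_cyclic} Photon_chl -> ATP_chl
#@ RubiscoCarb: rubisco_carboxylase
RubiscoCarb: CO2_chl + {p.nadph_per_co2_calvin} NADPH_chl + {p.atp_per_co2_calvin} ATP_chl -> CH2O_chl + H2O_chl
#@ RubiscoOx: rubisco_oxygenase
RubiscoOx: CH2O_chl + O2_chl + {p.oxygenase_atp_cost} ATP_chl -> CO2_chl + H2O_chl
StarchSyn: 6 CH2O_chl + {p.atp_per_starch} ATP_chl -> Starch_chl + H2O_chl
StarchDeg: Starch_chl + H2O_chl -> 6 CH2O_chl
MDH_chl: OAA_chl + NADPH_chl -> Mal_chl
NitrateRed: NO3_chl + {p.nadph_per_no3} NADPH_chl -> NH3_chl + 3 H2O_chl
# --- cytosol ---
Glycolysis: 3 CH2O_cyt -> Pyr_cyt + NADH_cyt + ATP_cyt
SucSyn: 12 CH2O_cyt + {p.atp_per_sucrose} ATP_cyt -> Suc_cyt + H2O_cyt
CellWallSyn: 6 CH2O_cyt + {p.atp_per_cellwall} ATP_cyt -> CellWall_cyt + H2O_cyt
AASyn: Pyr_cyt + NH3_cyt + NADH_cyt + {p.atp_per_aa} ATP_cyt -> AA_cyt + H2O_cyt
MDH_cyt: Mal_cyt <> OAA_cyt + NADH_cyt
#@ Maintenance: maintenance_atpase
Maintenance: ATP_cyt ->
# --- mitochondrion ---
MDH_mit: Mal_mit -> OAA_mit + NADH_mit
PyrOxTCA: Pyr_mit + 3 H2O_mit -> 3 CO2_mit + {p.nadh_per_pyruvate_oxidation} NADH_mit + {p.atp_per_pyruvate_oxidation} ATP_mit
ComplexV: NADH_mit + 1/2 O2_mit -> {p.atp_per_mito_nadh} ATP_mit + H2O_mit
#@ AOX: dissipation
AOX: NADH_mit + 1/2 O2_mit -> H2O_mit
"""


def build_core_leaf_model(params: CoreLeafParams | None = None) -> CoreLeafModel:
    """Build and audit the core-leaf model.

    Raises ``ValueError`` naming the offending reaction if a parameter
    combination breaks the C/N/O balance.
    """
    p = params or CoreLeafParams()
    net = loads(_model_text(p))
    apply_element_table(net, ELEMENT_TABLE)
    bad = elemental_imbalances(net)
    if bad:
        rxn, imb = next(iter(bad.items()))
        raise ValueError(f"core-leaf model unbalanced: reaction {rxn} off by {imb}")
    biomass = CompositionTable(entries=p.biomass_composition, label="biomass")
    phloem = CompositionTable(entries=p.phloem_composition, label="phloem")
    _check_nc_ordering(net, biomass, phloem)
    manifest = {
        "params": {
            k: float(getattr(p, k))
            for k in (
                "photons_per_nadph_noncyclic",
                "atp_per_nadph_noncyclic",
                "photons_per_atp_cyclic",
                "nadph_per_co2_calvin",
                "atp_per_co2_calvin",
                "oxygenase_atp_cost",
                "nadph_per_no3",
                "atp_per_mito_nadh",
            )
        },
        "maintenance_atp": float(p.maintenance_atp),
        "rubisco_cap": float(p.rubisco_cap),
        "output_rate": float(p.output_rate),
        "min_photon_flux": {},
    }
    model = CoreLeafModel(network=net, biomass=biomass, phloem=phloem, manifest=manifest)
    b_scn, p_scn = model.scenarios()
    manifest["min_photon_flux"] = {
        "biomass": analytic_min_photon_flux(p, b_scn.fixed_fluxes),
        "phloem": analytic_min_photon_flux(p, p_scn.fixed_fluxes),
    }
    return model


def _check_nc_ordering(
    net: MetabolicNetwork, biomass: CompositionTable, phloem: CompositionTable
) -> None:
    def nc(table: CompositionTable) -> tuple[float, float]:
        n = c = 0.0
        for rxn_id, rel in table.entries.items():
            for met_id, coef in net.reaction(rxn_id).stoichiometry.items():
                met = net.metabolite(met_id)
                if met.is_external and coef > 0:
                    c += rel * float(coef) * (met.carbon_atoms or 0)
                    n += rel * float(coef) * (met.nitrogen_atoms or 0)
        return n, c

    nb, cb = nc(biomass)
    np_, cp = nc(phloem)
    if not np_ / cp > nb / cb:
        raise ValueError("phloem composition must have higher N:C than biomass")


def analytic_min_photon_flux(
    p: CoreLeafParams, fixed_fluxes: dict[str, float]
) -> float:
    """Closed-form minimal photon flux for a pure output scenario (ammonia
    N source available).

    Reasoning, independent of any LP: every output carbon transits the
    Calvin lump exactly once, costing ``photons_per_nadph * nadph_per_co2``
    photons per carbon (non-cyclic ATP exactly covers Calvin ATP when
    ``atp_per_nadph * nadph_per_co2 == atp_per_co2``; any surplus/deficit
    is folded into the ATP demand).  ATP beyond that comes from the
    cheapest photon source: either cyclic photophosphorylation
    (``photons_per_atp_cyclic`` per ATP) or the "bundle" of diverting one
    NADPH through the malate shuttle to mitochondrial oxidation, which
    yields ``atp_per_mito_nadh + atp_per_nadph_noncyclic`` ATP per
    ``photons_per_nadph`` photons.  The amino-acid NADH demand is met
    exactly by the glycolysis byproduct, and its ATP cost nets against the
    glycolytic ATP.  Only the regime where the bundle is the cheaper
    source and chloroplast-located demand fits the bundle's chloroplast
    share is supported (asserted), which holds for the default parameters.
    """
    f = {k: F(v).limit_denominator(10**9) for k, v in fixed_fluxes.items()}
    carbons = {
        "CellWall_tx": F(6),
        "Starch_tx": F(6),
        "Suc_tx": F(12),
        "AA_tx": F(3),
    }
    ch2o = sum(carbons[k] * v for k, v in f.items())
    # location-resolved extra ATP demand
    d_chl = p.atp_per_starch * f.get("Starch_tx", F(0))
    d_cyt = (
        p.atp_per_cellwall * f.get("CellWall_tx", F(0))
        + p.atp_per_sucrose * f.get("Suc_tx", F(0))
        + (p.atp_per_aa - 1) * f.get("AA_tx", F(0))  # glycolysis ATP credit
        + p.maintenance_atp
    )
    surplus_per_c = (
        p.atp_per_nadph_noncyclic * p.nadph_per_co2_calvin - p.atp_per_co2_calvin
    )
    d_chl -= surplus_per_c * ch2o
    if d_chl < 0:  # chloroplast surplus spills over to the cytosol
        d_cyt += d_chl
        d_chl = F(0)
    if d_cyt < 0:
        raise ValueError("net ATP surplus at zero light: threshold undefined")
    bundle_atp = p.atp_per_mito_nadh + p.atp_per_nadph_noncyclic
    bundle_cost = p.photons_per_nadph_noncyclic / bundle_atp
    if bundle_cost > p.photons_per_atp_cyclic:
        raise ValueError("cyclic-dominant regime not supported by the closed form")
    s = (d_chl + d_cyt) / bundle_atp  # NADPH diverted to the shuttle
    if p.atp_per_nadph_noncyclic * s < d_chl:
        raise ValueError("chloroplast ATP demand exceeds the bundle share")
    photons = (
        p.photons_per_nadph_noncyclic * p.nadph_per_co2_calvin * ch2o
        + p.photons_per_nadph_noncyclic * s
    )
    return float(photons)


# -- random small networks with enumeration oracles ----------------------


def random_branched_network(
    seed: int, n_reactions: int = 6
) -> tuple[MetabolicNetwork, FluxSolution]:
    """A seeded random nutrient-to-product network (<= 8 reactions) with a
    known-by-enumeration minimal-total-flux solution attached.

    Topology: a linear backbone of internal metabolites from an uptake
    transporter to an export transporter, plus random shortcut/branch
    edges, random small integer coefficients and random reversibility.
    The attached oracle fixes the export flux at 1 and enumerates vertices
    exactly; deterministic in ``seed``.
    """
    if not 3 <= n_reactions <= 8:
        raise ValueError("n_reactions must be in [3, 8]")
    rng = np.random.default_rng(seed)
    n_int = int(rng.integers(2, min(4, n_reactions - 1) + 1))
    mets = [f"M{i}" for i in range(n_int)]
    lines = [f"T_in: x_S -> {mets[0]}"]
    for i in range(n_int - 1):
        arrow = "<>" if rng.random() < 0.3 else "->"
        coef = int(rng.integers(1, 3))
        rhs = f"{coef} {mets[i + 1]}" if coef != 1 else mets[i + 1]
        lines.append(f"R{i}: {mets[i]} {arrow} {rhs}")
    lines.append(f"T_out: {mets[-1]} -> x_P")
    extra = n_reactions - len(lines)
    for e in range(extra):
        i = int(rng.integers(0, n_int - 1))
        j = int(rng.integers(i + 1, n_int))
        coef = int(rng.integers(1, 3))
        rhs = f"{coef} {mets[j]}" if coef != 1 else mets[j]
        arrow = "<>" if rng.random() < 0.3 else "->"
        lines.append(f"S{e}: {mets[i]} {arrow} {rhs}")
    net = loads("\n".join(lines))
    constraints = LeafConstraints(
        output=OutputScenario(fixed_fluxes={"T_out": 1.0}, label="unit export")
    )
    oracle = brute_force_min_flux(net, constraints)
    return net, oracle


def unit_export_constraints() -> LeafConstraints:
    """The constraint set the random-network oracle was solved under."""
    return LeafConstraints(
        output=OutputScenario(fixed_fluxes={"T_out": 1.0}, label="unit export")
    )
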