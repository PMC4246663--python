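"""Derived physiology of a flux solution.

* Assimilatory Quotient (AQ): net CO2 fixed per net O2 released, both
  measured at the cell boundary (internal refixation of respiratory or
  photorespiratory CO2 cancels at the boundary, which keeps the quantity
  well-defined under degenerate optima).
* Active-reaction counts (same activity threshold as region detection).
* Compartment exchange fluxes (import-positive sign convention).
* Nitrogen-source shares (ammonia vs nitrate fraction of N uptake).
"""

from __future__ import annotations

from dataclasses import dataclass

from .fba import FluxSolution, activity_threshold
from .model import MetabolicNetwork


class UndefinedQuotientError(ZeroDivisionError):
    """AQ is undefined: the solution releases no O2."""


def _boundary_flux(sol: FluxSolution, species: str) -> float:
    """Net uptake (positive into the cell) of an external species, summed
    over all transporters touching ``x_<species>``."""
    net = sol.network
    ext_id = f"x_{species}"
    if not net.has_metabolite(ext_id):
        raise KeyError(f"no external species {ext_id!r}")
    total = 0.0
    found = False
    for rxn in net.reactions:
        coef = rxn.stoichiometry.get(ext_id)
        if coef is None:
            continue
        found = True
        # external coefficient negative means the species is consumed from
        # outside when the reaction runs forward, i.e. uptake
        total += -float(coef) * sol.net_flux.get(rxn.id, 0.0)
    if not found:
        raise KeyError(f"no transporter for {ext_id!r}")
    return total


def assimilation_quotient(
    sol: FluxSolution, co2: str = "CO2", o2: str = "O2"
) -> float:
    """AQ = net CO2 uptake / net O2 release at the cell boundary."""
    if not sol.optimal:
        raise ValueError("AQ requires an optimal solution")
    co2_uptake = _boundary_flux(sol, co2)
    o2_release = -_boundary_flux(sol, o2)
    if abs(o2_release) <= activity_threshold(sol.photon_flux):
        raise UndefinedQuotientError("no net O2 release; AQ undefined")
    return co2_uptake / o2_release


def active_reaction_count(sol: FluxSolution, tol: float | None = None) -> int:
    """Number of reactions carrying net flux above the activity threshold
    (default: the scale-aware threshold shared with region detection)."""
    if not sol.optimal:
        raise ValueError("count requires an optimal solution")
    return len(sol.active_set(tol))


@dataclass
class CompartmentExchange:
    """Net species movement across one compartment boundary; positive =
    import into the compartment, negative = export."""

    compartment: str
    fluxes: dict[str, float]


def compartment_exchange(
    sol: FluxSolution, net: MetabolicNetwork, compartment: str
) -> CompartmentExchange:
    """Signed exchange of every species crossing the compartment boundary.

    A reaction spans the boundary when its stoichiometry touches both this
    compartment and somewhere else; its contribution to a species inside
    the compartment (coefficient x flux) is import when positive.
    """
    if compartment not in net.compartments:
        raise KeyError(f"unknown compartment {compartment!r}")
    fluxes: dict[str, float] = {}
    for rxn in net.reactions:
        comps = {net.metabolite(m).compartment for m in rxn.stoichiometry}
        if compartment not in comps or len(comps) < 2:
            continue
        v = sol.net_flux.get(rxn.id, 0.0)
        for met_id, coef in rxn.stoichiometry.items():
            if net.metabolite(met_id).compartment == compartment:
                fluxes[met_id] = fluxes.get(met_id, 0.0) + float(coef) * v
    return CompartmentExchange(compartment=compartment, fluxes=fluxes)


def nitrogen_source_shares(
    sol: FluxSolution, nh3: str = "NH3", no3: str = "NO3"
) -> tuple[float, float]:
    """Fractions of total nitrogen uptake arriving as ammonia vs nitrate
    (weighted by N atoms; both carry one here).  Sums to 1."""
    if not sol.optimal:
        raise ValueError("shares require an optimal solution")
    net = sol.network

    def n_uptake(species: str) -> float:
        ext = net.metabolite(f"x_{species}")
        n_atoms = ext.nitrogen_atoms if ext.nitrogen_atoms is not None else 1
        try:
            return _boundary_flux(sol, species) * n_atoms
        except KeyError:
            return 0.0

    u_nh3 = n_uptake(nh3)
    u_no3 = n_uptake(no3)
    total = u_nh3 + u_no3
    if total <= activity_threshold(sol.photon_flux):
        raise ZeroDivisionError("no nitrogen uptake; shares undefined")
    return u_nh3 / total, u_no3 / total
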