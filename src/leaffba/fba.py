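"""Minimal-total-flux linear programming under leaf-cell constraints.

The optimization problem: split every reversible reaction into an
irreversible forward/backward pair, then

    minimize    sum_j w_j                      (total flux, economy proxy)
    subject to  N_split @ w = 0                (steady state)
                photon uptake  = photon_flux   (equality: light is imposed)
                export transporters fixed at the output-scenario values
                maintenance ATPase fixed
                v_cyclic - v_noncyclic <= 0    (optional, default on)
                v_carboxylase + v_oxygenase <= rubisco_cap
                w >= 0

Photon uptake is an *equality*, not an upper bound: above light saturation
the network must dissipate the surplus (photorespiration, substrate
cycles), which is exactly the high-light regime of interest.  Solved with
scipy's HiGHS backend.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import MetabolicNetwork, Reaction
from .targets import OutputScenario

#: LP feasibility tolerance (steady-state residual, scale-aware).
FEASIBILITY_TOL = 1e-9
#: Activity threshold: a reaction counts as active when
#: ``|net flux| > ACTIVITY_TOL_REL * photon_flux`` (floored at 1e-9).
ACTIVITY_TOL_REL = 1e-7


def activity_threshold(photon_flux: float) -> float:
    return max(ACTIVITY_TOL_REL * photon_flux, 1e-9)


class UnboundedModelError(RuntimeError):
    """The LP is unbounded: the network can create mass/energy from nothing."""


@dataclass(frozen=True)
class LeafConstraints:
    """Constraint set of one scan point.

    ``photon_flux`` — imposed photon uptake (equality, model units).
    ``rubisco_cap`` — bound on carboxylase + oxygenase rate (Calvin-cycle
    capacity); ``None`` disables it.
    ``maintenance_atp`` — fixed flux through the tagged maintenance ATPase,
    identical for biomass and phloem runs.
    ``cyclic_le_noncyclic`` — cap cyclic photophosphorylation at the
    non-cyclic rate (prevents trivial dissipation of excess photons).
    ``blocked_reactions`` — reactions removed before solving (e.g. the NH3
    transporter, to force nitrate as sole N source).
    """

    output: OutputScenario
    photon_flux: float = 0.0
    rubisco_cap: float | None = None
    maintenance_atp: float = 0.0
    cyclic_le_noncyclic: bool = True
    blocked_reactions: tuple[str, ...] = ()
    #: when True the photon uptake is bounded above by ``photon_flux``
    #: instead of fixed to it — used by the bisection search, where
    #: "feasible with at most p photons" is monotone in p even for models
    #: with no dissipation route
    photon_is_upper_bound: bool = False

    def with_photon_flux(self, photon_flux: float) -> "LeafConstraints":
        return replace(self, photon_flux=photon_flux)

    def with_output(self, output: OutputScenario) -> "LeafConstraints":
        return replace(self, output=output)


@dataclass
class FluxSolution:
    """Recombined net fluxes of one optimal (or infeasible) LP solve."""

    status: str  # "optimal" | "infeasible"
    net_flux: dict[str, float]
    objective: float
    photon_flux: float
    r: float
    network: MetabolicNetwork | None = None
    steady_state_residual: float = float("nan")

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def active_set(self, tol: float | None = None) -> frozenset[str]:
        if tol is None:
            tol = activity_threshold(self.photon_flux)
        return frozenset(r for r, v in self.net_flux.items() if abs(v) > tol)

    def __getitem__(self, rxn_id: str) -> float:
        return self.net_flux[rxn_id]


def split_reversible(
    net: MetabolicNetwork,
) -> tuple[sp.csc_matrix, list[tuple[str, int, int | None]]]:
    """Split-column stoichiometry matrix and the recombination mapping.

    Returns ``(N_split, mapping)`` where mapping entries are
    ``(reaction_id, forward_column, backward_column_or_None)`` and the net
    flux of a reaction is ``w[fwd] - w[bwd]``.
    """
    internal = {m.id: i for i, m in enumerate(net.internal_metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    mapping: list[tuple[str, int, int | None]] = []
    ncol = 0
    for rxn in net.reactions:
        fwd = ncol
        ncol += 1
        for met_id, coef in rxn.stoichiometry.items():
            i = internal.get(met_id)
            if i is not None:
                rows.append(i)
                cols.append(fwd)
                vals.append(float(coef))
        bwd: int | None = None
        if rxn.reversible:
            bwd = ncol
            ncol += 1
            for met_id, coef in rxn.stoichiometry.items():
                i = internal.get(met_id)
                if i is not None:
                    rows.append(i)
                    cols.append(bwd)
                    vals.append(-float(coef))
        mapping.append((rxn.id, fwd, bwd))
    N = sp.coo_matrix((vals, (rows, cols)), shape=(len(internal), ncol)).tocsc()
    return N, mapping


def _fix_net_flux(
    bounds: list[list[float | None]],
    fwd: int,
    bwd: int | None,
    value: float,
) -> None:
    """Pin a reaction's net flux via variable bounds (non-negative values
    go on the forward column; the backward column, if any, is closed)."""
    if value < 0:
        if bwd is None:
            raise ValueError("negative fixed flux on an irreversible reaction")
        bounds[fwd] = [0.0, 0.0]
        bounds[bwd] = [-value, -value]
    else:
        bounds[fwd] = [value, value]
        if bwd is not None:
            bounds[bwd] = [0.0, 0.0]


def minimize_total_flux(
    net: MetabolicNetwork, constraints: LeafConstraints
) -> FluxSolution:
    """Solve the minimal-total-flux LP at one scan point."""
    if constraints.blocked_reactions:
        net = net.without_reactions(constraints.blocked_reactions)
    N, mapping = split_reversible(net)
    ncol = N.shape[1]
    cols = {rxn_id: (fwd, bwd) for rxn_id, fwd, bwd in mapping}
    bounds: list[list[float | None]] = [[0.0, None] for _ in range(ncol)]

    photon_tagged = net.reactions_with_tag("photon_import")
    if photon_tagged:
        photon_rxn = net.single_reaction_with_tag("photon_import")
        fwd, bwd = cols[photon_rxn.id]
        if constraints.photon_is_upper_bound:
            bounds[fwd] = [0.0, constraints.photon_flux]
            if bwd is not None:
                bounds[bwd] = [0.0, 0.0]
        else:
            _fix_net_flux(bounds, fwd, bwd, constraints.photon_flux)
    elif constraints.photon_flux:
        raise ValueError("photon_flux set but no photon_import-tagged reaction")
    else:
        photon_rxn = None

    for rxn_id, value in constraints.output.fixed_fluxes.items():
        if photon_rxn is not None and rxn_id == photon_rxn.id:
            raise ValueError("photon transporter cannot be an output")
        _fix_net_flux(bounds, *cols[rxn_id], value)

    if constraints.maintenance_atp or net.reactions_with_tag("maintenance_atpase"):
        ngam = net.single_reaction_with_tag("maintenance_atpase")
        _fix_net_flux(bounds, *cols[ngam.id], constraints.maintenance_atp)

    a_ub_rows: list[np.ndarray] = []
    b_ub: list[float] = []

    def _net_row(pairs: Sequence[tuple[str, float]]) -> np.ndarray:
        row = np.zeros(ncol)
        for rxn_id, sign in pairs:
            fwd, bwd = cols[rxn_id]
            row[fwd] += sign
            if bwd is not None:
                row[bwd] -= sign
        return row

    if constraints.cyclic_le_noncyclic:
        cyc = net.reactions_with_tag("cyclic_photophos")
        noncyc = net.reactions_with_tag("noncyclic_photophos")
        if cyc and noncyc:
            a_ub_rows.append(
                _net_row([(r.id, 1.0) for r in cyc] + [(r.id, -1.0) for r in noncyc])
            )
            b_ub.append(0.0)

    if constraints.rubisco_cap is not None:
        rub = net.reactions_with_tag("rubisco_carboxylase") + net.reactions_with_tag(
            "rubisco_oxygenase"
        )
        if rub:
            a_ub_rows.append(_net_row([(r.id, 1.0) for r in rub]))
            b_ub.append(float(constraints.rubisco_cap))

    res = linprog(
        c=np.ones(ncol),
        A_eq=N,
        b_eq=np.zeros(N.shape[0]),
        A_ub=np.vstack(a_ub_rows) if a_ub_rows else None,
        b_ub=np.asarray(b_ub) if b_ub else None,
        bounds=[tuple(b) for b in bounds],
        method="highs",
    )
    if res.status == 3:
        raise UnboundedModelError(
            "minimal-flux LP unbounded: the model creates mass or energy"
        )
    if res.status != 0:
        return FluxSolution(
            status="infeasible",
            net_flux={},
            objective=float("nan"),
            photon_flux=constraints.photon_flux,
            r=constraints.output.r,
            network=net,
        )
    w = res.x
    net_flux = {
        rxn_id: float(w[fwd] - (w[bwd] if bwd is not None else 0.0))
        for rxn_id, fwd, bwd in mapping
    }
    residual = float(np.max(np.abs(N @ w))) if N.shape[0] else 0.0
    return FluxSolution(
        status="optimal",
        net_flux=net_flux,
        objective=float(res.fun),
        photon_flux=constraints.photon_flux,
        r=constraints.output.r,
        network=net,
        steady_state_residual=residual,
    )


# -- photon-excess diagnostics ------------------------------------------


def _is_cofactor(net: MetabolicNetwork, met_id: str) -> bool:
    """Element-free bookkeeping species (ATP, NADPH, NADH, photons)."""
    m = net.metabolite(met_id)
    return m.carbon_atoms == 0 and m.nitrogen_atoms == 0 and m.oxygen_atoms == 0


def _cycle_scale(net: MetabolicNetwork, a: Reaction, b: Reaction):
    """Positive lambda such that running a at 1 and b at lambda cancels
    every non-cofactor species, leaving only net cofactor consumption (a
    substrate cycle, e.g. starch synthesis + degradation burning ATP).
    Returns None when the pair is not such a cycle."""
    mets_a = {m for m in a.stoichiometry if not _is_cofactor(net, m)}
    mets_b = {m for m in b.stoichiometry if not _is_cofactor(net, m)}
    if not mets_a or mets_a != mets_b:
        return None
    lam = None
    for met in mets_a:
        ratio = -a.stoichiometry[met] / b.stoichiometry[met]
        if ratio <= 0:
            return None
        if lam is None:
            lam = ratio
        elif ratio != lam:
            return None
    # net cofactor change must be consumption (dissipation), not creation
    total = {}
    for met, c in a.stoichiometry.items():
        if _is_cofactor(net, met):
            total[met] = total.get(met, Fraction(0)) + c
    for met, c in b.stoichiometry.items():
        if _is_cofactor(net, met):
            total[met] = total.get(met, Fraction(0)) + lam * c
    if any(c > 0 for c in total.values()) or all(c == 0 for c in total.values()):
        return None
    return lam


def apply_photon_excess_check(sol: FluxSolution) -> dict:
    """Report dissipation activity in an optimal solution.

    Substrate cycles are reaction pairs with exactly opposite stoichiometry
    both carrying net flux in their forward sense (e.g. starch synthesis +
    degradation); tagged ``dissipation`` reactions (e.g. the alternative
    oxidase) are reported alongside.  The total quantifies the high-light
    regime where excess reductant and ATP must be burned.
    """
    if not sol.optimal:
        raise ValueError("diagnostics require an optimal solution")
    net = sol.network
    tol = activity_threshold(sol.photon_flux)
    cycles: dict[tuple[str, str], float] = {}
    rxns = net.reactions
    for i in range(len(rxns)):
        vi = sol.net_flux.get(rxns[i].id, 0.0)
        if vi <= tol:
            continue
        for j in range(i + 1, len(rxns)):
            vj = sol.net_flux.get(rxns[j].id, 0.0)
            if vj <= tol:
                continue
            lam = _cycle_scale(net, rxns[i], rxns[j])
            if lam is not None:
                cycles[(rxns[i].id, rxns[j].id)] = min(vi, vj / lam)
    tagged = {
        r.id: sol.net_flux.get(r.id, 0.0)
        for r in net.reactions_with_tag("dissipation")
        if abs(sol.net_flux.get(r.id, 0.0)) > tol
    }
    total = sum(cycles.values()) + sum(abs(v) for v in tagged.values())
    return {
        "substrate_cycles": cycles,
        "dissipation_reactions": tagged,
        "total": total,
    }
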