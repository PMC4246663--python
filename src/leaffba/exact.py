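"""Brute-force minimal-total-flux oracle by vertex enumeration.

Independent of the LP solver: the split problem is put in standard form
(fixed fluxes substituted into the right-hand side, inequality rows given
slack columns) and every basic solution is enumerated in exact rational
arithmetic.  The objective is linear and bounded below on a pointed
polyhedron, so the optimum sits on a vertex; the minimum over feasible
basic solutions is therefore the exact optimum.  Only viable for small
networks (the column cap guards against combinatorial blow-up).
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

from .fba import FluxSolution, LeafConstraints
from .model import MetabolicNetwork

MAX_COLUMNS = 24
MAX_BASES = 500_000


class ProblemTooLargeError(ValueError):
    pass


def _rref(rows: list[list[Fraction]]) -> tuple[list[list[Fraction]], bool]:
    """Row-reduce [A|b]; returns (independent rows, consistent?)."""
    rows = [r[:] for r in rows]
    ncols = len(rows[0]) - 1
    pivot_row = 0
    for col in range(ncols):
        pr = None
        for r in range(pivot_row, len(rows)):
            if rows[r][col] != 0:
                pr = r
                break
        if pr is None:
            continue
        rows[pivot_row], rows[pr] = rows[pr], rows[pivot_row]
        piv = rows[pivot_row][col]
        rows[pivot_row] = [x / piv for x in rows[pivot_row]]
        for r in range(len(rows)):
            if r != pivot_row and rows[r][col] != 0:
                f = rows[r][col]
                rows[r] = [a - f * b for a, b in zip(rows[r], rows[pivot_row])]
        pivot_row += 1
        if pivot_row == len(rows):
            break
    independent = rows[:pivot_row]
    for r in rows[pivot_row:]:
        if any(x != 0 for x in r[:-1]):
            raise AssertionError("elimination left a nonzero row")
        if r[-1] != 0:
            return independent, False
    return independent, True


def _solve_square(A: list[list[Fraction]], b: list[Fraction]):
    """Exact solve of a square system; None when singular."""
    n = len(A)
    M = [A[i][:] + [b[i]] for i in range(n)]
    for col in range(n):
        pr = next((r for r in range(col, n) if M[r][col] != 0), None)
        if pr is None:
            return None
        M[col], M[pr] = M[pr], M[col]
        piv = M[col][col]
        M[col] = [x / piv for x in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [a - f * c for a, c in zip(M[r], M[col])]
    return [M[i][n] for i in range(n)]


def brute_force_min_flux(
    net: MetabolicNetwork, constraints: LeafConstraints
) -> FluxSolution:
    """Exact enumeration counterpart of
    :func:`leaffba.fba.minimize_total_flux` (same contract, tiny nets only).
    """
    if constraints.photon_is_upper_bound:
        raise ValueError("the enumeration oracle supports only fixed photon flux")
    if constraints.blocked_reactions:
        net = net.without_reactions(constraints.blocked_reactions)

    # split columns with Fraction coefficients
    columns: list[tuple[str, int, dict[str, Fraction]]] = []  # (rxn, sign, stoich)
    for rxn in net.reactions:
        columns.append((rxn.id, +1, dict(rxn.stoichiometry)))
        if rxn.reversible:
            columns.append(
                (rxn.id, -1, {m: -c for m, c in rxn.stoichiometry.items()})
            )

    fixed_net: dict[str, Fraction] = {}
    photon_tags = net.reactions_with_tag("photon_import")
    if photon_tags:
        fixed_net[photon_tags[0].id] = Fraction(constraints.photon_flux).limit_denominator(10**9)
    elif constraints.photon_flux:
        raise ValueError("photon_flux set but no photon_import-tagged reaction")
    for rxn_id, v in constraints.output.fixed_fluxes.items():
        fixed_net[rxn_id] = Fraction(v).limit_denominator(10**9)
    if net.reactions_with_tag("maintenance_atpase"):
        ngam = net.single_reaction_with_tag("maintenance_atpase")
        fixed_net[ngam.id] = Fraction(constraints.maintenance_atp).limit_denominator(10**9)

    internal = [m.id for m in net.internal_metabolites]
    row_of = {m: i for i, m in enumerate(internal)}
    n_balance = len(internal)

    # inequality rows on net fluxes -> appended as equality rows with slacks
    ineq: list[tuple[dict[str, Fraction], Fraction]] = []
    if constraints.cyclic_le_noncyclic:
        cyc = net.reactions_with_tag("cyclic_photophos")
        ncy = net.reactions_with_tag("noncyclic_photophos")
        if cyc and ncy:
            coefs = {r.id: Fraction(1) for r in cyc}
            coefs.update({r.id: Fraction(-1) for r in ncy})
            ineq.append((coefs, Fraction(0)))
    if constraints.rubisco_cap is not None:
        rub = net.reactions_with_tag("rubisco_carboxylase") + net.reactions_with_tag(
            "rubisco_oxygenase"
        )
        if rub:
            ineq.append(
                (
                    {r.id: Fraction(1) for r in rub},
                    Fraction(constraints.rubisco_cap).limit_denominator(10**9),
                )
            )

    free_cols: list[tuple[str, int, dict[str, Fraction]]] = []
    b = [Fraction(0)] * (n_balance + len(ineq))
    # substitute fixed reactions into b (forward sense; negatives unsupported,
    # matching the non-negative OutputScenario contract)
    for rxn_id, value in fixed_net.items():
        if value < 0:
            raise ValueError("negative fixed fluxes unsupported in the oracle")
        stoich = net.reaction(rxn_id).stoichiometry
        for m, c in stoich.items():
            i = row_of.get(m)
            if i is not None:
                b[i] -= c * value
        for k, (coefs, _) in enumerate(ineq):
            if rxn_id in coefs:
                b[n_balance + k] -= coefs[rxn_id] * value
    for col in columns:
        if col[0] not in fixed_net:
            free_cols.append(col)

    n_free = len(free_cols)
    n_cols = n_free + len(ineq)  # plus one slack per inequality
    if n_cols > MAX_COLUMNS:
        raise ProblemTooLargeError(f"{n_cols} columns exceeds cap {MAX_COLUMNS}")

    A: list[list[Fraction]] = [
        [Fraction(0)] * n_cols for _ in range(n_balance + len(ineq))
    ]
    for j, (rxn_id, sign, stoich) in enumerate(free_cols):
        for m, c in stoich.items():
            i = row_of.get(m)
            if i is not None:
                A[i][j] = c
        for k, (coefs, _) in enumerate(ineq):
            if rxn_id in coefs:
                A[n_balance + k][j] = sign * coefs[rxn_id]
    for k, (_, rhs) in enumerate(ineq):
        A[n_balance + k][n_free + k] = Fraction(1)
        b[n_balance + k] = rhs + b[n_balance + k]

    reduced, consistent = _rref([A[i] + [b[i]] for i in range(len(A))])
    if not consistent:
        return _infeasible(constraints)
    m_rank = len(reduced)
    A_red = [row[:-1] for row in reduced]
    b_red = [row[-1] for row in reduced]

    from math import comb

    if comb(n_cols, m_rank) > MAX_BASES:
        raise ProblemTooLargeError("too many candidate bases")

    best_obj: Fraction | None = None
    best_x: list[Fraction] | None = None
    cost = [Fraction(1)] * n_free + [Fraction(0)] * len(ineq)
    for basis in combinations(range(n_cols), m_rank):
        sub = [[A_red[i][j] for j in basis] for i in range(m_rank)]
        x_b = _solve_square(sub, b_red)
        if x_b is None or any(x < 0 for x in x_b):
            continue
        obj = sum(cost[j] * x for j, x in zip(basis, x_b))
        if best_obj is None or obj < best_obj:
            best_obj = obj
            x = [Fraction(0)] * n_cols
            for j, v in zip(basis, x_b):
                x[j] = v
            best_x = x
    if best_obj is None:
        return _infeasible(constraints)

    net_flux = {rxn_id: float(v) for rxn_id, v in fixed_net.items()}
    for j, (rxn_id, sign, _) in enumerate(free_cols):
        net_flux[rxn_id] = net_flux.get(rxn_id, 0.0) + sign * float(best_x[j])
    for rxn in net.reactions:
        net_flux.setdefault(rxn.id, 0.0)
    objective = best_obj + sum(abs(v) for v in fixed_net.values())
    return FluxSolution(
        status="optimal",
        net_flux=net_flux,
        objective=float(objective),
        photon_flux=constraints.photon_flux,
        r=constraints.output.r,
        network=net,
        steady_state_residual=0.0,
    )


def _infeasible(constraints: LeafConstraints) -> FluxSolution:
    return FluxSolution(
        status="infeasible",
        net_flux={},
        objective=float("nan"),
        photon_flux=constraints.photon_flux,
        r=constraints.output.r,
    )
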