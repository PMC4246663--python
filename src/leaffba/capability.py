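"""Flux-capability classification.

A reaction "can carry flux" when some steady-state flux vector gives it a
nonzero rate while all exchange transporters other than the named nutrient
and output sets are closed.  Computed by per-reaction flux maximization on
the split (all-irreversible) problem, with the standard shortcut of
harvesting every reaction already seen active in a previous optimum.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.optimize import linprog

from .fba import split_reversible
from .model import MetabolicNetwork

#: Default per-variable bound and the matching activity cutoff
#: (1e-6 x scale: solver noise floor).
DEFAULT_BOUND = 1e3
CAPABILITY_TOL_REL = 1e-6


class InfeasibleNetworkError(RuntimeError):
    """The base steady-state problem itself has no solution."""


def flux_capable_reactions(
    net: MetabolicNetwork,
    nutrients: Iterable[str],
    outputs: Iterable[str],
    bound: float = DEFAULT_BOUND,
) -> set[str]:
    """Ids of reactions that can carry steady-state flux from the nutrient
    transporters to the output transporters.

    ``nutrients`` and ``outputs`` name transporter reactions left open; any
    other reaction touching an external metabolite is fixed to zero.
    """
    open_exchange = set(nutrients) | set(outputs)
    for rxn_id in open_exchange:
        if not net.has_reaction(rxn_id):
            raise KeyError(f"unknown transporter {rxn_id!r}")
    N, mapping = split_reversible(net)
    ncol = N.shape[1]
    tol = CAPABILITY_TOL_REL * bound

    bounds = np.zeros((ncol, 2))
    bounds[:, 1] = bound
    for rxn_id, fwd, bwd in mapping:
        rxn = net.reaction(rxn_id)
        if "transporter" in rxn.tags and rxn_id not in open_exchange:
            bounds[fwd] = (0.0, 0.0)
            if bwd is not None:
                bounds[bwd] = (0.0, 0.0)

    b_eq = np.zeros(N.shape[0])
    base = linprog(
        c=np.zeros(ncol),
        A_eq=N,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if base.status != 0:
        raise InfeasibleNetworkError(
            "steady-state base problem infeasible with the given exchange sets"
        )

    capable: set[str] = set()
    col_to_rxn = {}
    for rxn_id, fwd, bwd in mapping:
        col_to_rxn[fwd] = rxn_id
        if bwd is not None:
            col_to_rxn[bwd] = rxn_id

    def harvest(x: np.ndarray) -> None:
        for col in np.nonzero(x > tol)[0]:
            capable.add(col_to_rxn[int(col)])

    for rxn_id, fwd, bwd in mapping:
        for col in (fwd, bwd):
            if col is None or col_to_rxn[col] in capable or bounds[col, 1] == 0:
                continue
            c = np.zeros(ncol)
            c[col] = -1.0  # maximize this direction
            res = linprog(c=c, A_eq=N, b_eq=b_eq, bounds=bounds, method="highs")
            if res.status == 0:
                harvest(res.x)
    return capable
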