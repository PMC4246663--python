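"""Scans over photon flux and the biomass-to-phloem transition axis.

The light axis is the scan index ``i``; the output-transition axis is the
phloem fraction ``r`` (0 = pure biomass, 1 = pure phloem, equal carbon).
Each grid cell is an independent minimal-total-flux LP.  On top of the
grid: bisection for the minimal feasible light, change-point detection on
the active reaction set (phenotype regions), and the relative-difference
surface D = J(i,r)/J(i,r=ref) - 1 used to compare flux responses across
the transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fba import FluxSolution, LeafConstraints, activity_threshold, minimize_total_flux
from .model import MetabolicNetwork
from .targets import OutputScenario, mix_outputs

#: Active-set changes of at least this size count as a "major" rearrangement
#: when summarizing regions at coarse granularity.
MAJOR_REARRANGEMENT = 5


@dataclass
class ScanResult:
    photon_values: list[float]
    r_values: list[float]
    #: solutions[i][k] is the cell at photon_values[i], r_values[k]
    solutions: list[list[FluxSolution]]

    def __post_init__(self) -> None:
        if any(
            b <= a for a, b in zip(self.photon_values, self.photon_values[1:])
        ):
            raise ValueError("photon_values must be strictly increasing")

    def slice_at_r(self, r: float) -> list[FluxSolution]:
        k = self._r_index(r)
        return [row[k] for row in self.solutions]

    def _r_index(self, r: float) -> int:
        for k, rv in enumerate(self.r_values):
            if math.isclose(rv, r, rel_tol=0.0, abs_tol=1e-12):
                return k
        raise KeyError(f"r={r} not on the scan grid")

    def feasible_fraction(self) -> float:
        cells = [s for row in self.solutions for s in row]
        return sum(s.optimal for s in cells) / len(cells)


@dataclass
class RegionPartition:
    """Breakpoints along the light axis separating constant-active-set
    regions, labeled A, B, ... from low light."""

    breakpoints: list[float]
    labels: list[str]

    @property
    def n_regions(self) -> int:
        return len(self.labels)


@dataclass
class RelativeDifferenceGrid:
    """D(i,r) = J(i,r)/J(i,r=ref) - 1 for one reaction; NaN marks cells
    where the reference flux is below the activity threshold (undefined
    rather than infinite)."""

    reaction_id: str
    reference_r: float
    photon_values: list[float]
    r_values: list[float]
    values: np.ndarray  # shape (len(photon_values), len(r_values))


def find_min_photon_flux(
    net: MetabolicNetwork,
    constraints: LeafConstraints,
    lo: float,
    hi: float,
    tol: float = 1e-6,
) -> float:
    """Bisection search for the light threshold below which the output
    cannot be produced.  Requires infeasibility at ``lo`` and feasibility
    at ``hi``; returns the threshold to within ``tol``.

    The search solves with photon uptake *bounded above* by the candidate
    (rather than fixed), so feasibility is monotone in light even for
    models without a dissipation route; the returned threshold is the same
    minimal equality-feasible photon flux.
    """
    import dataclasses

    probe = dataclasses.replace(constraints, photon_is_upper_bound=True)

    def feasible(p: float) -> bool:
        return minimize_total_flux(net, probe.with_photon_flux(p)).optimal

    if feasible(lo):
        raise ValueError(f"lower bracket feasible at photon flux {lo}")
    if not feasible(hi):
        raise ValueError(f"upper bracket infeasible at photon flux {hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi


def scan_light(
    net: MetabolicNetwork,
    constraints: LeafConstraints,
    photon_values: list[float] | np.ndarray,
) -> ScanResult:
    """1-D light scan at the output scenario carried by ``constraints``."""
    photon_values = [float(p) for p in photon_values]
    sols = [
        [minimize_total_flux(net, constraints.with_photon_flux(p))]
        for p in photon_values
    ]
    return ScanResult(
        photon_values=photon_values,
        r_values=[constraints.output.r],
        solutions=sols,
    )


def scan_2d(
    net: MetabolicNetwork,
    constraints: LeafConstraints,
    photon_values: list[float] | np.ndarray,
    r_values: list[float] | np.ndarray,
    biomass: OutputScenario,
    phloem: OutputScenario,
) -> ScanResult:
    """Full light x phloem-fraction grid.  ``phloem`` must already be
    equal-carbon scaled so carbon fixation is invariant along r."""
    photon_values = [float(p) for p in photon_values]
    r_values = [float(r) for r in r_values]
    mixes = [mix_outputs(biomass, phloem, r) for r in r_values]
    sols = [
        [
            minimize_total_flux(
                net, constraints.with_output(mix).with_photon_flux(p)
            )
            for mix in mixes
        ]
        for p in photon_values
    ]
    return ScanResult(photon_values=photon_values, r_values=r_values, solutions=sols)


def log_photon_grid(lo: float, hi: float, n: int) -> np.ndarray:
    """Logarithmically spaced light grid (the default: responses are
    piecewise linear so log spacing resolves the low-light structure)."""
    if lo <= 0:
        raise ValueError("log grid needs lo > 0")
    return np.geomspace(lo, hi, n)


def detect_regions(
    scan: ScanResult,
    r: float,
    min_change: int = 1,
    tol: float | None = None,
) -> RegionPartition:
    """Partition the light axis into constant-flux-pattern regions.

    A breakpoint falls between consecutive feasible grid points whose
    active reaction sets differ by at least ``min_change`` members
    (symmetric difference).  Regions are labeled A, B, ... from low light.
    """
    slice_ = scan.slice_at_r(r)
    pts = [
        (p, s)
        for p, s in zip(scan.photon_values, slice_)
        if s.optimal
    ]
    if len(pts) < 3:
        raise ValueError("need at least 3 feasible points to detect regions")
    active = [
        s.active_set(tol if tol is not None else activity_threshold(p))
        for p, s in pts
    ]
    breakpoints: list[float] = []
    for k in range(len(pts) - 1):
        if len(active[k] ^ active[k + 1]) >= min_change:
            breakpoints.append(0.5 * (pts[k][0] + pts[k + 1][0]))
    labels = [_region_label(i) for i in range(len(breakpoints) + 1)]
    return RegionPartition(breakpoints=breakpoints, labels=labels)


def _region_label(i: int) -> str:
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def region_linearity_residual(
    scan: ScanResult, regions: RegionPartition, r: float
) -> float:
    """Largest relative residual of any reaction flux from a straight-line
    fit against photon flux within its region.

    Within one region the active set is constant, so every flux of the
    minimal-flux solution is an affine function of light; the residual
    measures how well the scan respects that piecewise linearity.
    """
    slice_ = scan.slice_at_r(r)
    pts = [(p, s) for p, s in zip(scan.photon_values, slice_) if s.optimal]
    edges = (
        [-math.inf] + list(regions.breakpoints) + [math.inf]
    )
    worst = 0.0
    rxn_ids = list(pts[0][1].net_flux)
    for lo, hi in zip(edges, edges[1:]):
        seg = [(p, s) for p, s in pts if lo < p < hi]
        if len(seg) < 3:
            continue
        x = np.array([p for p, _ in seg])
        A = np.vstack([x, np.ones_like(x)]).T
        for rxn_id in rxn_ids:
            y = np.array([s.net_flux[rxn_id] for _, s in seg])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = np.max(np.abs(A @ coef - y))
            scale = max(np.max(np.abs(y)), 1.0)
            worst = max(worst, resid / scale)
    return worst


def relative_difference(
    scan: ScanResult, reaction_id: str, reference_r: float = 0.5
) -> RelativeDifferenceGrid:
    """The relative-difference surface D(i,r) = J(i,r)/J(i,ref) - 1.

    Cells whose reference flux is inactive (|J| below the activity
    threshold) are undefined (NaN), not infinite.
    """
    k_ref = scan._r_index(reference_r)
    n_i, n_r = len(scan.photon_values), len(scan.r_values)
    values = np.full((n_i, n_r), np.nan)
    for i, p in enumerate(scan.photon_values):
        ref = scan.solutions[i][k_ref]
        if not ref.optimal:
            continue
        j_ref = ref.net_flux.get(reaction_id, 0.0)
        if abs(j_ref) <= activity_threshold(p):
            continue
        for k in range(n_r):
            s = scan.solutions[i][k]
            if s.optimal:
                values[i, k] = s.net_flux.get(reaction_id, 0.0) / j_ref - 1.0
    return RelativeDifferenceGrid(
        reaction_id=reaction_id,
        reference_r=reference_r,
        photon_values=list(scan.photon_values),
        r_values=list(scan.r_values),
        values=values,
    )


def linear_tail_reached(scan: ScanResult, r: float, tol: float = 1e-6) -> bool:
    """True when the last two inter-point slope changes of every flux are
    zero (to ``tol``), i.e. the scan already covers the final all-linear
    regime and extending the light range further adds no new transitions."""
    slice_ = [s for s in scan.slice_at_r(r) if s.optimal]
    if len(slice_) < 4:
        return False
    p = [pv for pv, s in zip(scan.photon_values, scan.slice_at_r(r)) if s.optimal]
    last = slice_[-4:]
    p = p[-4:]
    for rxn_id in last[0].net_flux:
        y = [s.net_flux[rxn_id] for s in last]
        slopes = [(y[k + 1] - y[k]) / (p[k + 1] - p[k]) for k in range(3)]
        scale = max(max(abs(v) for v in y), 1.0)
        if any(abs(slopes[k + 1] - slopes[k]) > tol * scale for k in range(2)):
            return False
    return True
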