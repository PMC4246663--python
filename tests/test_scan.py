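"""Bisection, scanning, region detection and the relative-difference grid."""

import math

import numpy as np
import pytest

import leaffba as L
from leaffba.fba import FluxSolution
from leaffba.scan import ScanResult


def _fabricated_scan(photon_values, flux_tables, r=0.0):
    """ScanResult from hand-written net-flux tables (one dict per light)."""
    sols = [
        [
            FluxSolution(
                status="optimal",
                net_flux=dict(table),
                objective=sum(abs(v) for v in table.values()),
                photon_flux=p,
                r=r,
            )
        ]
        for p, table in zip(photon_values, flux_tables)
    ]
    return ScanResult(photon_values=list(photon_values), r_values=[r], solutions=sols)


class TestBisection:
    def test_atp_toy_threshold_is_analytic(self, atp_toy):
        net, constraints = atp_toy
        t = L.find_min_photon_flux(net, constraints, lo=0.0, hi=10.0, tol=1e-6)
        assert t == pytest.approx(3.0, abs=1e-6)

    def test_bracket_errors(self, atp_toy):
        net, constraints = atp_toy
        with pytest.raises(ValueError, match="lower bracket feasible"):
            L.find_min_photon_flux(net, constraints, lo=5.0, hi=10.0)
        with pytest.raises(ValueError, match="upper bracket infeasible"):
            L.find_min_photon_flux(net, constraints, lo=0.0, hi=1.0)

    def test_phloem_threshold_below_biomass(self, thresholds):
        # the phloem mix needs less ATP per fixed carbon, so it is feasible
        # at slightly lower light
        assert thresholds["phloem"] < thresholds["biomass"]


class TestScans:
    def test_two_point_smoke(self, core_model, scenarios, thresholds):
        b, _ = scenarios
        t = thresholds["biomass"]
        scan = L.scan_light(
            core_model.network, core_model.constraints(b), [t * 1.01, t * 1.5]
        )
        assert all(row[0].optimal for row in scan.solutions)

    def test_infeasibility_recorded_not_raised(self, core_model, scenarios, thresholds):
        b, _ = scenarios
        t = thresholds["biomass"]
        scan = L.scan_light(
            core_model.network, core_model.constraints(b), [t * 0.5, t * 1.1]
        )
        assert scan.solutions[0][0].status == "infeasible"
        assert scan.solutions[1][0].optimal

    def test_feasibility_monotone_in_light(self, core_model, scenarios, thresholds):
        b, _ = scenarios
        t = thresholds["biomass"]
        scan = L.scan_light(
            core_model.network,
            core_model.constraints(b),
            np.linspace(t * 0.3, t * 3, 12),
        )
        feas = [row[0].optimal for row in scan.solutions]
        assert feas == sorted(feas)  # infeasible only at the low-light end

    def test_2d_edges_reproduce_1d_scans(
        self, core_model, scenarios, grid_scan, biomass_scan
    ):
        b, p = scenarios
        net = core_model.network
        left = grid_scan.slice_at_r(0.0)
        ref = L.scan_light(
            net, core_model.constraints(b), grid_scan.photon_values
        ).slice_at_r(0.0)
        for s1, s2 in zip(left, ref):
            assert s1.net_flux == pytest.approx(s2.net_flux, abs=1e-9)

    def test_carbon_audit_constant_along_r(self, grid_scan, scenarios):
        # net CO2 uptake at the boundary equals exported carbon in every
        # cell, hence is constant along the transition axis
        b, _ = scenarios
        from leaffba.metrics import _boundary_flux

        for row in grid_scan.solutions:
            for s in row:
                assert _boundary_flux(s, "CO2") == pytest.approx(
                    b.carbon_rate, rel=1e-9
                )

    def test_grid_refinement_keeps_breakpoints(
        self, core_model, scenarios, thresholds
    ):
        b, _ = scenarios
        t = thresholds["biomass"]
        coarse_grid = np.geomspace(t * 1.001, t * 4, 25)
        fine_grid = np.geomspace(t * 1.001, t * 4, 49)
        net = core_model.network
        c = core_model.constraints(b)
        coarse = L.detect_regions(L.scan_light(net, c, coarse_grid), 0.0)
        fine = L.detect_regions(L.scan_light(net, c, fine_grid), 0.0)
        step = np.max(np.diff(coarse_grid))
        for bp in coarse.breakpoints:
            assert min(abs(bp - x) for x in fine.breakpoints) <= step


class TestDetectRegions:
    def test_planted_change_point(self):
        flat = {"R1": 1.0, "R2": 0.5}
        changed = {"R1": 1.0, "R2": 0.0, "R3": 0.7}
        scan = _fabricated_scan([1, 2, 3, 4], [flat, flat, changed, changed])
        part = L.detect_regions(scan, 0.0, min_change=1)
        assert part.n_regions == 2
        assert part.breakpoints == [2.5]
        assert part.labels == ["A", "B"]

    def test_infinite_min_change_gives_single_region(self, biomass_scan):
        part = L.detect_regions(biomass_scan, 0.0, min_change=10**9)
        assert part.n_regions == 1 and part.breakpoints == []

    def test_too_few_points_rejected(self):
        scan = _fabricated_scan([1, 2], [{"R": 1.0}, {"R": 1.0}])
        with pytest.raises(ValueError):
            L.detect_regions(scan, 0.0)

    def test_toy_has_major_and_minor_granularity(self, biomass_scan):
        fine = L.detect_regions(biomass_scan, 0.0, min_change=1)
        major = L.detect_regions(biomass_scan, 0.0, min_change=5)
        assert fine.n_regions >= major.n_regions

    def test_piecewise_linear_within_regions(self, biomass_scan):
        part = L.detect_regions(biomass_scan, 0.0)
        resid = L.region_linearity_residual(biomass_scan, part, 0.0)
        assert resid <= 1e-6


class TestRelativeDifference:
    def test_arithmetic_identity_and_guard(self):
        tables = [
            {"J": 1.0, "Z": 0.0},
            {"J": 1.15, "Z": 0.0},
        ]
        sols = [
            [
                FluxSolution("optimal", dict(t), 0.0, photon_flux=1.0, r=rv)
                for rv, t in (
                    (0.5, tables[0]),
                    (1.0, tables[1]),
                )
            ]
        ]
        scan = ScanResult(photon_values=[1.0], r_values=[0.5, 1.0], solutions=sols)
        D = L.relative_difference(scan, "J", reference_r=0.5)
        assert D.values[0, 1] == pytest.approx(0.15)
        assert D.values[0, 0] == 0.0  # identity at the reference
        Z = L.relative_difference(scan, "Z", reference_r=0.5)
        assert np.isnan(Z.values).all()  # zero reference -> undefined

    def test_missing_reference_rejected(self, grid_scan):
        with pytest.raises(KeyError):
            L.relative_difference(grid_scan, "ComplexV", reference_r=0.55)

    def test_reference_column_zero_on_toy_grid(self, grid_scan):
        D = L.relative_difference(grid_scan, "MDH_mit", reference_r=0.5)
        k = grid_scan.r_values.index(0.5)
        col = D.values[:, k]
        assert np.nanmax(np.abs(col)) == 0.0


class TestLinearTail:
    def test_reached_only_at_high_light(self, core_model, scenarios, thresholds):
        b, _ = scenarios
        t = thresholds["biomass"]
        net = core_model.network
        c = core_model.constraints(b)
        high = L.scan_light(net, c, np.linspace(t * 2.2, t * 4, 6))
        assert L.linear_tail_reached(high, 0.0)
        low = L.scan_light(net, c, np.linspace(t * 1.01, t * 1.6, 6))
        assert not L.linear_tail_reached(low, 0.0)
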