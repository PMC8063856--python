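"""Demand scan: convexity, cap saturation, regions and response shapes."""

import numpy as np
import pytest

from fluxscan import STANDARD_CONDITIONS, exact_minimum
from fluxscan.scan import (
    RegionError,
    ScanCaps,
    classify_flux_patterns,
    convexity_defect,
    detect_regions,
    scan_demand,
)
from fluxscan.toy import default_scan_caps


class TestScanBasics:
    def test_grid_strictly_increasing(self, toy_scan):
        result, _ = toy_scan
        assert np.all(np.diff(result.demand_grid) > 0)
        assert result.demand_grid[-1] == pytest.approx(result.demand_max)

    def test_objective_nondecreasing_and_convex(self, toy_scan):
        result, _ = toy_scan
        assert np.all(np.diff(result.objective_curve) >= -1e-7)
        assert convexity_defect(result) >= -1e-7

    def test_no_inputs_no_product(self, toy_model):
        result = scan_demand(toy_model, ScanCaps(maxG=0.0, maxP=0.0, maxC=10.0), step=0.5)
        assert result.demand_max == 0.0
        assert len(result.demand_grid) == 0

    def test_demand_max_refined_to_tolerance(self, toy_model, toy_scan):
        result, _ = toy_scan
        from fluxscan.scan import _scan_constraints
        from fluxscan.lp import minimize_total_flux

        cons, caps = _scan_constraints(toy_model, result.caps, result.condition,
                                       result.demand_max)
        assert minimize_total_flux(toy_model, cons, caps).status == "optimal"
        cons, caps = _scan_constraints(toy_model, result.caps, result.condition,
                                       result.demand_max + 1e-4)
        assert minimize_total_flux(toy_model, cons, caps).status == "infeasible"


class TestSaturation:
    def test_caps_bind_in_order(self, toy_scan):
        result, _ = toy_scan
        pts = result.saturation_points
        assert set(pts) == {"G", "P", "C"}
        assert pts["G"] < pts["P"] < pts["C"]

    def test_glycerol_breakpoint_matches_oracle_yield(self, toy_model, toy_scan):
        """Below its cap the LP scales linearly, so glycerol saturates at
        maxG x (TAG per glycerol); the per-unit glycerol flux comes from the
        exact rational oracle."""
        result, _ = toy_scan
        exact = exact_minimum(toy_model, STANDARD_CONDITIONS[0].constraints(toy_model))
        gly_per_tag = exact.flux["tx_Glycerol"]
        predicted = result.caps.maxG / float(gly_per_tag)
        assert result.saturation_points["G"] == pytest.approx(predicted, abs=1e-4)

    def test_monotone_saturation(self, toy_scan):
        """Once a cap binds it stays bound at every larger demand."""
        result, _ = toy_scan
        seen = set()
        for sig in result.binding:
            assert sig >= frozenset(seen)
            seen |= sig


class TestRegions:
    def test_four_nested_regions(self, toy_scan):
        _, regions = toy_scan
        assert [r.label for r in regions] == ["A", "B", "C", "D"]
        sigs = regions.signatures
        assert sigs[0] == frozenset()
        assert sigs[1] == frozenset({"G"})
        assert sigs[2] == frozenset({"G", "P"})
        assert sigs[3] == frozenset({"G", "P", "C"})

    def test_regions_partition_demand_axis(self, toy_scan):
        result, regions = toy_scan
        assert regions.regions[0].start == 0.0
        for a, b in zip(regions.regions, regions.regions[1:]):
            assert a.end == b.start
        assert regions.regions[-1].end == pytest.approx(result.demand_max)

    def test_boundaries_sit_at_objective_kinks(self, toy_scan):
        """Region starts coincide with slope changes of the piecewise-linear
        objective curve."""
        result, regions = toy_scan
        d, f = result.demand_grid, result.objective_curve
        slopes = np.diff(f) / np.diff(d)
        kinks = set()
        for i in range(1, len(slopes)):
            if abs(slopes[i] - slopes[i - 1]) > 1e-4:
                kinks.add(round(float(d[i]), 6))
        for region in regions.regions[1:]:
            # the boundary is the last grid point of the previous region
            assert any(abs(region.start - k) <= 0.051 for k in kinks), (
                region.label, region.start, sorted(kinks))

    def test_single_region_when_no_cap_binds(self, toy_model):
        loose = ScanCaps(maxG=1e4, maxP=1e4, maxC=1e4)
        result = scan_demand(toy_model, loose, step=0.2, max_steps=5)
        regions = detect_regions(result)
        assert len(regions) == 1
        assert regions.regions[0].signature == frozenset()

    def test_region_D_marks_terminal_regime(self, toy_scan):
        """All three caps bind in the terminal regime, where the remaining
        carbon demand falls on anaplerotic HCO3 cycling."""
        result, regions = toy_scan
        last = regions.regions[-1]
        assert last.signature == frozenset({"G", "P", "C"})
        pepc = result.flux_matrix.loc["PEPCarboxylase"].to_numpy()
        assert pepc[-1] == pepc.max()  # anaplerotic flux is maximal at the end

    def test_mito_etc_grows_after_photon_saturation(self, toy_scan):
        """Past the photon cap the extra energy demand falls on the
        mitochondrial electron transport chain."""
        result, regions = toy_scan
        etc = result.flux_matrix.loc["ElectronTransportChain"].to_numpy()
        p_start = result.saturation_points["P"]
        idx = np.flatnonzero(result.demand_grid >= p_start - 1e-9)
        assert etc[idx[-1]] > etc[idx[0]]

    def test_gross_o2_production_maximal_in_final_regions(self, toy_scan):
        """Photosynthetic O2 evolution (light-reaction flux) peaks at the
        high-demand end of the scan."""
        result, regions = toy_scan
        light = result.flux_matrix.loc["LightReactions"].to_numpy()
        peak_demand = result.demand_grid[int(np.argmax(light))]
        assert peak_demand > regions.regions[-2].start


class TestFluxPatterns:
    def test_constant_reactions_excluded(self, toy_scan):
        result, regions = toy_scan
        groups, varying = classify_flux_patterns(result, regions)
        flat = [rid for rid in result.flux_matrix.index if rid not in varying]
        for rid in flat:
            traj = result.flux_matrix.loc[rid].to_numpy()
            assert traj.max() - traj.min() <= 1e-6 * max(1.0, result.demand_max)

    def test_chain_members_share_a_group(self, toy_scan):
        result, regions = toy_scan
        groups, _ = classify_flux_patterns(result, regions)
        membership = {rid: sig for sig, rids in groups.items() for rid in rids}
        assert membership["tx_TAG"] == membership["TAGSynthesis"]

    def test_requires_three_grid_points(self, toy_model):
        short = scan_demand(toy_model, default_scan_caps(), step=0.5, max_steps=2)
        with pytest.raises(ValueError):
            classify_flux_patterns(short)
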