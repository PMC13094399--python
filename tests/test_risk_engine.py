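"""Overlap statistics, tier rules with the conservative SE upgrade, and
refugia maps, each checked against exhaustive counting oracles."""

import numpy as np
import pytest

from heatrisk import (
    ClimateGrid,
    OverlapSummary,
    REFUGIA_CODES,
    SpeciesRange,
    ValueSample,
    WarmingSpec,
    assemble_scenarios,
    classify_risk,
    compute_envelope,
    extract_cell_values,
    make_scenarios,
    overlap_percent,
    refugia_map,
    summarise_overlaps,
)
from conftest import cells_polygon


def _sample(values):
    values = np.asarray(values, float)
    cells = np.column_stack([np.arange(values.size), np.zeros(values.size)])
    return ValueSample(values, cells)


def _envelope(lo, hi, epoch="current"):
    return compute_envelope(_sample([lo, hi]), epoch)


class TestOverlapPercent:
    @pytest.mark.parametrize("mode", ["upper", "two_sided"])
    def test_all_values_at_env_min_give_100(self, mode):
        env = _envelope(30.0, 40.0)
        assert overlap_percent(_sample([30.0] * 5), env, mode) == 100.0

    def test_upper_counts_ties_as_within(self):
        env = _envelope(30.0, 40.0)
        assert overlap_percent(_sample([38, 39, 40, 41, 42]), env, "upper") == 60.0

    @pytest.mark.parametrize("mode", ["upper", "two_sided"])
    def test_matches_counting_oracle(self, mode):
        rng = np.random.default_rng(17)
        values = rng.uniform(20, 50, 1000)
        lo, hi = sorted(rng.uniform(25, 45, 2))
        env = _envelope(lo, hi)
        got = overlap_percent(_sample(values), env, mode)
        count = 0
        for v in values:  # brute-force loop
            if mode == "upper":
                count += v <= hi
            else:
                count += lo <= v <= hi
        assert got == pytest.approx(100.0 * count / values.size)

    def test_weighted_fraction(self):
        s = ValueSample([30.0, 50.0], [[0, 0], [0, 1]], weights=[3.0, 1.0])
        assert overlap_percent(s, _envelope(25.0, 40.0)) == 75.0


class TestSummariseOverlaps:
    def _species(self, transform):
        cells = [(r, c) for r in range(2, 6) for c in range(2, 6)]
        poly = cells_polygon(transform, cells)
        return SpeciesRange("sp", poly, poly)

    def test_no_warming_means_100_se_0(self, grid_5x5):
        futures = [ClimateGrid(grid_5x5.values.copy(), grid_5x5.transform)
                   for _ in range(4)]
        sset = assemble_scenarios(grid_5x5, futures)
        poly = cells_polygon(grid_5x5.transform, [(1, 1), (2, 2), (3, 3)])
        summ = summarise_overlaps(SpeciesRange("sp", poly, poly), sset)
        assert summ.mean_current == summ.mean_historical == 100.0
        assert summ.se_current == summ.se_historical == 0.0

    def test_extreme_warming_means_0(self, grid_5x5):
        fut = ClimateGrid(grid_5x5.values + 100.0, grid_5x5.transform)
        sset = assemble_scenarios(grid_5x5, [fut])
        poly = cells_polygon(grid_5x5.transform, [(1, 1), (2, 2)])
        summ = summarise_overlaps(SpeciesRange("sp", poly, poly), sset)
        assert summ.mean_current == summ.mean_historical == 0.0
        assert summ.se_current == summ.se_historical == 0.0

    def test_known_warming_mask_gives_exact_mean_and_zero_se(self, grid_5x5):
        """Warm exactly 40% of the range's cells past the current TM in
        every scenario: mean overlap 60%, SE 0."""
        cells = [(r, c) for r in range(5) for c in range(2)]  # 10 cells
        poly = cells_polygon(grid_5x5.transform, cells)
        warmed = cells[:4]  # 40%
        futures = []
        for _ in range(5):
            v = grid_5x5.values.copy()
            for r, c in warmed:
                v[r, c] += 100.0
            futures.append(ClimateGrid(v, grid_5x5.transform))
        sset = assemble_scenarios(grid_5x5, futures)
        summ = summarise_overlaps(SpeciesRange("sp", poly, poly), sset)
        assert summ.mean_current == 60.0
        assert summ.se_current == 0.0

    def test_historical_overlap_bounds_current_for_nested_ranges(self, scenarios):
        from heatrisk import SpeciesSpec, make_species
        spec = SpeciesSpec("high", hist_width=9.0, delta_tm=0.5,
                           target_overlap_current=30.0,
                           target_overlap_historical=40.0)
        sp, _ = make_species(scenarios, spec, seed=9)
        summ = summarise_overlaps(sp, scenarios)
        assert np.all(summ.per_scenario_historical
                      >= summ.per_scenario_current)

    def test_uniform_extra_warming_never_lowers_risk(self, scenarios):
        """Adding a constant positive offset to every future grid never
        decreases the risk tier under the upper-tail overlap."""
        from heatrisk import SpeciesSpec, make_species
        order = {"low": 0, "moderate": 1, "high": 2}
        spec = SpeciesSpec("low", hist_width=18.0, delta_tm=2.0,
                           target_overlap_current=80.0,
                           target_overlap_historical=90.0)
        sp, _ = make_species(scenarios, spec, seed=2)
        prev = -1
        for extra in (0.0, 2.0, 6.0, 30.0):
            futures = [ClimateGrid(f.values + extra, f.transform,
                                   nodata_mask=f.nodata_mask)
                       for f in scenarios.futures]
            sset = assemble_scenarios(scenarios.baseline, futures)
            tier = classify_risk(summarise_overlaps(sp, sset)).tier
            assert order[tier] >= prev
            prev = order[tier]


class TestClassifyRisk:
    def _summary(self, mean_c, se_c, mean_h, se_h, k=16):
        # alternate m ± b over an even k: mean = m, SEM = b / sqrt(k - 1)
        def seq(m, se):
            b = se * np.sqrt(k - 1)
            vals = np.full(k, float(m))
            vals[::2] += b
            vals[1::2] -= b
            return vals
        return OverlapSummary("sp", seq(mean_c, se_c), seq(mean_h, se_h))

    def test_clear_low(self):
        ra = classify_risk(self._summary(80, 1, 90, 1))
        assert (ra.tier, ra.upgraded) == ("low", False)

    def test_clear_moderate(self):
        ra = classify_risk(self._summary(30, 1, 80, 1))
        assert (ra.tier, ra.upgraded) == ("moderate", False)

    def test_clear_high(self):
        ra = classify_risk(self._summary(30, 1, 40, 1))
        assert (ra.tier, ra.upgraded) == ("high", False)

    def test_se_overlap_upgrades_conservatively(self):
        """mean_c 52 with SE 3 crosses the 50% criterion: low → moderate."""
        ra = classify_risk(self._summary(52, 3, 90, 1))
        assert (ra.tier, ra.upgraded) == ("moderate", True)

    def test_exactly_threshold_fails_strict_criterion(self):
        ra = classify_risk(self._summary(50, 0, 90, 0))
        assert ra.tier == "moderate"

    def test_mean_below_threshold_never_downgraded(self):
        # mean_h 48 with large SE would "reach" 50 from below: stays high
        ra = classify_risk(self._summary(30, 0, 48, 10))
        assert ra.tier == "high"


class TestRefugiaMap:
    def _species(self, transform, cells):
        poly = cells_polygon(transform, cells)
        return SpeciesRange("sp", poly, poly)

    def test_no_warming_everything_all(self, grid_5x5):
        futures = [ClimateGrid(grid_5x5.values.copy(), grid_5x5.transform)
                   for _ in range(3)]
        sset = assemble_scenarios(grid_5x5, futures)
        cells = [(r, c) for r in range(3) for c in range(3)]
        sp = self._species(grid_5x5.transform, cells)
        hist = compute_envelope(
            extract_cell_values(sset.baseline, sp.historical), "historical")
        rmap = refugia_map(sp, sset, hist)
        assert rmap.area_fractions["all"] == 1.0
        assert np.all(rmap.categories[:3, :3] == REFUGIA_CODES["all"])

    def test_single_cell_pushed_over_in_one_scenario(self, grid_5x5):
        cells = [(r, c) for r in range(3) for c in range(3)]
        sp = self._species(grid_5x5.transform, cells)
        futures = [ClimateGrid(grid_5x5.values.copy(), grid_5x5.transform)
                   for _ in range(3)]
        futures[1].values[0, 0] += 100.0
        sset = assemble_scenarios(grid_5x5, futures)
        hist = compute_envelope(
            extract_cell_values(sset.baseline, sp.historical), "historical")
        rmap = refugia_map(sp, sset, hist)
        assert rmap.categories[0, 0] == REFUGIA_CODES["some"]
        assert rmap.area_fractions["some"] == pytest.approx(1 / 9)
        assert rmap.area_fractions["all"] == pytest.approx(8 / 9)

    def test_matches_triple_loop_oracle_and_fractions_sum(self, grid_5x5):
        rng = np.random.default_rng(23)
        futures = [ClimateGrid(grid_5x5.values + rng.uniform(0, 3, (5, 5)),
                               grid_5x5.transform) for _ in range(6)]
        sset = assemble_scenarios(grid_5x5, futures)
        cells = [(r, c) for r in range(1, 5) for c in range(1, 5)]
        sp = self._species(grid_5x5.transform, cells)
        hist = compute_envelope(
            extract_cell_values(sset.baseline, sp.historical), "historical")
        rmap = refugia_map(sp, sset, hist)
        tm = hist.env_max
        for r, c in cells:  # exhaustive (cell, scenario) oracle
            n_below = sum(f.values[r, c] <= tm for f in sset.futures)
            expected = ("all" if n_below == sset.k
                        else "none" if n_below == 0 else "some")
            assert rmap.categories[r, c] == REFUGIA_CODES[expected]
        assert sum(rmap.area_fractions.values()) == pytest.approx(1.0, abs=1e-9)
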