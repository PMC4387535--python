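import numpy as np
import pytest

import u5mbg as m
from u5mbg.stgp import PredictionSurface


def _surface(grid, mean, lower=None, upper=None):
    mean = np.full(grid.shape, mean) if np.isscalar(mean) else mean
    lower = mean if lower is None else (np.full(grid.shape, lower)
                                        if np.isscalar(lower) else lower)
    upper = mean if upper is None else (np.full(grid.shape, upper)
                                        if np.isscalar(upper) else upper)
    return PredictionSurface(grid=grid, time=0, mean=mean, lower=lower,
                             upper=upper, interval=0.95)


class TestUnder5Surface:
    def test_constant_product(self, grid25):
        surf = _surface(grid25, 0.2)
        pop = np.full(grid25.shape, 100.0)
        mean, lo, hi = m.under5_surface(surf, pop)
        assert np.all(mean == 20.0)

    def test_bounds_scale_with_population(self, grid25):
        surf = _surface(grid25, 0.2, lower=0.15, upper=0.25)
        pop = np.full(grid25.shape, 1000.0)
        _, lo, hi = m.under5_surface(surf, pop)
        assert np.all(lo == 150.0) and np.all(hi == 250.0)

    def test_matches_scalar_loop(self, grid25):
        rng = np.random.default_rng(0)
        mean = rng.uniform(0, 1, grid25.shape)
        pop = rng.uniform(0, 500, grid25.shape)
        out, _, _ = m.under5_surface(_surface(grid25, mean), pop)
        for idx in [(0, 0), (3, 7), (24, 24)]:
            assert out[idx] == mean[idx] * pop[idx]

    def test_grid_mismatch_rejected(self, grid25):
        surf = _surface(grid25, 0.2)
        with pytest.raises(ValueError, match="shape"):
            m.under5_surface(surf, np.ones((3, 3)))


class TestAdjustments:
    def test_uniform_national_total_exact(self):
        pop = np.full((10, 10), 1e4)      # national 1e6
        out = m.uniform_adjustment(pop, 0.175)
        assert out.sum() == pytest.approx(175_000.0, abs=1e-9)

    def test_uniform_zero_proportion(self):
        assert np.all(m.uniform_adjustment(np.ones((4, 4)), 0.0) == 0.0)

    def test_uniform_preserves_population_shares(self):
        rng = np.random.default_rng(1)
        pop = rng.uniform(0, 100, (6, 6))
        out = m.uniform_adjustment(pop, 0.3)
        np.testing.assert_allclose(out / out.sum(), pop / pop.sum())

    def test_census_per_zone_totals(self):
        pop = np.ones((4, 4)) * 10
        zones = np.zeros((4, 4), int)
        zones[:, 2:] = 1
        out = m.census_adjustment(pop, {0: 0.12, 1: 0.22}, zones)
        assert out[zones == 0].sum() == pytest.approx(0.12 * 80)
        assert out[zones == 1].sum() == pytest.approx(0.22 * 80)

    def test_census_equals_uniform_when_props_constant(self):
        rng = np.random.default_rng(2)
        pop = rng.uniform(0, 50, (5, 5))
        zones = rng.integers(0, 3, (5, 5))
        a = m.census_adjustment(pop, {0: 0.18, 1: 0.18, 2: 0.18}, zones)
        b = m.uniform_adjustment(pop, 0.18)
        np.testing.assert_allclose(a, b)

    def test_census_missing_zone_rejected(self):
        with pytest.raises(ValueError, match="zone 1"):
            m.census_adjustment(np.ones((2, 2)), {0: 0.1},
                                np.array([[0, 0], [1, 1]]))


class TestZonalAggregate:
    def test_single_zone_is_total(self):
        rng = np.random.default_rng(3)
        count = rng.uniform(0, 10, (5, 5))
        out = m.zonal_aggregate(count, np.zeros((5, 5), int))
        assert out[0] == pytest.approx(count.sum())

    def test_conservation_across_zones(self):
        rng = np.random.default_rng(4)
        count = rng.uniform(0, 10, (8, 8))
        zones = rng.integers(0, 4, (8, 8))
        out = m.zonal_aggregate(count, zones)
        assert sum(out.values()) == pytest.approx(count.sum(), rel=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        count = rng.uniform(0, 10, (6, 6))
        zones = rng.integers(0, 3, (6, 6))
        out = m.zonal_aggregate(count, zones)
        for z in range(3):
            acc = 0.0
            for i in range(6):
                for j in range(6):
                    if zones[i, j] == z:
                        acc += count[i, j]
            assert out[z] == pytest.approx(acc, rel=1e-12)

    def test_nan_cells_excluded_but_zones_kept(self):
        count = np.ones((3, 3))
        count[0, 0] = np.nan
        out = m.zonal_aggregate(count, np.zeros((3, 3), int))
        assert out[0] == 8.0


class TestUnprotected:
    def test_national_vaccination_identity(self):
        """39.7% basic-vaccination coverage leaves 60.3% of under-fives
        unprotected."""
        N = 1_000_000.0
        est = m.unprotected({0: (N, N, N)}, {0: 0.397}, "mbg")
        assert est[0].unprotected[0] == pytest.approx(0.603 * N)

    def test_full_coverage_zero_gap(self):
        est = m.unprotected({0: (100.0, 90.0, 110.0)}, {0: 1.0}, "mbg")
        assert est[0].unprotected == (0.0, 0.0, 0.0)

    def test_zero_coverage_everything_unprotected(self):
        est = m.unprotected({0: (100.0, 90.0, 110.0)}, {0: 0.0}, "mbg")
        assert est[0].unprotected == (100.0, 90.0, 110.0)

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            m.unprotected({0: (1.0, 1.0, 1.0)}, {0: 1.4}, "mbg")


class TestCompareMethods:
    def _est(self, method, totals):
        return [m.ZonalEstimate(zone_id=z, method=method, under5=(v, v, v))
                for z, v in totals.items()]

    def test_identical_methods_zero_differences(self):
        totals = {0: 100.0, 1: 250.0}
        tbl = m.compare_methods({"mbg": self._est("mbg", totals),
                                 "un_uniform": self._est("un_uniform", totals)})
        assert np.allclose(tbl["abs_diff"], 0.0)
        assert np.allclose(tbl["pct_diff"], 0.0)

    def test_percentage_difference_formula(self):
        tbl = m.compare_methods({"mbg": self._est("mbg", {0: 100.0}),
                                 "census": self._est("census", {0: 110.0})})
        assert tbl["pct_diff"].iloc[0] == pytest.approx(10.0)

    def test_high_proportion_zones_top_gap_ranking(self):
        """Zones where the mapped proportion exceeds the flat national figure
        dominate the mbg-vs-uniform gap ranking (the northern-states
        pattern)."""
        grid = m.RasterGrid(0, 0, 1.0, 10, 10)
        zones = m.gen_zone_raster(grid, 2, 1)     # south (0) / north (1)
        pop = np.full(grid.shape, 100.0)
        prop = np.where(zones == 1, 0.24, 0.15)   # elevated in the north
        surf = _surface(grid, prop)
        u5, _, _ = m.under5_surface(surf, pop)
        per_method = {
            "mbg": {z: (v, v, v) for z, v in m.zonal_aggregate(u5, zones).items()},
            "un_uniform": {z: (v, v, v) for z, v in m.zonal_aggregate(
                m.uniform_adjustment(pop, 0.175), zones).items()},
        }
        ests = {meth: m.unprotected(d, {0: 0.5, 1: 0.5}, meth)
                for meth, d in per_method.items()}
        tbl = m.compare_methods(ests)
        top = tbl[tbl["gap_rank"] == 1].iloc[0]
        assert top["zone_id"] == 1

    def test_mismatched_zone_sets_rejected(self):
        with pytest.raises(ValueError, match="zone sets"):
            m.compare_methods({"mbg": self._est("mbg", {0: 1.0}),
                               "census": self._est("census", {0: 1.0, 1: 2.0})})
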