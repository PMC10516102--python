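"""The simulated landscapes: determinism, correlation structure, ground truth."""

import numpy as np
import pytest

from sdmpipe import (
    LANDCOVER_ALLOWED,
    LANDCOVER_CLASSES,
    PA_CATEGORIES,
    ScenarioShift,
    SyntheticConfig,
    VirtualSpecies,
    default_scenario_shifts,
    generate_climate,
    generate_future,
    generate_landcover,
    generate_protected_areas,
    make_virtual_species,
    sample_presences,
)
from sdmpipe.raster import RasterGrid


class TestGenerateClimate:
    def test_same_seed_bit_identical(self):
        a = generate_climate(SyntheticConfig(seed=3))
        b = generate_climate(SyntheticConfig(seed=3))
        for name in a.names:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_nineteen_layers_by_default(self):
        assert generate_climate(SyntheticConfig(seed=0)).n_layers == 19

    def test_identity_mixing_white_noise_uncorrelated(self):
        # 100x100 = 10,000 cells, no smoothing, independent variables
        cfg = SyntheticConfig(
            grid_rows=100, grid_cols=100, n_climate_vars=4,
            spatial_range=0.0, mixing=np.eye(4), seed=5,
        )
        stack = generate_climate(cfg)
        X, _, _ = stack.to_table()
        r = np.corrcoef(X.T)
        off = r[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_mixing_matrix_is_respected(self):
        target = np.array([[1.0, 0.8], [0.8, 1.0]])
        cfg = SyntheticConfig(
            grid_rows=100, grid_cols=100, n_climate_vars=2,
            spatial_range=0.0, mixing=target, seed=5,
        )
        X, _, _ = generate_climate(cfg).to_table()
        assert abs(np.corrcoef(X.T)[0, 1] - 0.8) < 0.05

    def test_non_positive_definite_mixing_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PD
        with pytest.raises(ValueError, match="mixing"):
            generate_climate(
                SyntheticConfig(grid_rows=10, grid_cols=10, n_climate_vars=2, mixing=bad)
            )


class TestGenerateFuture:
    def test_identity_shift_is_noop(self, small_climate):
        shift = ScenarioShift("rcp45", "gcm1")
        fut = generate_future(small_climate, shift)
        for name in small_climate.names:
            np.testing.assert_array_equal(fut[name].values, small_climate[name].values)

    def test_additive_delta_moves_mean_exactly(self, small_climate):
        shift = ScenarioShift("rcp45", "gcm1", additive_deltas={"bio01": 2.0})
        fut = generate_future(small_climate, shift)
        assert np.isclose(
            fut["bio01"].values.mean() - small_climate["bio01"].values.mean(), 2.0
        )

    def test_unknown_variable_rejected(self, small_climate):
        with pytest.raises(KeyError, match="unknown variable"):
            generate_future(small_climate, ScenarioShift("x", "g", additive_deltas={"bogus": 1}))

    def test_two_scenarios_times_five_gcms(self):
        shifts = default_scenario_shifts()
        assert len(shifts) == 10
        assert {s.scenario_id for s in shifts} == {"rcp45", "rcp85"}
        for scen in ("rcp45", "rcp85"):
            assert sum(s.scenario_id == scen for s in shifts) == 5


class TestVirtualSpecies:
    def test_maximum_at_optimum_cell(self, small_climate):
        vs = VirtualSpecies("v", ("bio01", "bio12"), (0.1, -0.2), (0.4, 0.4))
        suit = make_virtual_species(small_climate, vs)
        assert np.isclose(np.nanmax(suit.values), 1.0)
        assert np.all((suit.values >= 0) & (suit.values <= 1))

    def test_infinite_breadth_gives_uniform_suitability(self, small_climate):
        vs = VirtualSpecies("v", ("bio01",), (0.0,), (1e9,))
        suit = make_virtual_species(small_climate, vs)
        assert np.nanstd(suit.values) < 1e-6

    def test_halving_breadth_never_raises_suitability(self, small_climate):
        wide = VirtualSpecies("v", ("bio01", "bio12"), (0.1, -0.2), (0.5, 0.5))
        narrow = VirtualSpecies("v", ("bio01", "bio12"), (0.1, -0.2), (0.25, 0.25))
        s_wide = make_virtual_species(small_climate, wide).values
        s_narrow = make_virtual_species(small_climate, narrow).values
        assert np.all(s_narrow <= s_wide + 1e-12)

    def test_empty_niche_rejected(self):
        with pytest.raises(ValueError, match="niche_vars"):
            VirtualSpecies("v", (), (), ())


class TestSamplePresences:
    def test_requested_count_returned(self, small_climate):
        vs = VirtualSpecies("v", ("bio01",), (0.0,), (0.4,))
        suit = make_virtual_species(small_climate, vs)
        pts = sample_presences(suit, 200, seed=1)
        assert pts.n == 200
        assert np.all(pts.labels == 1)

    def test_point_mass_suitability_puts_all_points_there(self, unit_grid):
        v = np.zeros((8, 8))
        v[3, 5] = 1.0
        pts = sample_presences(unit_grid.with_values(v), 50, seed=2)
        r, c = unit_grid.cell_of(pts.x, pts.y)
        assert np.all(r == 3) and np.all(c == 5)

    def test_uniform_suitability_is_multinomially_uniform(self, unit_grid):
        from scipy.stats import chisquare

        pts = sample_presences(unit_grid, 10_000, seed=3)
        r, c = unit_grid.cell_of(pts.x, pts.y)
        counts = np.bincount(r * 8 + c, minlength=64)
        assert chisquare(counts).pvalue > 0.001

    def test_all_zero_suitability_rejected(self, unit_grid):
        with pytest.raises(ValueError, match="zero"):
            sample_presences(unit_grid.with_values(np.zeros((8, 8))), 5, seed=0)


class TestProtectedAreas:
    def make_mask(self, n=30):
        return RasterGrid(np.ones((n, n)), x0=0.0, y0=float(n), cell_size=1.0)

    def test_zero_pas_gives_empty_list(self):
        assert generate_protected_areas(self.make_mask(), 0, (2, 5), seed=0) == []

    def test_footprints_connected_and_inside_mask(self):
        mask = self.make_mask()
        hole = mask.values.copy()
        hole[10:20, 10:20] = 0  # carve a hole the PAs must avoid
        mask = mask.with_values(hole)
        pas = generate_protected_areas(mask, 12, (3, 10), seed=4)
        for pa in pas:
            assert 3 <= pa.n_cells <= 10
            assert all(hole[r, c] > 0 for r, c in pa.cells)
            # connectedness: breadth-first reachability over rook moves
            cells = set(map(tuple, pa.cells))
            seen, stack = {tuple(pa.cells[0])}, [tuple(pa.cells[0])]
            while stack:
                r, c = stack.pop()
                for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                    if nb in cells and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            assert seen == cells

    def test_categories_from_the_three_classes(self):
        pas = generate_protected_areas(self.make_mask(), 20, (1, 4), seed=5)
        assert {pa.category for pa in pas} <= set(PA_CATEGORIES)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_protected_areas(self.make_mask(10), 1, (5, 200), seed=0)


class TestLandcover:
    def test_single_class_rejected(self, small_climate):
        with pytest.raises(ValueError, match="2 land-cover classes"):
            generate_landcover(small_climate, classes=("forest",))

    def test_codes_within_declared_class_set(self, small_climate):
        lc = generate_landcover(small_climate, seed=1)
        assert set(np.unique(lc.values)) <= set(range(len(LANDCOVER_CLASSES)))

    def test_warming_monotonically_grows_disallowed_class(self, small_climate):
        from sdmpipe import generate_future

        disallowed = len(LANDCOVER_CLASSES) - 1
        fracs = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            shift = ScenarioShift(
                "s", "g", additive_deltas={n: delta for n in small_climate.names}
            )
            lc = generate_landcover(generate_future(small_climate, shift), seed=1)
            fracs.append(np.mean(lc.values == disallowed))
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0]

    def test_allowed_classes_are_the_five_forest_types(self):
        assert len(LANDCOVER_ALLOWED) == 5
        assert all(c in LANDCOVER_CLASSES for c in LANDCOVER_ALLOWED)
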