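"""Gap analysis, representation targets, PA randomization null model."""

import numpy as np
import pytest

from sdmpipe import (
    PAUnit,
    RasterGrid,
    achieved_protection,
    classify_gap,
    filter_pas,
    null_model_test,
    protected_richness_proportion,
    randomize_pa,
    representation_target,
)


def pa_from_cells(cells, pa_id=1, category="IPA", cell_area=1.0):
    cells = np.asarray(cells, dtype=int)
    return PAUnit(pa_id=pa_id, category=category, cells=cells, area=len(cells) * cell_area)


def grid(values):
    v = np.asarray(values, float)
    return RasterGrid(v, y0=float(v.shape[0]))


class TestFilterPAs:
    def test_small_pa_excluded(self):
        mask = np.ones((10, 10), bool)
        pa = pa_from_cells([(0, 0)], cell_area=49.0)  # 49 km² < 50
        assert filter_pas([pa], mask, 49.0) == []

    def test_clip_before_threshold(self):
        # 60 km² PA with only 30 km² inside the mask → excluded
        mask = np.zeros((10, 10), bool)
        mask[:, :5] = True
        cells = [(0, c) for c in range(4, 6)]  # one in, one out
        pa = pa_from_cells(cells, cell_area=30.0)
        assert filter_pas([pa], mask, 30.0) == []

    def test_default_min_area_is_50(self):
        mask = np.ones((5, 5), bool)
        keep = pa_from_cells([(0, 0)], pa_id=1, cell_area=50.0)
        drop = pa_from_cells([(1, 1)], pa_id=2, cell_area=49.9)
        out = filter_pas([keep, drop], mask, np.where(np.arange(25).reshape(5, 5) == 0, 50.0, 49.9))
        assert [p.pa_id for p in out] == [1]


class TestRepresentationTarget:
    def test_restricted_range_anchor(self):
        assert representation_target(800.0) == 100.0

    def test_widespread_anchor(self):
        assert representation_target(500_000.0) == 10.0

    def test_log_midpoint_is_55(self):
        mid = float(np.sqrt(1_000.0 * 250_000.0))
        assert representation_target(mid) == pytest.approx(55.0)

    def test_continuous_and_non_increasing(self):
        areas = np.logspace(2, 7, 300)
        targets = np.array([representation_target(a) for a in areas])
        assert np.all(np.diff(targets) <= 1e-12)
        assert np.all((targets >= 10.0) & (targets <= 100.0))
        # continuity at the anchors
        assert representation_target(1_000.0) == pytest.approx(100.0)
        assert representation_target(1_000.0001) == pytest.approx(100.0, abs=1e-4)
        assert representation_target(250_000.0) == pytest.approx(10.0)

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            representation_target(0.0)


class TestAchievedProtection:
    def test_fully_inside(self):
        v = np.zeros((5, 5))
        v[1:3, 1:3] = 1
        pa = pa_from_cells([(r, c) for r in range(1, 3) for c in range(1, 3)])
        assert achieved_protection(grid(v), [pa], 1.0) == 100.0

    def test_disjoint(self):
        v = np.zeros((5, 5))
        v[0, 0] = 1
        pa = pa_from_cells([(4, 4)])
        assert achieved_protection(grid(v), [pa], 1.0) == 0.0

    def test_overlapping_pas_counted_once(self):
        v = np.ones((4, 4))
        cells = [(0, 0), (0, 1)]
        pa1, pa2 = pa_from_cells(cells, 1), pa_from_cells(cells, 2)
        both = achieved_protection(grid(v), [pa1, pa2], 1.0)
        single = achieved_protection(grid(v), [pa1], 1.0)
        assert both == single == pytest.approx(100 * 2 / 16)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            achieved_protection(grid(np.zeros((3, 3))), [], 1.0)


class TestClassifyGap:
    # hand-enumerated attainment table across all four classes
    @pytest.mark.parametrize(
        "achieved,target,expected",
        [
            (10.0, 10.0, "P"),     # attainment 100
            (9.0, 10.0, "P"),      # 90, boundary inclusive
            (8.99, 10.0, "PP"),    # just under 90
            (7.5, 10.0, "PP"),     # 75
            (7.0, 10.0, "PP"),     # 70, boundary inclusive
            (6.99, 10.0, "G"),     # just under 70
            (5.0, 10.0, "G"),      # 50
            (2.0, 10.0, "G"),      # 20, boundary inclusive
            (1.99, 10.0, "NP"),    # just under 20
            (0.0, 10.0, "NP"),
            (100.0, 100.0, "P"),
            (90.0, 100.0, "P"),
            (89.0, 100.0, "PP"),
            (70.0, 100.0, "PP"),
            (69.0, 100.0, "G"),
            (20.0, 100.0, "G"),
            (15.0, 100.0, "NP"),
            (55.0, 55.0, "P"),
            (44.0, 55.0, "PP"),    # 80
            (11.0, 55.0, "G"),     # 20
        ],
    )
    def test_hand_enumerated_table(self, achieved, target, expected):
        assert classify_gap(achieved, target) == expected

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, t = rng.uniform(0, 100), rng.uniform(1, 100)
            k = rng.uniform(0.1, 10)
            assert classify_gap(a, t) == classify_gap(a * k, t * k)


class TestRandomizePA:
    def test_domain_equal_to_pa_forces_identity(self):
        cells = [(r, c) for r in range(3) for c in range(3)]
        pa = pa_from_cells(cells)
        domain = np.ones((3, 3), bool)
        out = randomize_pa(pa, domain, np.random.default_rng(0))
        np.testing.assert_array_equal(np.sort(out.cells, axis=0), np.sort(pa.cells, axis=0))

    def test_cell_count_and_shape_preserved(self):
        rng = np.random.default_rng(1)
        cells = [(0, 0), (0, 1), (1, 1), (2, 1)]  # an L-tetromino
        pa = pa_from_cells(cells)
        domain = np.ones((20, 20), bool)
        for _ in range(20):
            out = randomize_pa(pa, domain, rng)
            assert out.n_cells == pa.n_cells
            rel = out.cells - out.cells.min(axis=0)
            np.testing.assert_array_equal(
                np.sort(rel.tolist()), np.sort((pa.cells - pa.cells.min(axis=0)).tolist())
            )
            assert domain[out.cells[:, 0], out.cells[:, 1]].all()

    def test_placements_uniform_on_open_domain(self):
        from scipy.stats import chisquare

        rng = np.random.default_rng(2)
        pa = pa_from_cells([(0, 0)])
        domain = np.ones((5, 5), bool)
        draws = [tuple(randomize_pa(pa, domain, rng).cells[0]) for _ in range(1000)]
        counts = np.bincount([r * 5 + c for r, c in draws], minlength=25)
        assert chisquare(counts).pvalue > 0.001

    def test_impossible_placement_rejected(self):
        pa = pa_from_cells([(0, 0), (0, 5)])
        with pytest.raises(ValueError, match="placement"):
            randomize_pa(pa, np.ones((3, 3), bool), np.random.default_rng(0))


class TestNullModel:
    def test_constant_richness_is_never_effective(self):
        pa = pa_from_cells([(2, 2), (2, 3)])
        rich = grid(np.full((8, 8), 3.0))
        res = null_model_test(pa, rich, n=99, rng=np.random.default_rng(0))
        assert res.p_value == 1.0
        assert not res.effective

    def test_unique_hotspot_gives_minimal_p(self):
        # the domain is large enough that none of the 999 random
        # placements re-covers the single hotspot cell, so only the
        # observed placement reaches the observed statistic
        v = np.zeros((100, 100))
        v[4, 4] = 5.0
        pa = pa_from_cells([(4, 4)])
        res = null_model_test(pa, grid(v), n=999, rng=np.random.default_rng(1))
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.effective

    def test_type_one_error_controlled_on_structureless_richness(self):
        # richness is a random permutation of values: across many simulated
        # PAs the fraction declared effective should stay near alpha
        rng = np.random.default_rng(3)
        rich = grid(rng.permutation(np.arange(900)).reshape(30, 30) / 100.0)
        domain = np.ones((30, 30), bool)
        false_pos = 0
        n_pas = 200
        for i in range(n_pas):
            r, c = rng.integers(0, 28), rng.integers(0, 28)
            pa = pa_from_cells([(r, c), (r + 1, c), (r, c + 1)])
            res = null_model_test(pa, rich, domain, n=199, rng=rng)
            false_pos += res.effective
        assert false_pos / n_pas <= 0.07

    def test_sum_statistic_flag(self):
        v = np.zeros((6, 6))
        v[0, 0] = 2.0
        pa = pa_from_cells([(0, 0), (0, 1)])
        res = null_model_test(pa, grid(v), n=9, rng=np.random.default_rng(4), stat="sum")
        assert res.observed_stat == 2.0


class TestProtectedRichnessProportion:
    def test_full_coverage_is_100(self):
        rich = grid(np.arange(16).reshape(4, 4))
        pa = pa_from_cells([(r, c) for r in range(4) for c in range(4)])
        assert protected_richness_proportion(rich, [pa]) == 100.0

    def test_zero_richness_cells_only(self):
        v = np.ones((4, 4))
        v[0, 0] = 0
        pa = pa_from_cells([(0, 0)])
        assert protected_richness_proportion(grid(v), [pa]) == 0.0

    def test_matches_cell_sum_oracle(self):
        rng = np.random.default_rng(5)
        rich = grid(rng.integers(0, 5, (8, 8)))
        cells = [(int(r), int(c)) for r, c in rng.integers(0, 8, (10, 2))]
        pa = pa_from_cells(sorted(set(cells)))
        expected = 100 * sum(rich.values[r, c] for r, c in set(cells)) / rich.values.sum()
        assert protected_richness_proportion(rich, [pa]) == pytest.approx(expected)

    def test_zero_total_richness_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            protected_richness_proportion(grid(np.zeros((3, 3))), [])
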