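import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phanerodiv import (
    DecayParams,
    DiversityGrid,
    Transect,
    distance_decay_similarity,
    find_peaks,
    find_troughs,
    integrate_alpha_profile,
    integrate_global,
    integrate_transect,
    jaccard_to_simpson,
    rasterize_points,
    trace_transect,
)
from phanerodiv._geo import bresenham_wrap, haversine_km
from phanerodiv.world import LAND, OCEAN, SHELF, AnnotatedGrid

DEFAULTS = DecayParams()


def blank_grid(nlat=30, nlon=60, res=6.0, cls=OCEAN):
    return DiversityGrid(
        diversity=np.full((nlat, nlon), np.nan),
        class_map=np.full((nlat, nlon), cls, dtype=np.int8),
        age_map=np.full((nlat, nlon), np.nan),
        resolution=res,
    )


class TestDecayMath:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (0.0, 1.0),
            (1000.0, 0.06 + 0.94 * math.exp(-2.4)),
            (2e4, 0.06),
        ],
    )
    def test_distance_decay_fitted_curve(self, d, expected):
        np.testing.assert_allclose(distance_decay_similarity(d, DEFAULTS), expected, atol=1e-12)

    @pytest.mark.parametrize(
        "J,a,b,expected",
        [
            (0.0, 10, 5, 0.0),
            (0.5, 10, 5, 1.0),  # R=2: (1+2)*0.5/1.5
            (0.9, 30, 10, 1.8 / 1.9),  # R=3 overflows -> recompute with R=1
        ],
    )
    def test_jaccard_to_simpson(self, J, a, b, expected):
        np.testing.assert_allclose(jaccard_to_simpson(J, a, b), expected)

    @given(st.floats(0, 1), st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=100, deadline=None)
    def test_simpson_bounded_and_shared_count_valid(self, J, a, b):
        V = float(jaccard_to_simpson(J, a, b))
        assert 0.0 <= V <= 1.0 + 1e-12
        assert V * min(a, b) <= min(a, b) + 1e-9

    def test_integrate_alpha_profile_hand_example(self):
        np.testing.assert_allclose(
            integrate_alpha_profile([10, 6, 3], [0.8, 0.5]), 10 + 0.2 * 6 + 0.5 * 3
        )

    def test_full_overlap_and_disjoint_limits(self):
        alphas = [9, 5, 2]
        assert integrate_alpha_profile(alphas, [1.0, 1.0]) == 9.0
        assert integrate_alpha_profile(alphas, [0.0, 0.0]) == 16.0


class TestUnionSetOracle:
    """The transect integral equals the cardinality of explicit genus sets.

    For a descending richness profile with integer shared counts satisfying
    the nesting assumption (genera present two cells apart are present in
    between), the union of the constructed communities has exactly the
    cardinality the integration formula yields.
    """

    def _random_instance(self, rng):
        L = rng.integers(2, 8)
        alphas = np.sort(rng.integers(1, 60, size=L))[::-1]
        shared = np.array([rng.integers(0, alphas[n + 1] + 1) for n in range(L - 1)])
        V = shared / alphas[1:]
        return alphas, shared, V

    def _build_sets(self, alphas, shared, rng):
        next_genus = alphas[0]
        comms = [set(range(alphas[0]))]
        for n in range(len(alphas) - 1):
            keep = set(rng.choice(sorted(comms[n]), size=shared[n], replace=False).tolist())
            fresh = set(range(next_genus, next_genus + alphas[n + 1] - shared[n]))
            next_genus += alphas[n + 1] - shared[n]
            comms.append(keep | fresh)
        return comms

    def test_union_cardinality_matches_formula(self):
        rng = np.random.default_rng(1234)
        for _ in range(250):
            alphas, shared, V = self._random_instance(rng)
            comms = self._build_sets(alphas, shared, rng)
            # constructed sets realize the requested Simpson overlaps
            for n in range(len(alphas) - 1):
                assert len(comms[n] & comms[n + 1]) == shared[n]
                assert len(comms[n + 1]) == alphas[n + 1]
            # nesting: genera present in n and n+2 are present in n+1
            for n in range(len(alphas) - 2):
                assert (comms[n] & comms[n + 2]) <= comms[n + 1]
            union = set().union(*comms)
            np.testing.assert_allclose(integrate_alpha_profile(alphas, V), len(union))


class TestPeaksAndTroughs:
    def test_single_bump_yields_argmax(self):
        g = blank_grid()
        g.diversity[10:13, 20:23] = [[1, 2, 1], [2, 9, 2], [1, 2, 1]]
        assert find_peaks(g, DEFAULTS) == [(11, 21)]

    def test_plateau_peak_is_middle_cell(self):
        g = blank_grid()
        g.diversity[5, 10:17] = [1, 2, 5, 5, 5, 2, 1]
        assert find_peaks(g, DEFAULTS) == [(5, 13)]

    def test_quantile_filter_on_eight_maxima(self):
        g = blank_grid()
        # 8 isolated bumps with values 1..8; 0.75-quantile of maxima is 6.25
        spots = [(3, 5), (3, 15), (3, 25), (3, 35), (12, 5), (12, 15), (12, 25), (12, 35)]
        for v, (r, c) in enumerate(spots, start=1):
            g.diversity[r, c] = v
        peaks = find_peaks(g, DEFAULTS)
        assert peaks == [(12, 25), (12, 35)]

    def test_empty_grid_has_no_peaks(self):
        assert find_peaks(blank_grid(), DEFAULTS) == []

    def test_longitude_wraparound_neighbours(self):
        g = blank_grid()
        g.diversity[8, 0] = 5.0
        g.diversity[8, 59] = 9.0  # larger neighbour across the antimeridian
        assert find_peaks(g, DEFAULTS) == [(8, 59)]

    def test_troughs_are_age_zero_ocean_cells(self):
        g = blank_grid()
        g.age_map[4, [1, 7, 30]] = 0.0
        g.age_map[5, 2] = 12.0
        g.class_map[4, 30] = LAND
        assert find_troughs(g) == [(4, 1), (4, 7)]


class TestBresenham:
    def test_straight_and_diagonal(self):
        assert bresenham_wrap(0, 0, 0, 3, 60) == [(0, 0), (0, 1), (0, 2), (0, 3)]
        assert bresenham_wrap(0, 0, 3, 3, 60) == [(0, 0), (1, 1), (2, 2), (3, 3)]

    def test_antimeridian_takes_short_way(self):
        path = bresenham_wrap(5, 1, 5, 58, 60)
        assert len(path) == 4  # 1 -> 0 -> 59 -> 58
        assert path == [(5, 1), (5, 0), (5, 59), (5, 58)]


class TestTraceTransect:
    def test_adjacent_peak_trough(self):
        # high-latitude row so the 6-degree step stays under the 555 km cap
        g = blank_grid()
        g.diversity[2, 20] = 8.0
        g.age_map[2, 21] = 0.0
        t = trace_transect((2, 20), find_troughs(g), g, DEFAULTS)
        assert t is not None and len(t.cells) == 2

    def test_land_fraction_rejection(self):
        g = blank_grid()
        g.diversity[10, 20] = 8.0
        g.age_map[10, 29] = 0.0
        g.class_map[10, 22:25] = LAND  # 3 land cells on a 10-cell path
        assert trace_transect((10, 20), find_troughs(g), g, DEFAULTS) is None

    def test_truncation_to_555_km(self):
        g = blank_grid(res=6.0)
        # near-equatorial row: 6 deg of longitude is ~660 km, so only the
        # first step under 555 km cumulative survives... use a finer grid
        g2 = blank_grid(nlat=90, nlon=180, res=2.0)
        g2.diversity[45, 20] = 8.0  # ~1 deg S
        g2.age_map[45, 40] = 0.0  # 40 deg away along the row
        t = trace_transect((45, 20), find_troughs(g2), g2, DEFAULTS)
        assert t is not None
        assert t.step_km.sum() <= DEFAULTS.truncation_km
        # adding one more cell would break the cap
        lat = 90.0 - (45 + 0.5) * 2.0
        step = haversine_km(lat, 0.0, lat, 2.0)
        assert t.step_km.sum() + step > DEFAULTS.truncation_km

    def test_raises_without_troughs(self):
        g = blank_grid()
        g.diversity[10, 20] = 8.0
        with pytest.raises(ValueError):
            trace_transect((10, 20), [], g, DEFAULTS)

    def test_unpopulated_cells_contribute_background(self):
        g = blank_grid()
        g.diversity[2, 20] = 8.0
        g.age_map[2, 23] = 0.0
        t = trace_transect((2, 20), find_troughs(g), g, DEFAULTS)
        np.testing.assert_allclose(t.alphas, [8.0, 1.0, 1.0, 1.0])


def random_transects(rng, n, spread=60.0):
    out = []
    for _ in range(n):
        L = rng.integers(2, 6)
        alphas = np.sort(rng.uniform(1, 50, L))[::-1]
        steps = rng.uniform(10, 300, L - 1)
        lat = rng.uniform(-spread, spread)
        lon = rng.uniform(-180, 180)
        out.append(
            Transect(
                cells=[(int(rng.integers(0, 30)), int(rng.integers(0, 60)))] * L,
                alphas=alphas,
                step_km=steps,
                peak_latlon=(lat, lon),
                trough_latlon=(lat, lon),
            )
        )
    return out


class TestIntegration:
    def test_transect_bounds(self):
        rng = np.random.default_rng(7)
        for t in random_transects(rng, 100):
            g = integrate_transect(t, DEFAULTS)
            assert t.alphas[0] - 1e-9 <= g <= t.alphas.sum() + 1e-9

    def test_zigzag_hand_example(self):
        """gamma_total = gamma_1 + (1 - V) gamma_2 with V from the peak distance."""
        t1 = Transect([(0, 0)], np.array([20.0]), np.array([]), (0.0, 0.0), (0.0, 0.0), gamma=20.0)
        t2 = Transect([(0, 1)], np.array([10.0]), np.array([]), (0.0, 10.0), (0.0, 10.0), gamma=10.0)
        d = haversine_km(0.0, 0.0, 0.0, 10.0)
        J = 0.06 + 0.94 * math.exp(-0.0024 * d)
        V = min((1 + 2.0) * J / (1 + J), 2 * J / (1 + J) if (1 + 2.0) * J / (1 + J) > 1 else 1.0)
        expected = 20.0 + (1.0 - V) * 10.0
        np.testing.assert_allclose(integrate_global([t1, t2], DEFAULTS), expected)

    def test_single_transect_base_case(self):
        t = Transect([(0, 0)], np.array([20.0]), np.array([]), (0.0, 0.0), (0.0, 0.0), gamma=20.0)
        assert integrate_global([t], DEFAULTS) == 20.0

    def test_global_bounds_and_duplicate_invariance(self):
        rng = np.random.default_rng(11)
        ts = random_transects(rng, 25)
        for t in ts:
            integrate_transect(t, DEFAULTS)
        total = integrate_global(ts, DEFAULTS)
        gammas = np.array([t.gamma for t in ts])
        assert gammas.max() - 1e-9 <= total <= gammas.sum() + 1e-9
        # a duplicate at a coincident peak is fully absorbed
        best = max(ts, key=lambda t: t.gamma)
        dup = Transect(best.cells, best.alphas, best.step_km, best.peak_latlon, best.trough_latlon, gamma=best.gamma)
        np.testing.assert_allclose(integrate_global(ts + [dup], DEFAULTS), total)

    def test_truncation_extension_never_decreases_gamma(self):
        rng = np.random.default_rng(23)
        wide = DecayParams(truncation_km=1110.0)
        g = blank_grid(nlat=90, nlon=180, res=2.0)
        for _ in range(40):
            r = int(rng.integers(30, 60))
            c = int(rng.integers(10, 170))
            g.diversity[r, c] = float(rng.uniform(5, 50))
            g.age_map[r, (c + 10) % 180] = 0.0
        troughs = find_troughs(g)
        for pk in zip(*np.where(np.isfinite(g.diversity))):
            t_short = trace_transect(pk, troughs, g, DEFAULTS)
            t_long = trace_transect(pk, troughs, g, wide)
            if t_short is None or t_long is None:
                continue
            assert integrate_transect(t_long, wide) >= integrate_transect(t_short, DEFAULTS) - 1e-9


class TestRasterize:
    def test_single_point_fills_its_cell_with_radius_zero(self):
        grid = AnnotatedGrid(
            class_map=np.full((30, 60), OCEAN, dtype=np.int8),
            age_map=np.full((30, 60), np.nan),
        )
        out = rasterize_points([0.0], [0.0], [7.0], [OCEAN], grid, 6.0, radius_km=0.0)
        assert np.nansum(out.diversity) == 7.0
        assert np.isfinite(out.diversity).sum() == 1

    def test_classes_interpolate_independently(self):
        cm = np.full((30, 60), OCEAN, dtype=np.int8)
        cm[:, :30] = SHELF
        grid = AnnotatedGrid(class_map=cm, age_map=np.full((30, 60), np.nan))
        out = rasterize_points(
            [0.0, 0.0], [-3.0, 3.0], [40.0, 4.0], [SHELF, OCEAN], grid, 6.0, radius_km=800.0
        )
        shelf_vals = out.diversity[cm == SHELF]
        ocean_vals = out.diversity[cm == OCEAN]
        assert set(np.unique(shelf_vals[np.isfinite(shelf_vals)])) == {40.0}
        assert set(np.unique(ocean_vals[np.isfinite(ocean_vals)])) == {4.0}

    def test_cell_mean_of_cohabiting_points(self):
        grid = AnnotatedGrid(
            class_map=np.full((30, 60), OCEAN, dtype=np.int8),
            age_map=np.full((30, 60), np.nan),
        )
        out = rasterize_points([1.0, 2.0], [1.0, 2.0], [4.0, 6.0], [OCEAN, OCEAN], grid, 6.0, radius_km=0.0)
        assert np.nansum(out.diversity) == 5.0

    def test_trough_backfill_sets_unit_richness(self):
        am = np.full((30, 60), np.nan)
        am[3, 3] = 0.0
        grid = AnnotatedGrid(class_map=np.full((30, 60), OCEAN, dtype=np.int8), age_map=am)
        out = rasterize_points([], [], [], [], grid, 6.0)
        assert out.diversity[3, 3] == 1.0
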