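import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegstab import (
    SimConfig,
    TrendMap,
    composite_index,
    ecosystem_state,
    mann_kendall,
    mann_kendall_p,
    morans_i,
    moving_window_metrics,
    rook_weights,
    simulate_stack,
    theil_sen,
    trend_map,
    window_trend_permutation_p,
)


def brute_force_theil_sen(y):
    slopes = []
    for i in range(len(y) - 1):
        for j in range(i + 1, len(y)):
            slopes.append((y[j] - y[i]) / (j - i))
    return float(np.median(slopes))


def brute_force_morans_i(layer, w_dense):
    z = layer.ravel() - layer.mean()
    n = z.size
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i, j] * z[i] * z[j]
            s0 += w_dense[i, j]
    return n / s0 * num / np.sum(z**2)


class TestTheilSen:
    def test_exact_line(self):
        assert theil_sen(2.0 * np.arange(10) + 1.0) == pytest.approx(2.0)

    def test_three_points(self):
        # pairwise slopes {1, 1.5, 2} -> median 1.5
        assert theil_sen([1.0, 2.0, 4.0]) == pytest.approx(1.5)

    def test_constant(self):
        assert theil_sen(np.full(8, 3.0)) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            y = rng.standard_normal(rng.integers(2, 25))
            assert theil_sen(y) == pytest.approx(brute_force_theil_sen(y), abs=1e-12)

    def test_insufficient_data(self):
        assert np.isnan(theil_sen([1.0]))
        assert np.isnan(theil_sen([1.0, np.nan]))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=-100, max_value=100), min_size=3, max_size=15),
        st.floats(min_value=-10, max_value=10),
        st.floats(min_value=-5, max_value=5),
    )
    def test_affine_equivariance(self, values, a, b):
        y = np.array(values)
        s = theil_sen(y)
        assert theil_sen(a + b * y) == pytest.approx(a * 0 + b * s, abs=1e-8)


class TestMannKendall:
    def test_monotone_strong(self):
        s, z, p = mann_kendall(np.arange(20, dtype=float))
        assert s == 20 * 19 / 2
        assert p < 0.001

    def test_reversed_antisymmetry(self, rng):
        y = rng.standard_normal(15)
        s1, _, p1 = mann_kendall(y)
        s2, _, p2 = mann_kendall(y[::-1])
        assert s2 == -s1
        assert p2 == pytest.approx(p1)

    def test_too_short(self):
        assert np.isnan(mann_kendall_p([1.0, 2.0, 3.0]))

    def test_type_one_error_calibrated(self, rng):
        rejections = sum(mann_kendall_p(rng.standard_normal(30)) < 0.05 for _ in range(400))
        assert 0.02 < rejections / 400 < 0.08

    def test_tie_correction_applied(self):
        y = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0])
        s, z, p = mann_kendall(y)
        assert np.isfinite(p) and p < 0.05


class TestTrendMap:
    def test_rising_persistence_gives_positive_dar(self):
        # phi ramps 0.2 -> 0.8 over time: later windows have higher AR
        rng = np.random.default_rng(5)
        n, side = 40, 8
        data = np.empty((n, side, side))
        for r in range(side):
            for c in range(side):
                e = np.zeros(n)
                e[0] = rng.standard_normal() * 0.1
                for t in range(1, n):
                    phi = 0.2 + 0.6 * t / (n - 1)
                    e[t] = phi * e[t - 1] + 0.1 * np.sqrt(1 - phi**2) * rng.standard_normal()
                data[:, r, c] = 1.0 + e
        from vegstab import GridSpec, RasterStack

        stack = RasterStack(np.abs(data) + 0.01, 1984 + np.arange(n), np.ones((side, side), bool), GridSpec())
        ws = moving_window_metrics(stack, window=15)
        tm = trend_map(ws, "ar")
        assert np.median(tm.slope[tm.valid]) > 0

    def test_all_invalid_input(self, small_stack):
        ws = moving_window_metrics(small_stack, window=15)
        ws.valid[:] = False
        tm = trend_map(ws, "pv")
        assert not tm.valid.any()

    def test_direction_consistent_with_slope(self, small_stack):
        ws = moving_window_metrics(small_stack, window=15)
        tm = trend_map(ws, "pv")
        ok = tm.valid
        assert np.all(np.sign(tm.slope[ok]) == tm.direction[ok])

    def test_bad_metric_rejected(self, small_stack):
        ws = moving_window_metrics(small_stack, window=15)
        with pytest.raises(ValueError):
            trend_map(ws, "cv")


class TestPermutationCalibration:
    def test_stationary_false_positive_rate(self):
        stack = simulate_stack(
            SimConfig(n_years=40, n_rows=10, n_cols=15, phi=0.3, sigma_rel=0.1, seed=77)
        )
        p = window_trend_permutation_p(stack, window=15, metric="pv", n_permutations=99, seed=1)
        assert np.nanmean(p < 0.05) <= 0.10


def _tm(slope, p=None, valid=None):
    slope = np.asarray(slope, float)
    p = np.full_like(slope, 0.01) if p is None else np.asarray(p, float)
    valid = np.isfinite(slope) if valid is None else np.asarray(valid, bool)
    direction = np.zeros(slope.shape, np.int8)
    direction[valid & (slope > 0)] = 1
    direction[valid & (slope < 0)] = -1
    return TrendMap(slope=slope, p_value=p, direction=direction, valid=valid)


class TestCompositeIndex:
    def test_opposing_signs_excluded(self):
        comp = composite_index(_tm([[1.0, -1.0]]), _tm([[-1.0, 1.0]]))
        assert comp.excluded.all()
        assert np.isnan(comp.value).all()
        assert (comp.label == 0).all()

    def test_double_max_pixel_scores_two(self):
        dar = _tm([[2.0, 1.0], [0.5, -0.1]])
        dpv = _tm([[0.4, 0.2], [0.1, -0.3]])
        comp = composite_index(dar, dpv)
        assert comp.value[0, 0] == pytest.approx(2.0)
        assert comp.label[0, 0] == 1

    def test_zero_slopes_retained_neutral(self):
        comp = composite_index(_tm([[0.0]]), _tm([[0.0]]))
        assert not comp.excluded[0, 0]
        assert comp.value[0, 0] == 0.0
        assert comp.label[0, 0] == 3

    def test_sign_sweep_contract(self):
        vals = [-1.0, -0.5, 0.0, 0.5, 1.0]
        dar = _tm([[a for a in vals for _ in vals]])
        dpv = _tm([[b for _ in vals for b in vals]])
        comp = composite_index(dar, dpv)
        a = dar.slope.ravel()
        b = dpv.slope.ravel()
        v = comp.value.ravel()
        lab = comp.label.ravel()
        exc = comp.excluded.ravel()
        for i in range(a.size):
            if np.sign(a[i]) * np.sign(b[i]) < 0:
                assert exc[i] and lab[i] == 0
            else:
                assert not exc[i]
                assert -2.0 - 1e-12 <= v[i] <= 2.0 + 1e-12
                if v[i] > 0:
                    assert lab[i] == 1 and a[i] >= 0 and b[i] >= 0
                elif v[i] < 0:
                    assert lab[i] == 2 and a[i] <= 0 and b[i] <= 0

    def test_hotspot_iff_both_positive(self):
        comp = composite_index(_tm([[0.5, -0.5]]), _tm([[0.2, -0.2]]))
        assert comp.label[0, 0] == 1
        assert comp.label[0, 1] == 2

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_index(_tm([[1.0]]), _tm([[1.0, 2.0]]))

    def test_all_excluded_warns_not_raises(self):
        comp = composite_index(_tm([[1.0]]), _tm([[-1.0]]))
        assert comp.excluded.all()  # empty result, no exception


class TestMoransI:
    def test_checkerboard_negative(self):
        board = np.indices((10, 10)).sum(axis=0) % 2
        i_obs, p = morans_i(board.astype(float), permutations=199, seed=0)
        assert i_obs < -0.9
        assert p < 0.01

    def test_null_expectation_iid(self, rng):
        values = []
        for k in range(40):
            layer = rng.standard_normal((20, 20))
            i_obs, _ = morans_i(layer, permutations=0)
            values.append(i_obs)
        # E[I] = -1/(N-1) under spatial randomness; sd of I at N=400 rook
        # weights is ~0.035, so the replicate mean pins the expectation
        assert abs(np.mean(values) - (-1 / 399)) < 0.02
        assert np.mean(np.abs(np.array(values) - (-1 / 399)) < 0.05) >= 0.8

    def test_two_block_gradient_positive(self):
        layer = np.zeros((10, 10))
        layer[:, 5:] = 1.0
        layer += np.linspace(0, 0.5, 10)[:, None]
        i_obs, p = morans_i(layer, permutations=999, seed=3)
        assert i_obs > 0.5
        assert p < 0.01

    def test_matches_brute_force(self, rng):
        w = rook_weights((8, 8))
        w_dense = w.toarray()
        for _ in range(25):
            layer = rng.standard_normal((8, 8))
            i_fast, _ = morans_i(layer, weights=w, permutations=0)
            assert i_fast == pytest.approx(brute_force_morans_i(layer, w_dense), abs=1e-12)

    def test_constant_layer_rejected(self):
        with pytest.raises(ValueError):
            morans_i(np.ones((5, 5)))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            morans_i(np.random.default_rng(0).standard_normal((2, 2)))


class TestEcosystemState:
    @staticmethod
    def _comp(value, excluded=None):
        value = np.asarray(value, float)
        excluded = np.zeros(value.shape, bool) if excluded is None else np.asarray(excluded, bool)
        label = np.zeros(value.shape, np.uint8)
        from vegstab import CompositeMap

        return CompositeMap(
            value=value, label=label, excluded=excluded,
            valid=np.ones(value.shape, bool), ar_norm=1.0, pv_norm=1.0,
        )

    def test_ideal(self):
        st_map = ecosystem_state(_tm([[0.5]], p=[[0.01]]), self._comp([[-1.2]]))
        assert st_map.codes[0, 0] == 1

    def test_abysmal(self):
        st_map = ecosystem_state(_tm([[-0.5]], p=[[0.01]]), self._comp([[1.0]]))
        assert st_map.codes[0, 0] == 4

    def test_acceptable_and_poor(self):
        st_map = ecosystem_state(
            _tm([[0.5, -0.5]], p=[[0.01, 0.01]]), self._comp([[1.0, -1.0]])
        )
        assert st_map.codes[0, 0] == 2
        assert st_map.codes[0, 1] == 3

    def test_excluded_is_unknown(self):
        comp = self._comp([[np.nan]], excluded=[[True]])
        st_map = ecosystem_state(_tm([[0.5]], p=[[0.01]]), comp)
        assert st_map.codes[0, 0] == 5

    def test_nonsignificant_ef_unknown(self):
        st_map = ecosystem_state(_tm([[0.5]], p=[[0.5]]), self._comp([[-1.0]]))
        assert st_map.codes[0, 0] == 5

    def test_custom_state_table(self):
        table = {(1, -1): "acceptable", (1, 1): "ideal", (-1, -1): "abysmal", (-1, 1): "poor"}
        st_map = ecosystem_state(_tm([[0.5]], p=[[0.01]]), self._comp([[-1.0]]), state_table=table)
        assert st_map.codes[0, 0] == 2

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            ecosystem_state(_tm([[0.5, 1.0]]), self._comp([[1.0]]))
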