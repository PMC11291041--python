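import numpy as np
import pytest
from hypothesis import given, strategies as st

from survpipe.hazard import (
    DiscretizationGrid,
    SurvivalCurve,
    make_grid,
    median_survival,
    pchazard_nll,
)


def step_integral_oracle(hazards, cuts, t, n_points=10_000):
    """Numerically integrate the step hazard on a mesh that includes every
    discontinuity, so the midpoint rule is exact for the step function."""
    pts = np.concatenate([np.linspace(0.0, t, n_points), cuts[cuts < t], [t]])
    pts = np.unique(pts)
    mids = (pts[:-1] + pts[1:]) / 2
    k = np.searchsorted(cuts, mids, side="left") - 1
    lam = np.asarray(hazards)[k]
    return float(np.sum(lam * np.diff(pts)))


class TestGrid:
    def test_median_split_example(self):
        grid = make_grid(np.array([1.0, 2.0, 3.0, 4.0]), m=2)
        np.testing.assert_allclose(grid.cuts, [0.0, 2.5, 4.0])

    def test_single_interval(self):
        grid = make_grid(np.array([3.0, 7.0]), m=1)
        np.testing.assert_allclose(grid.cuts, [0.0, 7.0])

    def test_constant_durations_degenerate(self):
        with pytest.raises(ValueError):
            make_grid(np.array([5.0, 5.0, 5.0]), m=2)

    def test_m_exceeding_distinct_durations(self):
        with pytest.raises(ValueError, match="distinct"):
            make_grid(np.array([1.0, 2.0]), m=3)

    def test_last_cut_covers_max(self):
        rng = np.random.default_rng(0)
        d = rng.exponential(10, 100) + 0.01
        grid = make_grid(d, m=5)
        assert grid.cuts[-1] == d.max()

    def test_locate_boundaries(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0, 2.0]))
        k, rho = grid.locate(np.array([1.0, 1.5, 2.0]))
        np.testing.assert_array_equal(k, [0, 1, 1])
        np.testing.assert_allclose(rho, [1.0, 0.5, 1.0])


class TestNLL:
    def test_single_interval_event(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0]))
        assert pchazard_nll(np.array([1.0]), grid, 0.5, 1) == pytest.approx(0.5)

    def test_two_interval_event_closed_form(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0, 2.0]))
        val = pchazard_nll(np.array([2.0, 0.5]), grid, 1.5, 1)
        assert val == pytest.approx(-np.log(0.5) + 2.0 + 0.25, abs=1e-12)

    def test_censored_is_cumulative_hazard_only(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0]))
        assert pchazard_nll(np.array([1.0]), grid, 0.5, 0) == pytest.approx(0.5)

    def test_event_with_zero_hazard_errors(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="zero hazard"):
            pchazard_nll(np.array([0.0]), grid, 0.5, 1)

    def test_time_outside_grid_errors(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            pchazard_nll(np.array([1.0]), grid, 1.5, 1)

    @given(
        data=st.data(),
        m=st.integers(1, 5),
        d=st.integers(0, 1),
    )
    def test_matches_numeric_integration_oracle(self, data, m, d):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        cuts = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 10.0, m))])
        grid = DiscretizationGrid(cuts=cuts)
        lam = rng.uniform(0.05, 3.0, m)
        t = rng.uniform(1e-6, cuts[-1])
        H = step_integral_oracle(lam, cuts, t)
        k = np.searchsorted(cuts, t, side="left") - 1
        expected = H - d * np.log(lam[k])
        assert pchazard_nll(lam, grid, t, d) == pytest.approx(expected, abs=1e-6)


class TestCurveAndMedian:
    def test_unit_hazard_point(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0]))
        curve = _curve_from(np.array([1.0]), grid)
        assert curve.at(0.5)[0] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_zero_hazard_gives_unit_survival(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0, 2.0]))
        curve = _curve_from(np.array([0.0, 0.0]), grid)
        np.testing.assert_allclose(curve.survival, 1.0)

    def test_two_interval_closed_form(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0, 2.0]))
        curve = _curve_from(np.array([2.0, 0.5]), grid)
        assert curve.at(1.5)[0] == pytest.approx(np.exp(-2.25), rel=1e-10)

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(1)
        grid = DiscretizationGrid(cuts=np.concatenate([[0.0], np.sort(rng.uniform(0.5, 20, 6))]))
        curve = _curve_from(rng.uniform(0, 2, 6), grid)
        assert np.all(np.diff(curve.survival) <= 1e-15)

    def test_constant_hazard_median(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 100.0]))
        curve = _curve_from(np.array([0.1]), grid)
        med = median_survival(curve)
        assert med.time == pytest.approx(np.log(2) / 0.1, rel=1e-9)
        assert not med.extrapolated

    def test_median_exactly_at_cut_point(self):
        lam = np.log(2)  # S(1) = 0.5 exactly
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0, 2.0]))
        curve = _curve_from(np.array([lam, lam]), grid)
        assert median_survival(curve).time == pytest.approx(1.0, rel=1e-12)

    def test_crossing_inside_first_interval(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0, 2.0]))
        curve = _curve_from(np.array([2.0, 0.5]), grid)
        assert median_survival(curve).time == pytest.approx(np.log(2) / 2, rel=1e-9)

    def test_extrapolated_median_flagged(self):
        grid = DiscretizationGrid(cuts=np.array([0.0, 1.0]))
        curve = _curve_from(np.array([0.1]), grid)  # S(1)=0.905 > 0.5
        med = median_survival(curve)
        assert med.extrapolated
        assert med.time == pytest.approx(np.log(2) / 0.1, rel=1e-9)

    def test_zero_tail_hazard_median_undefined(self):
        curve = SurvivalCurve(times=np.array([0.0, 1.0, 2.0]),
                              survival=np.array([1.0, 0.9, 0.9]))
        with pytest.raises(ValueError, match="median undefined"):
            median_survival(curve)

    @given(scale=st.floats(0.1, 100.0))
    def test_median_equivariant_under_time_rescaling(self, scale):
        grid1 = DiscretizationGrid(cuts=np.array([0.0, 1.0, 2.0]))
        lam = np.array([0.9, 0.4])
        grid2 = DiscretizationGrid(cuts=grid1.cuts * scale)
        m1 = median_survival(_curve_from(lam, grid1)).time
        m2 = median_survival(_curve_from(lam / scale, grid2)).time
        assert m2 == pytest.approx(m1 * scale, rel=1e-9)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            SurvivalCurve(times=np.array([0.0, 1.0]), survival=np.array([1.0, 1.1]))
        with pytest.raises(ValueError):
            SurvivalCurve(times=np.array([0.0, 1.0]), survival=np.array([0.9, 0.8]))


def _curve_from(hazards, grid):
    from survpipe.hazard import HazardModel, HazardNetConfig, predict_curve
    from survpipe._mlp import MLP

    class _Fixed:
        def __init__(self, lam):
            self.lam = np.asarray(lam, dtype=float)

        def forward(self, X, training=False, rng=None):
            # inverse softplus so the model head reproduces lam exactly
            lam = np.clip(self.lam, 1e-12, None)
            return np.tile(np.log(np.expm1(lam)) if np.all(lam < 30) else lam,
                           (X.shape[0], 1))

    model = HazardModel(net=_Fixed(hazards), grid=grid,
                        config=HazardNetConfig(m=grid.m))
    return predict_curve(model, np.zeros(1))


def test_fixed_hazard_helper_is_exact():
    grid = DiscretizationGrid(cuts=np.array([0.0, 1.0]))
    curve = _curve_from(np.array([1.0]), grid)
    assert curve.at(1.0)[0] == pytest.approx(np.exp(-1.0), rel=1e-9)
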