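"""Inverse fit: SSE objective, annealing search, curve aggregation, calls."""

import numpy as np
import pytest

from sftm import (
    EfficiencyCurve,
    FitConfig,
    Origin,
    ReplicationModel,
    SearchResult,
    SimulationConfig,
    TimeCourse,
    anneal_search,
    benchmark_nine_origin,
    call_origins,
    example_two_origin,
    firing_efficiency,
    fit_sftm,
    noiseless_timecourse,
    regional_efficiency_curve,
    sse_objective,
)
from sftm.profiles import InvalidTimeCourseError


def search_result(locations, efficiencies, t_starts=None, t_ends=None, **kw):
    locations = np.asarray(locations, dtype=float)
    n = locations.size
    return SearchResult(
        locations=locations,
        t_starts=np.zeros(n) if t_starts is None else np.asarray(t_starts, float),
        t_ends=np.full(n, 10.0) if t_ends is None else np.asarray(t_ends, float),
        efficiencies=np.asarray(efficiencies, dtype=float),
        sse=kw.get("sse", 1.0),
        m_requested=kw.get("m_requested", n),
        seed=kw.get("seed", 0),
    )


@pytest.fixture(scope="module")
def two_origin_tc():
    model, tc = example_two_origin()
    return model, tc


class TestSseObjective:
    def test_zero_on_own_data(self, two_origin_tc):
        model, tc = two_origin_tc
        assert sse_objective(model, tc) == pytest.approx(0.0, abs=1e-20)

    def test_noise_floor_matches_chi_square(self):
        # 100 loci x 10 times: SSE of the true model is ~ sd^2 * chi2_1000,
        # i.e. n*sd^2 within a few percent.
        model, _ = benchmark_nine_origin()
        cfg = SimulationConfig(
            model, 1000, tuple(float(t) for t in range(0, 20, 2)), noise_sd=0.0
        )
        clean = noiseless_timecourse(cfg)
        rng = np.random.default_rng(42)
        sd = 0.1
        noisy = TimeCourse(
            clean.chrom, clean.positions, clean.times,
            clean.values + rng.normal(0, sd, clean.values.shape),
            normalized=True,
        )
        expected = clean.values.size * sd**2
        assert sse_objective(model, noisy) == pytest.approx(expected, rel=0.20)

    def test_location_perturbation_increases_sse(self, two_origin_tc):
        model, tc = two_origin_tc
        base = sse_objective(model, tc)
        for delta in (-1000.0, 1000.0):
            shifted = ReplicationModel(
                [Origin(1000 + delta, 0, 10), Origin(4000, 2, 6)],
                model.fork_velocity, model.chrom_length,
            )
            assert sse_objective(shifted, tc) > base + 1e-6

    def test_requires_normalized(self, two_origin_tc):
        model, tc = two_origin_tc
        raw = TimeCourse(tc.chrom, tc.positions, tc.times, tc.values, normalized=False)
        with pytest.raises(ValueError, match="normalis"):
            sse_objective(model, raw)


class TestAnnealSearch:
    def test_single_origin_recovered(self):
        model = ReplicationModel([Origin(3000, 1, 7)], 1000.0, 6000.0)
        cfg = SimulationConfig(model, 1000, tuple(np.linspace(0, 12, 13)), noise_sd=0)
        tc = noiseless_timecourse(cfg)
        res = anneal_search(tc, 1, FitConfig(velocity=1000.0), seed=5)
        assert abs(res.locations[0] - 3000.0) <= 1000.0
        assert res.sse <= 0.05
        assert res.efficiencies[0] == pytest.approx(1.0)

    def test_two_origins_recovered_with_restarts(self, two_origin_tc):
        model, tc = two_origin_tc
        cfg = FitConfig(velocity=1000.0)
        best = min(
            (anneal_search(tc, 2, cfg, seed=s) for s in range(5)),
            key=lambda r: r.sse,
        )
        assert best.n_origins == 2
        assert abs(best.locations[0] - 1000.0) <= 1000.0
        assert abs(best.locations[1] - 4000.0) <= 1000.0

    def test_dormant_origins_discarded(self, two_origin_tc):
        _, tc = two_origin_tc
        for s in range(3):
            res = anneal_search(tc, 3, FitConfig(velocity=1000.0), seed=s)
            assert np.all(res.efficiencies >= 1e-6)

    def test_m_bounds_checked(self, two_origin_tc):
        _, tc = two_origin_tc
        with pytest.raises(ValueError, match="m="):
            anneal_search(tc, 99, FitConfig(velocity=1000.0), seed=0)

    def test_reproducible_under_seed(self, two_origin_tc):
        _, tc = two_origin_tc
        cfg = FitConfig(velocity=1000.0)
        a = anneal_search(tc, 2, cfg, seed=17)
        b = anneal_search(tc, 2, cfg, seed=17)
        assert np.array_equal(a.locations, b.locations)
        assert a.sse == b.sse


class TestRegionalEfficiencyCurve:
    grid = np.arange(0.0, 10_001.0, 1000.0)

    def test_single_origin_peak(self):
        results = [search_result([5000.0], [0.6]) for _ in range(4)]
        curve = regional_efficiency_curve(results, self.grid, window=3000)
        assert curve.values[5] == pytest.approx(0.6)
        assert curve.values[0] == 0.0

    def test_empty_searches_give_zero(self):
        results = [search_result([], [])]
        curve = regional_efficiency_curve(results, self.grid, window=3000)
        assert np.all(curve.values == 0.0)

    def test_close_origins_sum(self):
        results = [search_result([4000.0, 5000.0], [0.3, 0.4])]
        curve = regional_efficiency_curve(results, self.grid, window=3000)
        # Window of 3 kbp centred between them covers both.
        assert curve.values[4] == pytest.approx(0.7)

    def test_capped_at_one(self):
        results = [search_result([4000.0, 4500.0, 5000.0], [0.9, 0.9, 0.9])]
        curve = regional_efficiency_curve(results, self.grid, window=3000)
        assert np.all(curve.values <= 1.0)

    def test_product_mode(self):
        results = [search_result([4000.0, 5000.0], [0.5, 0.5])]
        curve = regional_efficiency_curve(
            results, self.grid, window=3000, combine="product"
        )
        assert curve.values[4] == pytest.approx(0.75)

    def test_average_over_searches(self):
        results = [
            search_result([5000.0], [0.8]),
            search_result([], []),
        ]
        curve = regional_efficiency_curve(results, self.grid, window=3000)
        assert curve.values[5] == pytest.approx(0.4)


class TestCallOrigins:
    grid = np.arange(0.0, 20_001.0, 1000.0)

    def make_curve(self, peaks):
        values = np.zeros(self.grid.size)
        for idx, height in peaks:
            values[idx] = height
            values[idx - 1] = height / 2
            values[idx + 1] = height / 2
        return EfficiencyCurve(self.grid, values)

    def test_subthreshold_peak_not_called(self):
        curve = self.make_curve([(10, 0.04)])
        results = [search_result([10_000.0], [0.04])]
        assert call_origins(curve, results, threshold=0.05, window=3000) == []

    def test_single_call_with_median_window(self):
        curve = self.make_curve([(10, 0.6)])
        results = [
            search_result([10_200.0], [0.6], t_starts=[2.0], t_ends=[6.0]),
            search_result([9_800.0], [0.5], t_starts=[4.0], t_ends=[8.0]),
        ]
        calls = call_origins(curve, results, threshold=0.05, window=3000)
        assert len(calls) == 1
        c = calls[0]
        assert c.location == 10_000.0
        assert c.efficiency == pytest.approx(0.6)
        assert c.t_fire_start == pytest.approx(3.0)
        assert c.t_fire_end == pytest.approx(7.0)
        assert c.n_support == 2

    def test_plateau_resolved_to_midpoint(self):
        # An isolated origin yields a window-wide rectangular plateau
        # centred on it; the call goes to the plateau midpoint.
        values = np.zeros(self.grid.size)
        values[8:11] = 0.5
        curve = EfficiencyCurve(self.grid, values)
        results = [search_result([9000.0], [0.5])]
        calls = call_origins(curve, results, threshold=0.05, window=3000)
        assert len(calls) == 1
        assert calls[0].location == 9000.0

    def test_empty_call_list_allowed(self):
        curve = EfficiencyCurve(self.grid, np.zeros(self.grid.size))
        assert call_origins(curve, [], threshold=0.05, window=3000) == []


class TestFitPipeline:
    def test_two_origin_end_to_end(self, two_origin_tc):
        model, tc = two_origin_tc
        # Window below the 3 kbp inter-origin distance so the two calls
        # stay separable on this short demo chromosome.
        config = FitConfig(
            m_range=(2, 2), n_restarts=4, velocity=1000.0, seed=11,
            region_window=2000.0,
        )
        calls, diag = fit_sftm(tc, config)
        assert len(calls) == 2
        locs = sorted(c.location for c in calls)
        assert abs(locs[0] - 1000.0) <= 1000.0
        assert abs(locs[1] - 4000.0) <= 1000.0
        true_eff = [firing_efficiency(model, i) for i in range(2)]
        called_eff = [c.efficiency for c in sorted(calls, key=lambda c: c.location)]
        assert called_eff == pytest.approx(true_eff, abs=0.05)
        assert {r["m"] for r in diag["searches"]} == {2}

    def test_pipeline_deterministic(self, two_origin_tc):
        _, tc = two_origin_tc
        config = FitConfig(m_range=(2, 2), n_restarts=2, velocity=1000.0, seed=3)
        calls_a, _ = fit_sftm(tc, config)
        calls_b, _ = fit_sftm(tc, config)
        assert [(c.location, c.efficiency) for c in calls_a] == [
            (c.location, c.efficiency) for c in calls_b
        ]

    def test_constant_input_rejected(self):
        tc = TimeCourse(
            "chrT", 1000.0 * np.arange(1, 6), np.arange(5.0),
            np.full((5, 5), 0.5),
        )
        with pytest.raises(InvalidTimeCourseError):
            fit_sftm(tc, FitConfig(velocity=1000.0))

    def test_curve_values_bounded(self, two_origin_tc):
        _, tc = two_origin_tc
        config = FitConfig(m_range=(3, 3), n_restarts=2, velocity=1000.0, seed=5)
        _, diag = fit_sftm(tc, config)
        curve = diag["curve"]
        assert np.all((curve.values >= 0) & (curve.values <= 1))
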